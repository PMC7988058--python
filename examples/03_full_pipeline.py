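"""Full pipeline on a synthetic cohort: phantoms -> features -> screen -> KM/Cox.

Generates a 30-patient cohort whose death hazard falls with true lesion MPP
(HR 0.89 per unit), extracts the 36 features per patient, screens them by
ROC against the progression label, and reports KM and Cox results for the
screened features. Everything is reproducible from the embedded config.
"""

from texsurv import CohortSpec, RunConfig, run_all

config = RunConfig(
    cohort=CohortSpec(n_patients=30, seed=2, beta_mpp=-0.117),
    out_dir="scratch/example_run",
)
report = run_all(config)

print(f"\nROC screen: {len(report.screened)} of {len(report.roc_table)} feature/SSF "
      f"combinations pass p < {0.05}")
for row in sorted(report.roc_table, key=lambda r: -r.get("auc", 0))[:5]:
    print(
        f"  {row['feature']:>9} SSF {row['ssf']:g}: AUC {row['auc']:.3f} "
        f"({row['direction']}), p={row['p_value']:.2g}"
    )
print("\nCox (OS, per feature unit) for screened features:")
for c in report.cox_results:
    if c.get("status") == "ok":
        print(
            f"  {c['feature']:>9} SSF {c['ssf']:g}: HR {c['hr']:.3f} "
            f"[{c['ci95'][0]:.3f}, {c['ci95'][1]:.3f}], p={c['p_value']:.2g}"
        )
print(
    "\nAn MPP hazard ratio below 1 reproduces the generated direction of effect:\n"
    "patients with brighter highlighted texture (higher MPP) live longer."
)
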