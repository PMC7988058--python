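"""End-to-end orchestration: simulate/load -> extract -> screen -> KM/Cox.

A run is fully determined by a :class:`RunConfig` (parsed from YAML or JSON
or built in code): it either points at real inputs (volumes + masks +
survival CSV) or embeds a synthetic :class:`~texsurv.cohort.CohortSpec` —
never both. The analysis has two stages, mirroring univariate biomarker
screening: every feature x SSF is first tested by ROC against the
progression label; features passing the p-value screen proceed to
optimal-threshold Kaplan-Meier (OS and PFS) and univariate Cox (OS).
Every cut-point p-value is labelled exploratory, because the threshold is
searched rather than pre-specified.

Reports carry a provenance block (config hash, seed, package version) and
contain no timestamps, so rerunning the same config reproduces the report
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, imaging_io
from .cohort import CohortSpec, PhantomSpec, generate_cohort, write_cohort
from .errors import ConfigurationError, DataError, KeyingError, ValidationError
from .filtration import (
    DEFAULT_CONFIG,
    DEFAULT_SSF_LIST,
    FiltrationConfig,
    extract_feature_table,
)
from .imaging_io import FEATURE_COLUMNS, CTVolume
from .survival import cox_univariate, optimal_cutoff_km, roc_analysis

logger = logging.getLogger("texsurv")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort: CohortSpec | None = None
    data_dir: str | None = None
    volumes: tuple[str, ...] | None = None
    masks: tuple[str, ...] | None = None
    survival_csv: str | None = None
    ssf_list: tuple[float, ...] = DEFAULT_SSF_LIST
    screen_p: float = 0.05
    endpoints: tuple[str, ...] = ("os", "pfs")
    per_slice: bool = False
    out_dir: str = "texsurv_run"
    seed: int | None = None
    write_phantoms: bool = False
    plots: bool = False

    def __post_init__(self):
        has_real = self.data_dir is not None or self.volumes is not None
        if self.cohort is not None and has_real:
            raise ConfigurationError(
                "config must give either real inputs or a cohort spec, not both"
            )
        if self.cohort is None and not has_real:
            raise ConfigurationError("config gives neither real inputs nor a cohort spec")
        if has_real and self.survival_csv is None:
            raise ConfigurationError("real inputs require a survival table CSV")
        if self.volumes is not None:
            if self.masks is None or len(self.masks) != len(self.volumes):
                raise ConfigurationError("volumes and masks lists must align")
        bad = [e for e in self.endpoints if e not in ("os", "pfs")]
        if bad:
            raise ConfigurationError(f"unknown endpoints: {bad}")
        if not 0 < self.screen_p <= 1:
            raise ConfigurationError("screen_p must be in (0, 1]")

    @property
    def effective_seed(self) -> int:
        if self.seed is not None:
            return int(self.seed)
        if self.cohort is not None:
            return int(self.cohort.seed)
        return 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_cohort_spec(d: dict) -> CohortSpec:
    d = dict(d)
    phantom = d.pop("phantom", None)
    kwargs = {}
    if phantom is not None:
        p = dict(phantom)
        for key in ("grid_shape", "spacing_mm"):
            if key in p:
                p[key] = tuple(p[key])
        kwargs["phantom"] = PhantomSpec(**p)
    for key in (
        "lesion_mean_hu_range",
        "texture_amplitude_hu_range",
        "texture_scale_mm_range",
        "lesion_diameter_mm_range",
    ):
        if key in d:
            d[key] = tuple(d[key])
    return CohortSpec(**d, **kwargs)


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a plain dict (parsed YAML/JSON)."""
    d = dict(d)
    try:
        if "cohort" in d and d["cohort"] is not None:
            d["cohort"] = _build_cohort_spec(d["cohort"])
        inputs = d.pop("inputs", None)
        if inputs:
            d["data_dir"] = inputs.get("data_dir")
            if "volumes" in inputs:
                d["volumes"] = tuple(inputs["volumes"])
                d["masks"] = tuple(inputs["masks"])
            d["survival_csv"] = inputs.get("survival")
        for key in ("ssf_list", "endpoints"):
            if key in d:
                d[key] = tuple(d[key])
        return RunConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(f"bad config field: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def run_extract(
    pairs,
    ssf_list=DEFAULT_SSF_LIST,
    config: FiltrationConfig = DEFAULT_CONFIG,
    per_slice: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Extract the feature table for (volume, mask) pairs.

    ``pairs`` yields either in-memory (CTVolume, LesionMask) tuples or
    (volume path, mask path) tuples. A failure on one patient is logged and
    isolated — remaining patients still produce rows. Returns the table and
    the list of per-patient failures.
    """
    tables, failures = [], []
    n_ok = 0
    for vol_src, mask_src in pairs:
        pid = None
        try:
            if isinstance(vol_src, CTVolume):
                volume, mask = vol_src, mask_src
            else:
                stem = Path(vol_src).name.split(".")[0]
                pid = stem[:-3] if stem.endswith("_ct") else stem
                volume = imaging_io.read_volume(vol_src, patient_id=pid)
                mask = imaging_io.read_mask(mask_src, volume)
            pid = volume.patient_id
            tables.append(
                extract_feature_table(volume, mask, ssf_list, config, per_slice=per_slice)
            )
            n_ok += 1
            logger.info("extracted features for %s", pid)
        except (DataError, OSError) as exc:
            failures.append({"patient_id": pid or str(vol_src), "reason": str(exc)})
            logger.warning("skipping %s: %s", pid or vol_src, exc)
    if n_ok == 0:
        raise ConfigurationError("no patients could be extracted")
    return pd.concat(tables, ignore_index=True), failures


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisReport:
    """Structured result of one pipeline run (JSON-serialisable)."""

    roc_table: list[dict]
    screened: list[dict]
    km_results: list[dict]
    cox_results: list[dict]
    failures: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, float) and not math.isfinite(obj):
                return None
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return clean(obj.item())
            return obj

        return json.dumps(clean(self.to_dict()), sort_keys=True, indent=2) + "\n"


def _roc_stage(features: pd.DataFrame, survival: pd.DataFrame) -> list[dict]:
    merged = features.merge(
        survival[["patient_id", "progressor"]], on="patient_id", how="left"
    )
    rows = []
    for (feat, ssf), grp in (
        merged.melt(
            id_vars=[c for c in ("patient_id", "ssf", "progressor") if c in merged],
            value_vars=FEATURE_COLUMNS,
            var_name="feature",
        )
        .groupby(["feature", "ssf"], sort=True)
    ):
        row = {"feature": feat, "ssf": float(ssf)}
        vals = grp.dropna(subset=["value"])
        try:
            if len(vals) < len(grp):
                row["n_missing"] = int(len(grp) - len(vals))
            if len(vals) < 4:
                raise ValidationError("fewer than 4 observations with a defined value")
            roc = roc_analysis(vals["value"].to_numpy(), vals["progressor"].to_numpy())
            row.update(roc.as_dict())
            row["n"] = int(len(vals))
            row["status"] = "ok"
        except ValidationError as exc:
            row["status"] = "excluded"
            row["reason"] = str(exc)
        rows.append(row)
    return rows


def run_analysis(
    features: pd.DataFrame,
    survival: pd.DataFrame,
    config: RunConfig,
    roc_features: pd.DataFrame | None = None,
) -> AnalysisReport:
    """Two-stage analysis: ROC screen, then KM/Cox on screened features.

    ``roc_features`` optionally supplies a finer observation unit (per-slice
    rows) for stage 1; stage 2 always runs per patient.
    """
    survival = imaging_io.validate_survival_table(survival)
    feat_ids = set(features["patient_id"])
    surv_ids = set(survival["patient_id"])
    matched = feat_ids & surv_ids
    if len(matched) < 4:
        orphans = sorted(feat_ids ^ surv_ids)
        raise KeyingError(
            f"only {len(matched)} patients join between features and survival; "
            f"unmatched ids: {orphans}",
            orphans=orphans,
        )

    features = features[features["patient_id"].isin(matched)]
    survival = survival[survival["patient_id"].isin(matched)].reset_index(drop=True)

    stage1 = _roc_stage(
        roc_features if roc_features is not None else features, survival
    )

    screened = [
        {"feature": r["feature"], "ssf": r["ssf"], "auc": r["auc"], "p_value": r["p_value"]}
        for r in stage1
        if r.get("status") == "ok" and r["p_value"] < config.screen_p
    ]

    wide = features.set_index(["patient_id", "ssf"])
    km_results, cox_results = [], []
    for hit in screened:
        col = wide[hit["feature"]].xs(hit["ssf"], level="ssf")
        joined = survival.set_index("patient_id").join(col.rename("value"), how="inner")
        joined = joined.dropna(subset=["value"])
        base = {"feature": hit["feature"], "ssf": hit["ssf"]}
        for endpoint in config.endpoints:
            tcol, ecol = f"{endpoint}_days", f"{endpoint}_event"
            entry = dict(base, endpoint=endpoint)
            try:
                cp = optimal_cutoff_km(
                    joined["value"].to_numpy(),
                    joined[tcol].to_numpy(),
                    joined[ecol].to_numpy(),
                )
                entry.update(cp.logrank.as_dict())
                entry["n_candidates"] = cp.n_candidates
                entry["status"] = "ok"
            except ValidationError as exc:
                entry["status"] = "excluded"
                entry["reason"] = str(exc)
            km_results.append(entry)
        centry = dict(base, endpoint="os")
        try:
            cox = cox_univariate(
                joined["value"].to_numpy(),
                joined["os_days"].to_numpy(),
                joined["os_event"].to_numpy(),
            )
            centry.update(cox.as_dict())
            centry["status"] = "ok"
        except ValidationError as exc:
            centry["status"] = "excluded"
            centry["reason"] = str(exc)
        cox_results.append(centry)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.effective_seed,
        "version": __version__,
        "n_patients": int(len(survival)),
        "screen_p": config.screen_p,
        "cutpoint_p_values": "exploratory (threshold searched, no multiplicity adjustment)",
    }
    return AnalysisReport(
        roc_table=stage1,
        screened=screened,
        km_results=km_results,
        cox_results=cox_results,
        failures=[],
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _resolve_pairs(config: RunConfig):
    if config.volumes is not None:
        return list(zip(config.volumes, config.masks))
    data_dir = Path(config.data_dir)
    if not data_dir.is_dir():
        raise ConfigurationError(f"data_dir does not exist: {data_dir}")
    vols = sorted(data_dir.glob("*_ct.nii*"))
    pairs = []
    for v in vols:
        m = Path(str(v).replace("_ct.nii", "_mask.nii"))
        if m.exists():
            pairs.append((v, m))
        else:
            logger.warning("no mask found for %s", v)
    if not pairs:
        raise ConfigurationError(f"no volume/mask pairs found under {data_dir}")
    return pairs


def run_all(config: RunConfig, out_dir=None) -> AnalysisReport:
    """Simulate (if configured) -> extract -> analyze -> write artifacts.

    Writes ``features.csv``, ``survival.csv``, ``report.json`` (and
    ``truth.csv`` for synthetic cohorts) under the output directory.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort is not None:
        spec = config.cohort
        if config.seed is not None:
            spec = dataclasses.replace(spec, seed=int(config.seed))
        logger.info("simulating cohort: n=%d seed=%d", spec.n_patients, spec.seed)
        cohort = generate_cohort(spec)
        pairs = list(zip(cohort.volumes, cohort.masks))
        survival = cohort.survival
        cohort.truth.to_csv(out / "truth.csv", index=False)
        if config.write_phantoms:
            write_cohort(cohort, out / "phantoms")
    else:
        pairs = _resolve_pairs(config)
        survival = imaging_io.read_survival_table(config.survival_csv)

    logger.info("extracting features (SSF list %s)", list(config.ssf_list))
    features, failures = run_extract(pairs, config.ssf_list)
    roc_features = None
    if config.per_slice:
        roc_features, _ = run_extract(pairs, config.ssf_list, per_slice=True)

    imaging_io.write_feature_table(features, out / "features.csv")
    imaging_io.write_survival_table(survival, out / "survival.csv")

    logger.info("running analysis on %d patients", features["patient_id"].nunique())
    report = run_analysis(features, survival, config, roc_features=roc_features)
    report = dataclasses.replace(report, failures=failures)
    (out / "report.json").write_text(report.to_json())
    if config.plots:
        _write_plots(report, features, survival, out)
    logger.info("report written to %s", out / "report.json")
    return report


def _write_plots(report: AnalysisReport, features, survival, out: Path) -> None:
    """Optional KM and ROC figures for screened features."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .survival import km_estimate

    plot_dir = out / "plots"
    plot_dir.mkdir(exist_ok=True)
    wide = features.set_index(["patient_id", "ssf"])
    for entry in report.km_results:
        if entry.get("status") != "ok":
            continue
        col = wide[entry["feature"]].xs(entry["ssf"], level="ssf")
        joined = survival.set_index("patient_id").join(col.rename("value")).dropna(
            subset=["value"]
        )
        thr = entry["threshold"]
        tcol, ecol = f"{entry['endpoint']}_days", f"{entry['endpoint']}_event"
        fig, ax = plt.subplots(figsize=(5, 4))
        for label, sel in (("low", joined["value"] <= thr), ("high", joined["value"] > thr)):
            curve = km_estimate(joined.loc[sel, tcol], joined.loc[sel, ecol])
            ax.step(
                np.concatenate([[0], curve.event_times]),
                np.concatenate([[1.0], curve.survival_probs]),
                where="post",
                label=f"{label} (n={sel.sum()})",
            )
        ax.set_xlabel(f"{entry['endpoint'].upper()} days")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        ax.set_title(
            f"{entry['feature']} SSF {entry['ssf']:g} <= {thr:.2f} "
            f"(log-rank p={entry['p_value']:.3g}, exploratory)"
        )
        fig.tight_layout()
        fig.savefig(plot_dir / f"km_{entry['feature']}_ssf{entry['ssf']:g}_{entry['endpoint']}.png")
        plt.close(fig)
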