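"""Filter one synthetic lesion and read off its first-order texture features.

Builds a textured lesion phantom, applies the Laplacian-of-Gaussian
band-pass at each spatial scale filter (SSF) value and prints the six
first-order histogram features of the lesion VOI per scale.
"""

from texsurv import PhantomSpec, extract_feature_table, generate_phantom

spec = PhantomSpec(
    lesion_diameter_mm=14.0,
    lesion_mean_hu=60.0,       # venous-phase soft-tissue enhancement
    texture_amplitude_hu=35.0,  # heterogeneity strength
    texture_scale_mm=3.0,       # correlation length of the texture
)
volume, mask = generate_phantom(spec, seed=1, patient_id="demo")

table = extract_feature_table(volume, mask)
print(table.round(3).to_string(index=False))
print(
    "\nSSF 0 is the unfiltered lesion (mean ~ its HU); at SSF > 0 the zero-sum\n"
    "band-pass removes the mean, so 'mean' hovers near 0 while 'sd' and 'mpp'\n"
    "grow where the filter scale matches the ~3 mm texture."
)
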