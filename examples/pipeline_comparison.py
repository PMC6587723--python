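"""Compare nuisance-regression pipelines on a small synthetic group.

Runs three pipelines (no regression, WM+CSF+RP, and the full basis with
polynomial detrending) over a reduced group and prints the grey-matter
mean one-sample t value per measure — the intersubject-consistency
statistic the pipelines are judged by.
"""

from alffpipe import SimulationConfig, generate_group, group_summary, parse_label

config = SimulationConfig(n_subjects=8, n_sessions=2, rng_seed=5)
group = generate_group(config)

labels = ["none", "wm+csf+rp", "detr+wm+csf+rp"]
summaries = {label: group_summary(group, parse_label(label)) for label in labels}

header = f"{'pipeline':>16s}" + "".join(f"{m:>10s}" for m in ("alff", "falff", "hfalff"))
print(header)
for label in labels:
    row = f"{label:>16s}"
    for measure in ("alff", "falff", "hfalff"):
        row += f"{summaries[label][measure]['gm_mean_t']:10.1f}"
    print(row)

trt_none = summaries["none"]["alff"]["gm_trt_variance"]
trt_full = summaries["detr+wm+csf+rp"]["alff"]["gm_trt_variance"]
print(f"\nALFF test-retest variance: none {trt_none:.2e} -> "
      f"full {trt_full:.2e} ({100 * (trt_full - trt_none) / trt_none:+.0f}%)")
# Full regression raises ALFF consistency and cuts test-retest variance;
# for fALFF the best pipeline omits polynomial detrending — the
# direction-of-effect pattern the package is built to expose.
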