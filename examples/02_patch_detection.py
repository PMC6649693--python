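"""Call contiguous binding patches and score them against the answer key.

Runs CSP + intensity-ratio analysis on a synthetic titration, merges
significant residues into patches and reports per-patch Jaccard overlap
with the planted ground truth.
"""

from titramap import (
    SimConfig,
    answer_key_report,
    compute_csp,
    compute_intensity_ratio,
    detect_patches,
    generate_titration,
)

series, truth = generate_titration(SimConfig(seed=7))
free, top = series.free, series.points[-1]

patches = detect_patches(compute_csp(free, top), compute_intensity_ratio(free, top))
for p in patches:
    print(f"patch {p.start_index}-{p.end_index}  len={p.length}  "
          f"peak CSP={p.peak_value:.3f} ppm  triggered by {p.track_names}")

report = answer_key_report(truth, patches)
print(f"sensitivity={report['sensitivity']:.2f}  "
      f"spurious={report['n_spurious']}  "
      f"Jaccard per planted patch={[round(j, 2) for j in report['per_patch_jaccard']]}")
# Sensitivity 1.0 with zero spurious patches means every planted contact
# patch was recovered and nothing was hallucinated from baseline noise.
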