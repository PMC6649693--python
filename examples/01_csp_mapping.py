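"""Map a binding surface from chemical-shift perturbations.

Generates a synthetic 4-point titration (free + 0.5/1/2 ligand equivalents
on a 191-residue construct with four planted contact patches), computes the
weighted CSP track at the top point and prints the residues above the
significance threshold.
"""

import numpy as np

from titramap import SimConfig, compute_csp, generate_titration
from titramap.patch_detection import PatchParams, csp_significance_threshold

series, truth = generate_titration(SimConfig(seed=42))
csp = compute_csp(series.free, series.points[-1])

thr = csp_significance_threshold(csp, PatchParams())
hot = csp.residue_index[csp.present & (csp.values > thr)]
print(f"CSP threshold (trimmed mean + 2 sd): {thr:.4f} ppm")
print(f"significant residues: {list(map(int, hot))}")
print(f"planted patches:      {[(s, e) for s, e, _ in truth.patches]}")
print(f"max CSP: {np.nanmax(csp.values):.3f} ppm at residue "
      f"{int(csp.residue_index[np.nanargmax(csp.values)])}")
# Significant residues should cluster inside the planted patches: a large
# compound shift change marks a contact site or a binding-coupled
# conformational change.
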