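# titramap

NMR titration analysis for mapping protein–ligand interaction surfaces from
assigned 2D ¹H–¹⁵N peak lists.

When an isotope-labelled protein is titrated with an unlabelled binding
partner (a peptide, a nucleic acid, a nucleosome), each backbone amide peak
reports on its own residue: peaks near the interface move (chemical-shift
perturbation), broaden (exchange with a large or dynamic complex), or
disappear entirely. `titramap` turns a series of assigned peak lists —
free protein plus bound points at increasing ligand:protein molar ratios —
into per-residue interaction maps:

* **CSP tracks** — the compound perturbation
  Δδ = √(ΔδH² + (α_N·ΔδN)²), α_N = 0.14 by default;
* **intensity-ratio tracks** — I/I₀ with peaks broadened beyond detection
  reported as 0 and explicitly flagged, optional 3-residue smoothing;
* **binding patches** — contiguous runs of significant residues (CSP above
  a trimmed mean + 2·sd threshold, I/I₀ below a cutoff, or broadened out),
  with patch-set comparison across conditions;
* **peak-trajectory classification** — total-least-squares linearity test
  in the (δH, α_N·δN) plane separating two-state fast exchange (straight
  paths) from multi-site/multi-state behaviour (curved paths);
* **Cα secondary shifts** — δCα − random coil (Wishart 1995 reference),
  with helix (positive) / strand (negative) segment calls for
  binding-induced folding;
* **binding forward model and Kd fit** — exact single-site mass balance
  with ligand depletion, fast-exchange shift averaging, exchange (Rex)
  broadening, and a global-Kd least-squares fit of CSP curves;
* **synthetic titration generator** — complete datasets with planted
  patches, broadening, second-site curvature, induced secondary structure
  and a ground-truth answer key, so the whole pipeline is testable without
  any deposited spectra.

## Worked example

```python
from titramap import (SimConfig, generate_titration, compute_csp,
                      compute_intensity_ratio, detect_patches, answer_key_report)

series, truth = generate_titration(SimConfig(seed=7))     # 191 residues, 4 patches
free, top = series.free, series.points[-1]                # free vs 1:2 point
patches = detect_patches(compute_csp(free, top), compute_intensity_ratio(free, top))
for p in patches:
    print(p.start_index, p.end_index, p.track_names)
print(answer_key_report(truth, patches)["sensitivity"])
```

prints

```
15 17 ('csp', 'ratio')
25 28 ('csp', 'ratio')
113 117 ('csp', 'ratio')
164 170 ('csp', 'ratio')
1.0
```

— all four planted contact patches recovered at their exact boundaries
(sensitivity 1.0), each triggered by both the shift-perturbation and the
broadening track. The `examples/` directory has one short script per
capability (CSP mapping, patch detection, trajectory classification,
secondary structure, Kd fitting); each prints the numbers it computes and
what they mean.

A thin CLI mirrors the library:

```
titramap simulate --seed 7 -o sim/
titramap csp --free sim/free.list --bound sim/r2.list -o csp.tsv
titramap patches --csp csp.tsv -o patches.tsv
titramap run --config run.yaml
```

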