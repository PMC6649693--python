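# Methods

## Chemical-shift perturbation metric

The compound CSP is the Euclidean weighted form
Δδ = √(ΔδH² + (α_N·ΔδN)²) with α_N = 0.14 by default. The ¹⁵N weight maps
the roughly five-fold wider ¹⁵N dispersion onto the ¹H ppm scale; 0.14 is
the most widely used convention for backbone amides. α_N is a parameter of
`CspParams`, is recorded in every output track's `params`, and the same
value is reused by the trajectory classifier so that CSP magnitudes and
trajectory geometry live in the same metric space.

Smoothing (`smooth_track`) is a centered arithmetic mean over *residue
numbering*, not array position: gaps in the numbering and chain ends
truncate the window, and missing values are excluded from both numerator
and divisor. By default only intensity-ratio tracks are smoothed (window
3); CSP tracks are left raw. A residue that is itself missing but has
observed neighbours inside the window receives the neighbour mean, which
lets short assignment gaps be bridged for display and SSE calling while
the flag columns keep the provenance.

## Intensity ratios and missing data

I/I₀ uses peak heights. Three outcomes are distinguished and flagged
explicitly, never conflated with zero perturbation:

* `ok` — both peaks measured, ratio reported (may exceed 1);
* `broadened_out` — peak present free, absent bound: ratio 0. These
  residues always count as significant in patch calling;
* `invalid` — I₀ = 0; no division is attempted.

Raw ratios are the default. An optional normalisation divides by the
median ratio of a user-declared set of unaffected residues, for titrations
where inter-spectrum intensity scale is not comparable.

## Patch detection

A residue is significant if CSP > threshold, or I/I₀ < `ratio_cutoff`
(default 0.35), or it broadened out. Runs of significant residues merge
across gaps of at most `max_gap` (default 1) positions; runs shorter than
`min_len` (default 3, since interaction patches of interest span at least
3 residues) are discarded.

The default CSP threshold is **mean + 2·sd of the 10%-trimmed track**.
Trimming keeps a strong binding patch from inflating its own baseline.
The 2·sd gate (rather than 1·sd) is deliberate: the compound CSP of an
unperturbed residue under isotropic Gaussian shift noise is
Rayleigh-distributed, and a 1·sd gate on that distribution passes ~17% of
baseline residues — enough to assemble several spurious 3-runs per
190-residue protein at the merging defaults. At 2·sd the spurious-patch
rate drops below one per run while sensitivity is untouched, since genuine
contact CSPs sit 20–50× above the noise floor. Both the trim fraction and
the sd factor are configurable (`PatchParams`).

## Trajectory linearity

For each residue observed in ≥3 titration points, the points
(δH, α_N·δN) are fitted with a total-least-squares line (SVD of the
centered cloud); `max_deviation` is the largest perpendicular distance and
`path_length` the extent along the principal axis. The call is

* `insufficient` if fewer than 3 points are observed (a line always fits 2);
* otherwise `broadened_out` if the final titration point is missing
  (deviation statistics still computed from the remaining points);
* otherwise `nonlinear` if max_deviation > `dev_factor`·noise_sd **and**
  path_length > 4·noise_sd, else `linear`.

The path-length gate stops unperturbed residues — whose "trajectory" is a
noise blob with order-1 relative deviation — from being called nonlinear.
`dev_factor` defaults to 3. The classifier reports geometry only and never
assigns a mechanism: curvature is consistent with a weak second site,
intermediate exchange via an on-pathway state, or binding-coupled
rearrangement, and peak paths alone cannot distinguish these.

## Secondary chemical shifts

ΔδCα(i) = δCα_obs(i) − RC(aa_i) against the packaged random-coil Cα table
of Wishart et al. (1995), recorded by name in the output; any table can be
substituted via TSV. No nearest-neighbour sequence corrections are applied
by default. After smoothing (window 3), helices are runs of ≥4 consecutive
residues above +0.7 ppm and strands runs of ≥3 below −0.7 ppm — the
conventional consensus-shift heuristics; Cα alone (no Cβ/CO combination)
is used. The sign convention (positive = helix, negative = strand) is
asserted on every call object.

## Binding model

Populations come from the exact quadratic mass balance, not the L≫P
approximation: titrations at 0.5–2 equivalents over a 50 μM protein are
ligand-depleted, and the approximation misestimates f by tens of percent
there. The observed peak is the fast-exchange population average; peak
height decays as exp(−ΔR₂·t_relax) with

ΔR₂ = f·(R₂,bound − R₂,free) + f(1−f)·Δω²/k_ex (contact residues only),

Δω converted to rad/s at a declared ¹H field (default 800 MHz). A single
effective decay time t_relax (default 0.05 s) stands in for the
acquisition-weighted relaxation window; the Rex term is maximal at
half-saturation, which is why contact peaks can vanish mid-titration yet
reappear at the endpoint.

`fit_kd` fits Δδ(i, L) = Δδ_max(i)·f(P, L, Kd) with one global Kd. For
fixed Kd the Δδ_max values are closed-form (separable least squares), so
the search is one-dimensional in log₁₀Kd: a 200-point log-grid scan
followed by bounded local refinement, robust to the flat/multimodal SSE
these near-stoichiometric designs produce.

## Synthetic data: what it emulates, what it does not

Defaults mirror the titration design the package targets: a 191-residue
construct at 50 μM with ratios 0/0.5/1/2, four planted contact patches of
3–8 residues (mean saturation CSP 0.25 ppm, per-residue jitter ±30%),
Kd₁ = 5 μM, shift noise 0.003 ppm, intensity noise 10% cv, detection floor
0.05, ~4% prolines placed outside patches. Free-state shifts are drawn
from per-residue-type typical amide values with seeded jitter (±0.3 ppm
¹H, ±2 ppm ¹⁵N). Exchange defaults (k_ex = 10⁴ s⁻¹, R₂ 15→25 s⁻¹) put
contact residues in fast-to-intermediate exchange: visible broadening,
with occasional peaks lost below the floor at mid-titration where f(1−f)
peaks. Slower k_ex (~1.5·10³ s⁻¹) reproduces the regime where peaks stay
lost at the top point. Shift noise is isotropic in the *scaled* plane
(sd σ on ¹H, σ/α_N on ¹⁵N ppm), so the classifier's single `noise_sd`
parameter describes trajectory geometry exactly.

The second site (when `kd2` is set; 20× weaker by convention) binds the
same ligand pool non-cooperatively; its shift response (default 0.15 ppm)
points 0.9–1.6 rad away from the primary direction, guaranteeing
non-collinear two-site trajectories.

Not emulated: peak overlap and crowding, volume-vs-height discrepancies,
temperature/referencing drift between spectra, assignment errors, and
field-dependent noise. Passing recovery tests therefore demonstrates the
analysis logic under clean, well-separated peaks — not robustness to
crowded spectra, which in practice is handled at the assignment stage.

The generator writes the ground truth (patches, responses, Kd, broadened
residues, SSE segments) next to every dataset; recovery tests read the
answer key rather than re-deriving it. One seeded generator drives all
draws, so a (config, seed) pair reproduces datasets byte-exactly.

## Numerical choices and degenerate inputs

* `fraction_bound` clips the discriminant at 0 and the result into [0, 1]
  to absorb rounding at the stoichiometric corner; Kd = 0 returns the
  exact limit min(L/P, 1). Agreement with an independent bisection solver
  is 1e-10 over the tested parameter cube.
* All-coincident trajectory points return deviation 0 (linear), not NaN.
* An all-missing track yields zero patches with a warning, not an error;
  an empty peak list, a duplicated residue index, or a proline carrying
  amide shifts are hard errors.
* Result TSVs write values at full `repr` precision and round-trip
  bit-exactly; pipeline outputs are canonically sorted by residue index,
  so reruns are hash-identical.

## Problem sizes

Default analyses run on 191-residue single-domain-scale series with 4
titration points; the recovery statistics in the test suite and the
acceptance script use 20–25 seeded replicates of that design and 200-residue
trajectory panels, which complete in seconds and give stable medians.

## Known limitations

Slow-exchange (two-peak) titrations, Bloch–McConnell lineshape fitting,
cooperative or allosteric binding models, volume-based intensities and
per-residue error propagation from spectral noise are out of scope. The
Kd fit assumes every responsive residue shares one site; residues with
mixed-site responses bias it. Default relaxation/exchange parameters are
simulation conveniences, not estimates of any particular protein's
biophysics.
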