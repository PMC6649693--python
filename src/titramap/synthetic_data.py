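"""Synthetic titration datasets with a planted, machine-readable answer key.

The generator emulates the shape of a nucleosome-titration HSQC experiment
on a ~190-residue construct: a handful of contiguous binding patches whose
residues move in fast exchange toward their saturation shifts, exchange
broadening that can take peaks below the detection floor at high ligand
ratios, an optional weak second site that curves peak trajectories, induced
helix/strand segments in the Cα shifts, and Gaussian shift /
multiplicative intensity noise.  Every random draw comes from one seeded
generator, so a config + seed reproduces the dataset bit-exactly.

The ground truth (patch locations, per-residue saturation responses, Kd
values, broadened-out residues, SSE segments) is returned — and written —
alongside the peak lists so recovery tests never re-derive the answer.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .binding_model import BindingParams, ResidueResponse, fraction_bound, observed_peak
from .csp_core import DEFAULT_ALPHA_N
from .errors import ParameterError
from .peaklist_io import PeakList, ResidueAssignment, TitrationSeries
from .secondary_shifts import WISHART_1995_CA

#: typical backbone amide (¹H, ¹⁵N) shifts per residue type, ppm
AMIDE_SHIFT_TABLE = {
    "A": (8.20, 123.2), "C": (8.32, 119.0), "D": (8.34, 120.6),
    "E": (8.42, 120.7), "F": (8.30, 120.3), "G": (8.33, 109.5),
    "H": (8.42, 119.1), "I": (8.00, 121.5), "K": (8.29, 121.5),
    "L": (8.16, 121.8), "M": (8.28, 120.5), "N": (8.40, 118.9),
    "Q": (8.32, 119.8), "R": (8.27, 121.3), "S": (8.31, 116.3),
    "T": (8.24, 113.6), "V": (8.03, 120.5), "W": (8.25, 121.3),
    "Y": (8.12, 120.3),
}

_AA_POOL = "ACDEFGHIKLMNQRSTVWY"  # prolines placed separately


@dataclass
class SimConfig:
    """Design of a synthetic titration.

    ``patches`` are (start, end, mean Δδ_max) triples: contiguous contact
    patches whose residues reach the given mean compound CSP at saturation.
    ``kd2``/``second_site_ddmax`` switch on a weak second site whose shift
    response points in a different direction in the scaled shift plane,
    producing curved trajectories.  Concentration units are μM throughout.
    """

    seed: int = 0
    n_residues: int = 191
    sequence: str | None = None
    patches: tuple = ((15, 17, 0.25), (25, 28, 0.25), (113, 117, 0.25), (164, 170, 0.25))
    binding: BindingParams = field(default_factory=BindingParams)
    second_site_ddmax: float = 0.15
    helix_segment: tuple[int, int] | None = (164, 174)
    strand_segment: tuple[int, int] | None = (113, 117)
    helix_amp: float = 2.5
    strand_amp: float = -2.0
    noise_shift_sd: float = 0.003
    noise_intensity_cv: float = 0.10
    noise_ca_sd: float = 0.05
    detection_floor: float = 0.05
    alpha_n: float = DEFAULT_ALPHA_N
    proline_fraction: float = 0.04

    def __post_init__(self) -> None:
        if not (0 < self.detection_floor < 1):
            raise ParameterError("detection_floor must lie in (0, 1)")
        if self.noise_shift_sd < 0 or self.noise_intensity_cv < 0 or self.noise_ca_sd < 0:
            raise ParameterError("noise parameters must be >= 0")
        n = len(self.sequence) if self.sequence else self.n_residues
        for start, end, dd in self.patches:
            if not (1 <= start <= end <= n):
                raise ParameterError(f"patch ({start}, {end}) outside sequence of length {n}")
            if dd <= 0:
                raise ParameterError("patch mean Δδ_max must be positive")


@dataclass
class SyntheticGroundTruth:
    """The answer key of one generated dataset."""

    seed: int
    sequence: str
    patches: tuple
    kd1: float
    kd2: float | None
    contact_residues: set[int]
    helix_segment: tuple[int, int] | None
    strand_segment: tuple[int, int] | None
    noise_shift_sd: float
    noise_intensity_cv: float
    broadened_out: set[int]
    responses: dict[int, ResidueResponse]


def _make_sequence(config: SimConfig, rng: np.random.Generator) -> str:
    if config.sequence:
        return config.sequence.upper()
    patch_residues = {
        i for start, end, _ in config.patches for i in range(start, end + 1)
    }
    seq = [str(_AA_POOL[k]) for k in rng.integers(0, len(_AA_POOL), config.n_residues)]
    # sprinkle prolines outside patches (no amide proton -> holes in tracks)
    n_pro = int(round(config.proline_fraction * config.n_residues))
    candidates = [i for i in range(1, config.n_residues + 1) if i not in patch_residues]
    for i in rng.choice(candidates, size=min(n_pro, len(candidates)), replace=False):
        seq[int(i) - 1] = "P"
    return "".join(seq)


def _make_responses(
    config: SimConfig, sequence: str, rng: np.random.Generator
) -> dict[int, ResidueResponse]:
    responses: dict[int, ResidueResponse] = {}
    two_site = config.binding.kd2 is not None
    for start, end, mean_dd in config.patches:
        for idx in range(start, end + 1):
            if sequence[idx - 1] == "P":
                continue
            csp_sat = mean_dd * rng.uniform(0.7, 1.3)
            theta = rng.uniform(0.15, 1.42)  # direction in the scaled shift plane
            ddh = csp_sat * math.cos(theta)
            ddn = csp_sat * math.sin(theta) / config.alpha_n
            ddh2 = ddn2 = 0.0
            if two_site:
                c2 = config.second_site_ddmax * rng.uniform(0.7, 1.3)
                theta2 = theta + rng.uniform(0.9, 1.6)  # guaranteed non-parallel
                ddh2 = c2 * math.cos(theta2)
                ddn2 = c2 * math.sin(theta2) / config.alpha_n
            responses[idx] = ResidueResponse(
                residue_index=idx, ddh=ddh, ddn=ddn, ddh2=ddh2, ddn2=ddn2, contact=True
            )
    return responses


def generate_titration(config: SimConfig) -> tuple[TitrationSeries, SyntheticGroundTruth]:
    """Generate a full titration series plus its ground truth.

    Free-state shifts are drawn from per-residue-type typical values with
    seeded jitter; each titration point applies the fast-exchange forward
    model, then shift noise (sd ``noise_shift_sd`` on ¹H and
    ``noise_shift_sd``/α_N on ¹⁵N, i.e. isotropic in the scaled plane) and
    multiplicative intensity noise.  Peaks whose noiseless relative
    intensity falls below ``detection_floor`` are dropped from that peak
    list and recorded as broadened out.  Prolines never appear in amide
    peak lists.
    """
    rng = np.random.default_rng(config.seed)
    sequence = _make_sequence(config, rng)
    responses = _make_responses(config, sequence, rng)
    bp = config.binding

    free_shifts: dict[int, tuple[float, float]] = {}
    for idx, aa in enumerate(sequence, start=1):
        if aa == "P":
            continue
        h0, n0 = AMIDE_SHIFT_TABLE[aa]
        free_shifts[idx] = (
            h0 + rng.uniform(-0.3, 0.3),
            n0 + rng.uniform(-2.0, 2.0),
        )

    null_response = {
        idx: ResidueResponse(residue_index=idx) for idx in free_shifts if idx not in responses
    }
    broadened: set[int] = set()
    points: list[PeakList] = []
    for ratio in bp.ratios:
        l_total = ratio * bp.p_total
        f1 = fraction_bound(bp.p_total, l_total, bp.kd1)
        f2 = fraction_bound(bp.p_total, l_total, bp.kd2) if bp.kd2 is not None else 0.0
        entries = []
        for idx in sorted(free_shifts):
            resp = responses.get(idx) or null_response[idx]
            h0, n0 = free_shifts[idx]
            h, n, rel = observed_peak(resp, f1, h0, n0, bp, f2=f2)
            if ratio > 0 and rel < config.detection_floor:
                broadened.add(idx)
                continue
            if config.noise_shift_sd > 0:
                h += rng.normal(0.0, config.noise_shift_sd)
                n += rng.normal(0.0, config.noise_shift_sd / config.alpha_n)
            intensity = rel
            if config.noise_intensity_cv > 0:
                intensity = max(rel * (1.0 + rng.normal(0.0, config.noise_intensity_cv)), 1e-12)
            entries.append(
                ResidueAssignment(
                    residue_index=idx,
                    residue_code=sequence[idx - 1],
                    shift_h=h,
                    shift_n=n,
                    intensity=intensity,
                )
            )
        label = "free" if ratio == 0 else f"1:{ratio:g}"
        points.append(PeakList(label=label, molar_ratio=ratio, entries=entries))

    series = TitrationSeries(sequence=sequence, points=points)
    gt = SyntheticGroundTruth(
        seed=config.seed,
        sequence=sequence,
        patches=config.patches,
        kd1=bp.kd1,
        kd2=bp.kd2,
        contact_residues=set(responses),
        helix_segment=config.helix_segment,
        strand_segment=config.strand_segment,
        noise_shift_sd=config.noise_shift_sd,
        noise_intensity_cv=config.noise_intensity_cv,
        broadened_out=broadened,
        responses=responses,
    )
    return series, gt


def generate_ca_shifts(config: SimConfig, sequence: str | None = None) -> PeakList:
    """Synthetic bound-state Cα shift table with planted helix/strand segments.

    Each residue's Cα is its random-coil value plus the planted secondary
    shift (``helix_amp`` inside the helix segment, ``strand_amp`` inside the
    strand segment) plus Gaussian noise.  Uses a seed offset from the main
    dataset's so shift tables and peak lists stay independently reproducible.
    """
    rng = np.random.default_rng(config.seed + 104729)
    if sequence is None:
        sequence = _make_sequence(config, np.random.default_rng(config.seed))
    entries = []
    for idx, aa in enumerate(sequence, start=1):
        ca = WISHART_1995_CA[aa]
        if config.helix_segment and config.helix_segment[0] <= idx <= config.helix_segment[1]:
            ca += config.helix_amp
        elif config.strand_segment and config.strand_segment[0] <= idx <= config.strand_segment[1]:
            ca += config.strand_amp
        if config.noise_ca_sd > 0:
            ca += rng.normal(0.0, config.noise_ca_sd)
        entries.append(ResidueAssignment(residue_index=idx, residue_code=aa, shift_ca=ca))
    return PeakList(label="bound_ca", molar_ratio=0.0, entries=entries)


# ---------------------------------------------------------------------------
# recovery scoring

def jaccard(a: set[int], b: set[int]) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0


def answer_key_report(
    gt: SyntheticGroundTruth,
    detected,
    sse=None,
    broadened_detected: set[int] | None = None,
    jaccard_threshold: float = 0.6,
) -> dict:
    """Score detected patches (and optional SSE calls) against the answer key.

    A planted patch counts as recovered when its best-matching detected
    patch reaches the Jaccard threshold; a detected patch with zero overlap
    with every planted patch is spurious.  SSE segments count as recovered
    when a call of the right type covers at least half the planted segment.
    """
    planted = [set(range(s, e + 1)) for s, e, _ in gt.patches]
    det_sets = [p.residues for p in detected]
    per_patch = [
        max((jaccard(pl, d) for d in det_sets), default=0.0) for pl in planted
    ]
    recovered = sum(1 for j in per_patch if j >= jaccard_threshold)
    spurious = sum(1 for d in det_sets if all(not (d & pl) for pl in planted))
    matched_det = sum(1 for d in det_sets if any(d & pl for pl in planted))
    report = {
        "per_patch_jaccard": per_patch,
        "sensitivity": recovered / len(planted) if planted else 1.0,
        "precision": matched_det / len(det_sets) if det_sets else 1.0,
        "n_detected": len(det_sets),
        "n_spurious": spurious,
    }
    if broadened_detected is not None and gt.broadened_out:
        report["broadened_recall"] = len(broadened_detected & gt.broadened_out) / len(
            gt.broadened_out
        )
    if sse is not None:
        seg_report = {}
        for name, seg, sse_type in (
            ("helix", gt.helix_segment, "helix"),
            ("strand", gt.strand_segment, "strand"),
        ):
            if seg is None:
                continue
            seg_set = set(range(seg[0], seg[1] + 1))
            hit = any(
                c.sse_type == sse_type
                and len(set(range(c.start_index, c.end_index + 1)) & seg_set)
                >= 0.5 * len(seg_set)
                for c in sse
            )
            seg_report[name] = hit
        report["sse_recovered"] = seg_report
    return report


# ---------------------------------------------------------------------------
# dataset writing

def _format_float(x: float) -> str:
    return repr(float(x))


def write_sparky(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list in the Sparky dialect (w1 = ¹⁵N, w2 = ¹H)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Assignment  w1  w2  Data Height\n")
        for e in peaklist.entries:
            if not e.has_amide:
                continue
            inten = "" if e.intensity is None else f"  {_format_float(e.intensity)}"
            fh.write(
                f"{e.residue_code}{e.residue_index}N-H  "
                f"{_format_float(e.shift_n)}  {_format_float(e.shift_h)}{inten}\n"
            )


def write_dataset(
    series: TitrationSeries,
    gt: SyntheticGroundTruth,
    outdir: str | Path,
    ca_shifts: PeakList | None = None,
) -> Path:
    """Write peak lists, ground truth and a series manifest to ``outdir``.

    Produces one Sparky ``.list`` per titration point, ``ground_truth.tsv``,
    ``sequence.fasta`` and a ``series.yaml`` manifest the pipeline can load.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"sequence_fasta": "sequence.fasta", "points": []}
    with open(outdir / "sequence.fasta", "w") as fh:
        fh.write(">synthetic\n")
        for k in range(0, len(gt.sequence), 60):
            fh.write(gt.sequence[k : k + 60] + "\n")
    for p in series.points:
        fname = "free.list" if p.molar_ratio == 0 else f"r{p.molar_ratio:g}.list"
        write_sparky(p, outdir / fname)
        manifest["points"].append(
            {"label": p.label, "ratio": float(p.molar_ratio), "path": fname, "format": "sparky"}
        )
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("field\tvalue\n")
        fh.write(f"seed\t{gt.seed}\n")
        fh.write(f"kd1\t{_format_float(gt.kd1)}\n")
        fh.write(f"kd2\t{'' if gt.kd2 is None else _format_float(gt.kd2)}\n")
        fh.write(f"noise_shift_sd\t{_format_float(gt.noise_shift_sd)}\n")
        fh.write(f"noise_intensity_cv\t{_format_float(gt.noise_intensity_cv)}\n")
        for s, e, dd in gt.patches:
            fh.write(f"patch\t{s}-{e}:{_format_float(dd)}\n")
        fh.write(f"contact_residues\t{','.join(map(str, sorted(gt.contact_residues)))}\n")
        fh.write(f"broadened_out\t{','.join(map(str, sorted(gt.broadened_out)))}\n")
        if gt.helix_segment:
            fh.write(f"helix_segment\t{gt.helix_segment[0]}-{gt.helix_segment[1]}\n")
        if gt.strand_segment:
            fh.write(f"strand_segment\t{gt.strand_segment[0]}-{gt.strand_segment[1]}\n")
    if ca_shifts is not None:
        with open(outdir / "ca_shifts.tsv", "w") as fh:
            fh.write("residue_index\tresidue_code\tshift_h_ppm\tshift_n_ppm\tintensity\tshift_ca_ppm\n")
            for e in ca_shifts.entries:
                fh.write(
                    f"{e.residue_index}\t{e.residue_code}\t\t\t\t{_format_float(e.shift_ca)}\n"
                )
        manifest["ca_shifts"] = "ca_shifts.tsv"
    manifest_path = outdir / "series.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
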