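"""Contiguous binding-patch detection on CSP / intensity-ratio tracks.

A residue is called significant when its CSP exceeds a threshold, its
I/I₀ falls below a cutoff, or its peak broadened beyond detection.  Runs
of significant residues (merging across gaps of at most ``max_gap``
non-significant or unobserved positions) of length at least ``min_len``
become binding patches.  The default CSP threshold is mean + 1·sd computed
on the 10%-trimmed track, which keeps a strong binding patch from inflating
its own baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import trimboth

from .csp_core import PerResidueProfile
from .errors import ParameterError
from .peaklist_io import FLAG_BROADENED

import logging

logger = logging.getLogger(__name__)


@dataclass
class PatchParams:
    """Thresholding and run-merging parameters for patch calling."""

    csp_threshold_mode: str = "mean_plus_sd"
    csp_fixed_cutoff: float | None = None
    ratio_cutoff: float | None = 0.35
    min_len: int = 3
    max_gap: int = 1
    trim_fraction: float = 0.10
    sd_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.csp_threshold_mode not in ("mean_plus_sd", "fixed"):
            raise ParameterError(f"unknown threshold mode {self.csp_threshold_mode!r}")
        if self.csp_threshold_mode == "fixed" and (
            self.csp_fixed_cutoff is None or self.csp_fixed_cutoff <= 0
        ):
            raise ParameterError("fixed mode needs a positive csp_fixed_cutoff")
        if self.ratio_cutoff is not None and self.ratio_cutoff <= 0:
            raise ParameterError("ratio_cutoff must be positive")
        if self.min_len < 1 or self.max_gap < 0:
            raise ParameterError("need min_len >= 1 and max_gap >= 0")
        if not (0 <= self.trim_fraction < 0.5):
            raise ParameterError("trim_fraction must be in [0, 0.5)")


@dataclass
class BindingPatch:
    """A contiguous run of significant residues (inclusive index range)."""

    start_index: int
    end_index: int
    track_names: tuple[str, ...] = ()
    peak_value: float = float("nan")
    mean_value: float = float("nan")
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ParameterError("patch start must be <= end")

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def residues(self) -> set[int]:
        return set(range(self.start_index, self.end_index + 1))


def csp_significance_threshold(csp: PerResidueProfile, params: PatchParams) -> float:
    """The CSP cutoff implied by ``params`` on this track."""
    if params.csp_threshold_mode == "fixed":
        return float(params.csp_fixed_cutoff)
    vals = csp.values[csp.present]
    if vals.size == 0:
        return float("inf")
    trimmed = trimboth(np.sort(vals), params.trim_fraction)
    if trimmed.size == 0:
        trimmed = vals
    return float(np.mean(trimmed) + params.sd_factor * np.std(trimmed))


def detect_patches(
    csp: PerResidueProfile,
    ratio: PerResidueProfile | None = None,
    params: PatchParams | None = None,
) -> list[BindingPatch]:
    """Call binding patches from a CSP track and an optional I/I₀ track.

    Tracks are aligned on residue index.  Broadened-out residues (flag set
    by :func:`titramap.csp_core.compute_intensity_ratio`) always count as
    significant.  Returns patches sorted by start index; an all-missing
    input yields an empty list with a warning rather than an error.
    """
    params = params or PatchParams()

    sig_by_index: dict[int, set[str]] = {}
    if np.any(csp.present):
        thr = csp_significance_threshold(csp, params)
        for idx, v, present in zip(csp.residue_index, csp.values, csp.present):
            if present and v > thr:
                sig_by_index.setdefault(int(idx), set()).add("csp")

    if ratio is not None:
        for idx, v, present, flag in zip(
            ratio.residue_index, ratio.values, ratio.present, ratio.flags
        ):
            if flag == FLAG_BROADENED:
                sig_by_index.setdefault(int(idx), set()).add("broadened_out")
            elif present and params.ratio_cutoff is not None and v < params.ratio_cutoff:
                sig_by_index.setdefault(int(idx), set()).add("ratio")

    if not np.any(csp.present) and (ratio is None or not np.any(ratio.present)):
        logger.warning("all track values missing; no patches can be called")
        return []

    if not sig_by_index:
        return []

    # merge runs of significant residues across gaps <= max_gap
    sig_sorted = sorted(sig_by_index)
    runs: list[list[int]] = [[sig_sorted[0]]]
    for idx in sig_sorted[1:]:
        if idx - runs[-1][-1] - 1 <= params.max_gap:
            runs[-1].append(idx)
        else:
            runs.append([idx])

    csp_at = {int(i): (float(v), bool(p)) for i, v, p in zip(csp.residue_index, csp.values, csp.present)}
    broadened = (
        {int(i) for i, fl in zip(ratio.residue_index, ratio.flags) if fl == FLAG_BROADENED}
        if ratio is not None
        else set()
    )

    patches: list[BindingPatch] = []
    for run in runs:
        start, end = run[0], run[-1]
        if end - start + 1 < params.min_len:
            continue
        tracks: set[str] = set()
        for idx in run:
            tracks |= sig_by_index[idx]
        inside = range(start, end + 1)
        csp_vals = [csp_at[i][0] for i in inside if i in csp_at and csp_at[i][1]]
        patches.append(
            BindingPatch(
                start_index=start,
                end_index=end,
                track_names=tuple(sorted(tracks)),
                peak_value=float(np.max(csp_vals)) if csp_vals else float("nan"),
                mean_value=float(np.mean(csp_vals)) if csp_vals else float("nan"),
                n_missing=sum(1 for i in inside if i in broadened),
            )
        )
    return patches


@dataclass
class PatchOverlap:
    """One row of a patch-set comparison."""

    category: str  # shared | a_only | b_only
    patch_a: BindingPatch | None
    patch_b: BindingPatch | None
    n_overlap: int


def compare_patch_sets(a: list[BindingPatch], b: list[BindingPatch]) -> list[PatchOverlap]:
    """Classify patches of two conditions as shared, a-only or b-only.

    Any residue-level overlap makes a pair shared; each shared pair reports
    its overlap size.  Mirrors comparing e.g. modified vs unmodified ligand:
    a patch present only under one condition marks a condition-dependent
    interaction.
    """
    report: list[PatchOverlap] = []
    matched_b: set[int] = set()
    for pa in a:
        hits = [
            (k, len(pa.residues & pb.residues))
            for k, pb in enumerate(b)
            if pa.residues & pb.residues
        ]
        if hits:
            for k, n in hits:
                matched_b.add(k)
                report.append(PatchOverlap("shared", pa, b[k], n))
        else:
            report.append(PatchOverlap("a_only", pa, None, 0))
    for k, pb in enumerate(b):
        if k not in matched_b:
            report.append(PatchOverlap("b_only", None, pb, 0))
    return report
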