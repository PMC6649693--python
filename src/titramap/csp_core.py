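"""Weighted chemical-shift perturbations, intensity ratios and smoothing.

The combined amide CSP between the free and ligand-bound spectrum of
residue *i* is the Euclidean weighted form

    Δδ(i) = sqrt( ΔδH(i)² + (α_N · ΔδN(i))² )

with the conventional ¹⁵N scaling factor α_N = 0.14 by default, chosen to
map the ~5× wider ¹⁵N dispersion onto the ¹H scale.  Intensity ratios are
I/I₀ (bound over free peak height); a peak present free but broadened
beyond detection in the bound spectrum is reported as ratio 0 with the
``broadened_out`` flag — explicitly distinguishable from an unperturbed
residue.  Sliding-window smoothing is a centered arithmetic mean over
*residue numbering* (gaps in the numbering truncate the window, as do chain
ends and missing values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError
from .peaklist_io import (
    FLAG_BROADENED,
    FLAG_INVALID,
    FLAG_MISSING,
    FLAG_OK,
    PeakList,
)

#: default ¹⁵N weight in the compound shift metric
DEFAULT_ALPHA_N = 0.14


@dataclass
class CspParams:
    """Parameters of the compound-CSP metric and optional smoothing."""

    alpha_n: float = DEFAULT_ALPHA_N
    window: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.alpha_n <= 1):
            raise ParameterError(f"alpha_n must be in (0, 1], got {self.alpha_n}")
        if self.window < 1 or self.window % 2 == 0:
            raise ParameterError(f"window must be odd and >= 1, got {self.window}")


@dataclass
class PerResidueProfile:
    """A named per-residue numeric track with an explicit missing-data mask.

    ``values`` are ppm for CSP / secondary-shift tracks and dimensionless
    for I/I₀.  ``flags`` refine the mask (``ok``, ``missing``,
    ``broadened_out``, ``invalid``); ``params`` records every parameter that
    produced the track so results are self-describing.
    """

    name: str
    residue_index: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    flags: list[str] = field(default_factory=list)
    codes: list[str] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.residue_index)
        if not (len(self.values) == len(self.missing_mask) == n):
            raise InputError("profile arrays must have equal length")
        if not self.flags:
            self.flags = [FLAG_MISSING if m else FLAG_OK for m in self.missing_mask]
        if len(self.flags) != n:
            raise InputError("flags length mismatch")
        if np.any(~np.isfinite(self.values[~self.missing_mask])):
            raise InputError(f"track {self.name!r} has non-finite values outside the mask")

    def __len__(self) -> int:
        return len(self.residue_index)

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of residues carrying a usable value."""
        return ~self.missing_mask

    def value_at(self, index: int) -> float | None:
        pos = np.flatnonzero(self.residue_index == index)
        if pos.size == 0 or self.missing_mask[pos[0]]:
            return None
        return float(self.values[pos[0]])


def compound_shift_distance(dh: float, dn: float, alpha_n: float = DEFAULT_ALPHA_N) -> float:
    """Weighted Euclidean distance in the (¹H, α_N·¹⁵N) shift plane."""
    return math.hypot(dh, alpha_n * dn)


def compute_csp(free: PeakList, bound: PeakList, params: CspParams | None = None) -> PerResidueProfile:
    """Per-residue weighted CSP between a free and a bound peak list.

    Residues present in only one list (or lacking amide shifts) are flagged
    missing.  Raises :class:`InputError` when the lists share no residue.
    """
    params = params or CspParams()
    f_by = free.by_index()
    b_by = bound.by_index()
    indices = sorted(set(f_by) | set(b_by))
    if not set(f_by) & set(b_by):
        raise InputError("free and bound peak lists share no residue index")
    values, missing, flags, codes = [], [], [], []
    for idx in indices:
        fe, be = f_by.get(idx), b_by.get(idx)
        codes.append((fe or be).residue_code)
        if fe is not None and be is not None and fe.has_amide and be.has_amide:
            values.append(
                compound_shift_distance(
                    be.shift_h - fe.shift_h, be.shift_n - fe.shift_n, params.alpha_n
                )
            )
            missing.append(False)
            flags.append(FLAG_OK)
        else:
            values.append(math.nan)
            missing.append(True)
            flags.append(FLAG_MISSING)
    return PerResidueProfile(
        name=f"csp[{free.label}->{bound.label}]",
        residue_index=indices,
        values=values,
        missing_mask=missing,
        flags=flags,
        codes=codes,
        params={"alpha_n": params.alpha_n, "free": free.label, "bound": bound.label},
    )


def compute_intensity_ratio(
    free: PeakList,
    bound: PeakList,
    normalize_to: set[int] | None = None,
) -> PerResidueProfile:
    """Per-residue I/I₀ between a free and a bound peak list.

    A residue present in the free list but absent from the bound list is
    reported as ratio 0 flagged ``broadened_out``.  A residue with I₀ = 0 is
    flagged ``invalid`` rather than divided.  ``normalize_to`` optionally
    names unaffected residues; ratios are then divided by the median ratio
    of that set to compensate inter-spectrum intensity scale.
    """
    f_by = free.by_index()
    b_by = bound.by_index()
    indices = sorted(f_by)
    values, missing, flags, codes = [], [], [], []
    any_ratio = False
    for idx in indices:
        fe = f_by[idx]
        be = b_by.get(idx)
        codes.append(fe.residue_code)
        if fe.intensity is None or not fe.has_amide:
            values.append(math.nan)
            missing.append(True)
            flags.append(FLAG_MISSING)
        elif fe.intensity == 0:
            values.append(math.nan)
            missing.append(True)
            flags.append(FLAG_INVALID)
        elif be is None or not be.has_amide:
            # peak broadened beyond detection in the bound spectrum
            values.append(0.0)
            missing.append(False)
            flags.append(FLAG_BROADENED)
        elif be.intensity is None:
            values.append(math.nan)
            missing.append(True)
            flags.append(FLAG_MISSING)
        else:
            values.append(be.intensity / fe.intensity)
            missing.append(False)
            flags.append(FLAG_OK)
            any_ratio = True
    if not any_ratio:
        raise InputError("no residue has intensities in both peak lists")
    profile = PerResidueProfile(
        name=f"ratio[{free.label}->{bound.label}]",
        residue_index=indices,
        values=values,
        missing_mask=missing,
        flags=flags,
        codes=codes,
        params={"free": free.label, "bound": bound.label, "normalized": False},
    )
    if normalize_to:
        ok = [
            v
            for i, v, fl in zip(profile.residue_index, profile.values, profile.flags)
            if int(i) in normalize_to and fl == FLAG_OK
        ]
        if not ok:
            raise InputError("none of the normalization residues has a valid ratio")
        scale = float(np.median(ok))
        if scale <= 0:
            raise InputError("normalization median is not positive")
        profile.values = profile.values / scale
        profile.params.update({"normalized": True, "normalization_median": scale})
    return profile


def smooth_track(track: PerResidueProfile, window: int) -> PerResidueProfile:
    """Centered moving average over residue numbering.

    The window spans residue indices ``i-h .. i+h`` (h = window//2); indices
    absent from the track or flagged missing simply do not contribute, so
    numbering gaps and chain ends use the truncated window.  ``window=1`` is
    the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window == 1:
        return track
    h = window // 2
    pos = {int(i): k for k, i in enumerate(track.residue_index)}
    values = np.array(track.values, dtype=float)
    out = np.full(len(track), np.nan)
    out_missing = np.array(track.missing_mask, dtype=bool).copy()
    for k, idx in enumerate(track.residue_index):
        neigh = [
            values[pos[j]]
            for j in range(int(idx) - h, int(idx) + h + 1)
            if j in pos and not track.missing_mask[pos[j]]
        ]
        if neigh:
            out[k] = float(np.mean(neigh))
            out_missing[k] = False
    flags = [
        FLAG_MISSING if m else (track.flags[k] if not track.missing_mask[k] else FLAG_OK)
        for k, m in enumerate(out_missing)
    ]
    return PerResidueProfile(
        name=track.name,
        residue_index=track.residue_index.copy(),
        values=out,
        missing_mask=out_missing,
        flags=flags,
        codes=list(track.codes) if track.codes is not None else None,
        params={**track.params, "smoothing_window": window},
    )
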