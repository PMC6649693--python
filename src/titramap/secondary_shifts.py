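"""Cα secondary chemical shifts and induced secondary-structure calls.

The secondary shift of residue *i* is the measured Cα shift minus the
random-coil value for its amino-acid type,

    ΔδCα(i) = δCα_obs(i) − δCα_RC(aa_i).

Cα nuclei in α-helices resonate downfield of random coil (positive
secondary shift) and in β-strands upfield (negative), so runs of
consistently positive / negative smoothed secondary shifts mark helices
and strands.  The packaged reference is the random-coil Cα set of Wishart
et al. (1995, J. Biomol. NMR 5, 67–81); no nearest-neighbour corrections
are applied by default, but any table can be supplied as TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .csp_core import PerResidueProfile, smooth_track
from .errors import InputError, ParameterError
from .peaklist_io import FLAG_MISSING, FLAG_OK, PeakList

#: Wishart et al. (1995) random-coil Cα shifts, ppm (DSS-referenced)
WISHART_1995_CA = {
    "A": 52.5, "C": 58.2, "D": 54.2, "E": 56.6, "F": 57.7,
    "G": 45.1, "H": 55.0, "I": 61.1, "K": 56.2, "L": 55.1,
    "M": 55.4, "N": 52.8, "P": 63.3, "Q": 56.2, "R": 56.0,
    "S": 58.3, "T": 61.8, "V": 62.2, "W": 57.5, "Y": 57.9,
}


@dataclass
class RandomCoilTable:
    """Per-amino-acid random-coil Cα reference shifts."""

    name: str = "wishart1995"
    ca: dict[str, float] = field(default_factory=lambda: dict(WISHART_1995_CA))

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.ca)
        if missing:
            raise InputError(f"random-coil table lacks entries for {sorted(missing)}")
        for aa, v in self.ca.items():
            if not (40.0 <= v <= 70.0):
                raise InputError(f"random-coil Cα for {aa} out of range: {v} ppm")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "RandomCoilTable":
        """Load an override table: two TSV columns residue_code, ca_ppm."""
        path = Path(path)
        table: dict[str, float] = {}
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith(("#", "residue_code")):
                continue
            code, val = line.split("\t")[:2]
            table[code.strip().upper()] = float(val)
        return cls(name=name or path.stem, ca=table)


@dataclass
class SecondaryStructureCall:
    """One called secondary-structure element (inclusive residue range)."""

    start_index: int
    end_index: int
    sse_type: str  # helix | strand
    mean_secondary_shift: float

    def __post_init__(self) -> None:
        length = self.end_index - self.start_index + 1
        if self.sse_type == "helix":
            if length < 4 or self.mean_secondary_shift <= 0:
                raise InputError("helix calls need length >= 4 and positive mean shift")
        elif self.sse_type == "strand":
            if length < 3 or self.mean_secondary_shift >= 0:
                raise InputError("strand calls need length >= 3 and negative mean shift")
        else:
            raise InputError(f"unknown SSE type {self.sse_type!r}")


def secondary_shift_track(
    ca_shifts: PeakList,
    sequence: str,
    rc: RandomCoilTable | None = None,
) -> PerResidueProfile:
    """ΔδCα track: measured Cα minus random-coil reference, per residue.

    Residues without a Cα shift are flagged missing; a residue code absent
    from the table raises an error naming the code.
    """
    rc = rc or RandomCoilTable()
    sequence = sequence.upper()
    any_ca = False
    indices, values, missing, flags, codes = [], [], [], [], []
    for e in ca_shifts.entries:
        if e.residue_index > len(sequence):
            raise InputError(
                f"residue {e.residue_index} beyond sequence length {len(sequence)}"
            )
        code = sequence[e.residue_index - 1]
        if code not in rc.ca:
            raise InputError(f"residue code {code!r} not in random-coil table {rc.name!r}")
        indices.append(e.residue_index)
        codes.append(code)
        if e.shift_ca is None:
            values.append(math.nan)
            missing.append(True)
            flags.append(FLAG_MISSING)
        else:
            values.append(e.shift_ca - rc.ca[code])
            missing.append(False)
            flags.append(FLAG_OK)
            any_ca = True
    if not any_ca:
        raise InputError("no residue carries a Cα shift")
    return PerResidueProfile(
        name="secondary_shift_ca",
        residue_index=indices,
        values=values,
        missing_mask=missing,
        flags=flags,
        codes=codes,
        params={"rc_table": rc.name},
    )


def call_sse(
    track: PerResidueProfile,
    helix_cut: float = 0.7,
    strand_cut: float = -0.7,
    smooth_window: int = 3,
    min_helix: int = 4,
    min_strand: int = 3,
) -> list[SecondaryStructureCall]:
    """Call helix/strand segments from a smoothed Cα secondary-shift track.

    Helices are runs of >= ``min_helix`` consecutive residues with smoothed
    ΔδCα above ``helix_cut``; strands runs of >= ``min_strand`` below
    ``strand_cut`` (positive = helix, negative = strand).  Runs must be
    consecutive in residue numbering; calls come back sorted and
    non-overlapping.
    """
    if not (helix_cut > 0 > strand_cut):
        raise ParameterError("need helix_cut > 0 > strand_cut")
    smoothed = smooth_track(track, smooth_window)
    calls: list[SecondaryStructureCall] = []
    raw_by_index = {
        int(i): float(v)
        for i, v, p in zip(smoothed.residue_index, smoothed.values, smoothed.present)
        if p
    }
    for sse_type, min_len, test in (
        ("helix", min_helix, lambda v: v > helix_cut),
        ("strand", min_strand, lambda v: v < strand_cut),
    ):
        run: list[int] = []
        for idx in sorted(raw_by_index) + [None]:  # sentinel flushes last run
            ok = idx is not None and test(raw_by_index[idx])
            contiguous = bool(run) and idx is not None and idx == run[-1] + 1
            if ok and (not run or contiguous):
                run.append(idx)
                continue
            if len(run) >= min_len:
                calls.append(
                    SecondaryStructureCall(
                        start_index=run[0],
                        end_index=run[-1],
                        sse_type=sse_type,
                        mean_secondary_shift=float(
                            np.mean([raw_by_index[i] for i in run])
                        ),
                    )
                )
            run = [idx] if ok else []
    calls.sort(key=lambda c: c.start_index)
    return calls
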