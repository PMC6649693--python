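"""Reading and writing assigned peak lists, shift tables and result tracks.

Supported formats
-----------------
* Sparky-style ``.list`` files: whitespace-delimited rows whose first token
  is an assignment label ``<Res1Letter><Index><AtomN>-<AtomH>`` (e.g.
  ``K113N-H``), followed by the w1 (¹⁵N) and w2 (¹H) shifts in ppm and an
  optional intensity column.
* Plain TSV with header ``residue_index  residue_code  shift_h_ppm
  shift_n_ppm  intensity [shift_ca_ppm]``.
* NMR-STAR v3 chemical-shift loops (read-only; H/N/CA atoms are mapped onto
  the amide/Cα fields).
* FASTA for the protein sequence (via Biopython).
* Per-residue result tracks as TSV (bit-exact round trip).

Residue numbering is 1-based author numbering taken from the assignment
label, never from row order.  Missing data stays explicit: a residue whose
amide peak broadened beyond detection is absent from the peak list, which
downstream code must distinguish from an unperturbed residue.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqUtils import seq1

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

#: flag values used in per-residue track files
FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_BROADENED = "broadened_out"
FLAG_INVALID = "invalid"


def _is_present(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


@dataclass
class ResidueAssignment:
    """One residue's assigned shifts and peak intensity in one spectrum.

    ``shift_h``/``shift_n`` are the backbone amide ¹H/¹⁵N shifts in ppm;
    ``shift_ca`` the ¹³Cα shift.  Any of them (and the intensity) may be
    ``None`` for missing.  Prolines carry no amide proton, so their
    ``shift_h``/``shift_n`` must be missing.
    """

    residue_index: int
    residue_code: str
    shift_h: float | None = None
    shift_n: float | None = None
    intensity: float | None = None
    shift_ca: float | None = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise InputError(
                f"residue_index must be a positive integer, got {self.residue_index}"
            )
        self.residue_code = str(self.residue_code).upper()
        if self.residue_code not in _AA1:
            raise InputError(f"unknown one-letter residue code {self.residue_code!r}")
        for name in ("shift_h", "shift_n", "shift_ca", "intensity"):
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if math.isnan(v):
                    v = None
                elif not math.isfinite(v):
                    raise InputError(f"{name} for residue {self.residue_index} is not finite")
                setattr(self, name, v)
        if self.intensity is not None and self.intensity < 0:
            raise InputError(f"negative intensity for residue {self.residue_index}")
        if self.residue_code == "P" and (
            _is_present(self.shift_h) or _is_present(self.shift_n)
        ):
            raise InputError(
                f"proline {self.residue_index} cannot carry amide ¹H/¹⁵N shifts"
            )

    @property
    def has_amide(self) -> bool:
        return _is_present(self.shift_h) and _is_present(self.shift_n)


@dataclass
class PeakList:
    """An assigned peak list for one titration point.

    ``molar_ratio`` is the ligand:protein molar ratio (0 for the free state).
    """

    label: str
    molar_ratio: float
    entries: list[ResidueAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.molar_ratio = float(self.molar_ratio)
        if self.molar_ratio < 0:
            raise InputError(f"molar_ratio must be >= 0, got {self.molar_ratio}")
        if not self.entries:
            raise InputError(f"peak list {self.label!r} has no entries")
        seen: set[int] = set()
        for e in self.entries:
            if e.residue_index in seen:
                raise InputError(
                    f"duplicate residue index {e.residue_index} in peak list {self.label!r}"
                )
            seen.add(e.residue_index)
        self.entries.sort(key=lambda e: e.residue_index)

    def by_index(self) -> dict[int, ResidueAssignment]:
        return {e.residue_index: e for e in self.entries}

    @property
    def indices(self) -> list[int]:
        return [e.residue_index for e in self.entries]


@dataclass
class TitrationSeries:
    """Ordered titration points sharing one residue index space.

    The first point must be the free state (molar ratio 0); points are kept
    sorted by ascending molar ratio.
    """

    sequence: str
    points: list[PeakList]

    def __post_init__(self) -> None:
        self.sequence = str(self.sequence).upper()
        if not self.points:
            raise InputError("a titration series needs at least one point")
        self.points.sort(key=lambda p: p.molar_ratio)
        if self.points[0].molar_ratio != 0:
            raise InputError("the first titration point must be the free state (ratio 0)")
        n = len(self.sequence)
        for p in self.points:
            for e in p.entries:
                if e.residue_index > n:
                    raise InputError(
                        f"residue index {e.residue_index} beyond sequence length {n}"
                    )
                if self.sequence[e.residue_index - 1] != e.residue_code:
                    raise InputError(
                        f"residue {e.residue_index} is {e.residue_code} in peak list "
                        f"{p.label!r} but {self.sequence[e.residue_index - 1]} in the sequence"
                    )

    @property
    def free(self) -> PeakList:
        return self.points[0]

    @property
    def bound_points(self) -> list[PeakList]:
        return self.points[1:]


# ---------------------------------------------------------------------------
# peak-list readers

_SPARKY_ASSIGN = re.compile(r"^([A-Za-z])(\d+)([A-Za-z][A-Za-z0-9]*)-([A-Za-z][A-Za-z0-9]*)$")


def _parse_sparky(lines: Iterable[str]) -> list[ResidueAssignment]:
    entries: list[ResidueAssignment] = []
    skipped = 0
    for raw in lines:
        line = raw.strip()
        if not line or line.lower().startswith("assignment"):
            continue
        tokens = line.split()
        m = _SPARKY_ASSIGN.match(tokens[0])
        if m is None or len(tokens) < 3:
            skipped += 1
            continue
        code, idx = m.group(1).upper(), int(m.group(2))
        try:
            shift_n = float(tokens[1])
            shift_h = float(tokens[2])
            intensity = float(tokens[3]) if len(tokens) > 3 else None
        except ValueError:
            skipped += 1
            continue
        entries.append(
            ResidueAssignment(
                residue_index=idx,
                residue_code=code,
                shift_h=shift_h,
                shift_n=shift_n,
                intensity=intensity,
            )
        )
    if skipped:
        logger.warning("skipped %d unparseable Sparky rows", skipped)
    return entries


_TSV_COLUMNS = ("residue_index", "residue_code", "shift_h_ppm", "shift_n_ppm", "intensity")


def _parse_tsv(lines: list[str]) -> list[ResidueAssignment]:
    header = lines[0].rstrip("\n").split("\t")
    required = set(_TSV_COLUMNS[:4])
    if not required.issubset(header):
        raise FormatError(
            f"TSV peak list must contain columns {sorted(required)}, got {header}"
        )
    col = {name: header.index(name) for name in header}

    def get(fields: list[str], name: str) -> float | None:
        if name not in col or col[name] >= len(fields):
            return None
        s = fields[col[name]].strip()
        if s in ("", "NA", "nan", "NaN", "."):
            return None
        return float(s)

    entries = []
    skipped = 0
    for raw in lines[1:]:
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        try:
            entries.append(
                ResidueAssignment(
                    residue_index=int(fields[col["residue_index"]]),
                    residue_code=fields[col["residue_code"]].strip(),
                    shift_h=get(fields, "shift_h_ppm"),
                    shift_n=get(fields, "shift_n_ppm"),
                    intensity=get(fields, "intensity"),
                    shift_ca=get(fields, "shift_ca_ppm"),
                )
            )
        except (ValueError, IndexError):
            skipped += 1
    if skipped:
        logger.warning("skipped %d unparseable TSV rows", skipped)
    return entries


def read_peaklist(
    path: str | Path,
    format: str = "sparky",
    label: str | None = None,
    molar_ratio: float = 0.0,
) -> PeakList:
    """Read an assigned peak list in the ``sparky`` or ``tsv`` dialect.

    Rows with unparseable assignment labels are skipped and counted in a
    warning; an empty file or a duplicated residue index raises
    :class:`FormatError`/:class:`InputError`.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path} is empty")
    lines = text.splitlines()
    if format == "sparky":
        entries = _parse_sparky(lines)
    elif format == "tsv":
        entries = _parse_tsv(lines)
    else:
        raise FormatError(f"unknown peak-list format {format!r}")
    if not entries:
        raise FormatError(f"no parseable peak rows in {path}")
    return PeakList(label=label or path.stem, molar_ratio=molar_ratio, entries=entries)


# ---------------------------------------------------------------------------
# NMR-STAR v3 chemical-shift loop (read-only convenience)

_STAR_ATOMS = {"H": "shift_h", "N": "shift_n", "CA": "shift_ca"}


def read_shift_table_nmrstar(path: str | Path, label: str = "nmrstar") -> PeakList:
    """Read H/N/CA rows from the first NMR-STAR v3 ``Atom_chem_shift`` loop.

    Only the assigned-chemical-shift loop is interpreted; residues lacking an
    amide entry keep missing ``shift_h``/``shift_n``.  A minimal purpose-built
    loop parser is used.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    tags: list[str] = []
    rows: list[list[str]] = []
    state = "search"  # search -> tags -> data
    for raw in lines:
        line = raw.strip()
        if state == "search":
            if line == "loop_":
                tags, rows, state = [], [], "tags"
        elif state == "tags":
            if line.startswith("_"):
                tags.append(line.split(".", 1)[-1] if "." in line else line.lstrip("_"))
            elif line and not line.startswith("#"):
                if any(t in ("Atom_ID", "Atom_chem_shift.Atom_ID") for t in tags):
                    state = "data"
                    rows.append(line.split())
                else:
                    state = "search"
        elif state == "data":
            if line in ("stop_", ""):
                break
            if line.startswith("#"):
                continue
            rows.append(line.split())
    if state != "data" or not rows:
        raise FormatError(f"no Atom_chem_shift loop found in {path}")

    def col(*names: str) -> int | None:
        for n in names:
            if n in tags:
                return tags.index(n)
        return None

    i_seq = col("Seq_ID", "Comp_index_ID")
    i_comp = col("Comp_ID")
    i_atom = col("Atom_ID")
    i_val = col("Val")
    if None in (i_seq, i_comp, i_atom, i_val):
        raise FormatError(f"chemical-shift loop in {path} lacks Seq_ID/Comp_ID/Atom_ID/Val tags")

    residues: dict[int, dict] = {}
    for row in rows:
        if len(row) <= max(i_seq, i_comp, i_atom, i_val):
            raise FormatError(f"malformed chemical-shift row in {path}: {row}")
        atom = row[i_atom].upper()
        if atom not in _STAR_ATOMS:
            continue
        idx = int(row[i_seq])
        code3 = row[i_comp].capitalize()
        try:
            code = seq1(code3)
        except Exception as exc:  # unknown 3-letter code
            raise FormatError(f"unknown residue name {row[i_comp]!r} in {path}") from exc
        rec = residues.setdefault(idx, {"residue_index": idx, "residue_code": code})
        rec[_STAR_ATOMS[atom]] = float(row[i_val])
    if not residues:
        raise FormatError(f"no H/N/CA chemical-shift rows in {path}")
    entries = [ResidueAssignment(**rec) for _, rec in sorted(residues.items())]
    return PeakList(label=label, molar_ratio=0.0, entries=entries)


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | Path) -> str:
    """Return the first sequence in a FASTA file as an upper-case string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return str(records[0].seq).upper()


# ---------------------------------------------------------------------------
# per-residue track round trip

def write_profile(track, path: str | Path) -> None:
    """Write a per-residue track as TSV (residue_index, residue_code, value, flag).

    Values are written with full ``repr`` precision so the matching reader
    round-trips bit-exactly.  The residue code column is filled from the
    track's ``codes`` attribute when present, else ``X`` placeholder is
    avoided by writing ``-``.
    """
    path = Path(path)
    codes = getattr(track, "codes", None)
    with open(path, "w") as fh:
        fh.write("residue_index\tresidue_code\tvalue\tflag\n")
        for k in range(len(track.residue_index)):
            idx = int(track.residue_index[k])
            code = codes[k] if codes is not None else "-"
            if bool(track.missing_mask[k]):
                val = "NA"
            else:
                val = repr(float(track.values[k]))
            flag = track.flags[k]
            fh.write(f"{idx}\t{code}\t{val}\t{flag}\n")


def read_profile(path: str | Path, name: str | None = None):
    """Read a per-residue track written by :func:`write_profile`."""
    from .csp_core import PerResidueProfile  # local import to avoid a cycle

    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t")[:4] != ["residue_index", "residue_code", "value", "flag"]:
        raise FormatError(f"{path} is not a per-residue track file")
    idx: list[int] = []
    codes: list[str] = []
    values: list[float] = []
    missing: list[bool] = []
    flags: list[str] = []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        f = raw.rstrip("\n").split("\t")
        idx.append(int(f[0]))
        codes.append(f[1])
        if f[2] == "NA":
            values.append(math.nan)
            missing.append(True)
        else:
            values.append(float(f[2]))
            missing.append(False)
        flags.append(f[3])
    return PerResidueProfile(
        name=name or path.stem,
        residue_index=idx,
        values=values,
        missing_mask=missing,
        flags=flags,
        codes=codes,
        params={"source": str(path)},
    )
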