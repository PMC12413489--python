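"""Domain types and file I/O: sample metadata, peak lists, peptide tables, reports.

All external formats are small delimited-text dialects (comma or tab,
auto-detected).  A *manifest* CSV binds each measurement file to its sample
metadata; cohort assembly is driven entirely by manifests.

Conventions
-----------
* A MALDI measurement is identified by (species, state, individual,
  technical_replicate, spot); a complete cohort for one species x state holds
  3 x 3 x 3 = 27 spectra.
* An LC-ESI peptide table is identified by the same key without the spot;
  a complete cohort holds 3 x 3 = 9 tables.
* Peptide sequences use the flanked dialect ``K.GFTLPTTNSR.G`` where the
  flanks are the residues preceding/following the tryptic cut (``-`` marks a
  protein terminus).  Methionine oxidation may be tagged inline: ``M(ox)``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "SampleKey",
    "PeakList",
    "PeptideObservation",
    "ParseError",
    "SchemaError",
    "parse_flanked_sequence",
    "format_flanked_sequence",
    "read_peaklist",
    "write_peaklist",
    "read_peptide_table",
    "write_peptide_table",
    "read_manifest",
    "write_manifest",
    "write_marker_report",
    "read_marker_report",
]

STATES = ("raw", "cooked")

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

OXIDATION_DELTA = 15.994915  # monoisotopic +O on methionine, Da


class ParseError(ValueError):
    """A file or field could not be parsed; message names the offending line."""


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one measurement.

    ``spot`` is present for MALDI spectra (3 dried droplets per technical
    replicate) and ``None`` for LC-ESI peptide tables.
    """

    species: str
    state: str
    individual: int
    technical_replicate: int
    spot: Optional[int] = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        if not self.species:
            raise ValueError("species label must be non-empty")
        for name in ("individual", "technical_replicate"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.spot is not None and (not isinstance(self.spot, int) or self.spot < 1):
            raise ValueError(f"spot must be a positive integer or None, got {self.spot!r}")

    @property
    def cohort(self) -> tuple[str, str]:
        """(species, state) label of the cohort this measurement belongs to."""
        return (self.species, self.state)

    def drop_spot(self) -> "SampleKey":
        return replace(self, spot=None)

    def __str__(self) -> str:
        spot = "" if self.spot is None else f"/spot{self.spot}"
        return f"{self.species}:{self.state}:i{self.individual}r{self.technical_replicate}{spot}"


@dataclass(frozen=True)
class PeakList:
    """A centroided MALDI spectrum bound to its sample key.

    ``mz`` is strictly increasing; intensities are arbitrary units >= 0.
    """

    key: SampleKey
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and not np.all(np.diff(mz) > 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(mz <= 0) or np.any(inten < 0):
            raise ValueError("mz must be positive and intensities non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_pairs(cls, key: SampleKey, pairs: Iterable[tuple[float, float]]) -> "PeakList":
        """Build from (mz, intensity) pairs; sorts and collapses duplicate m/z."""
        arr = np.asarray(sorted(pairs), dtype=float).reshape(-1, 2)
        if arr.size == 0:
            return cls(key, np.empty(0), np.empty(0))
        mz, inv = np.unique(arr[:, 0], return_inverse=True)
        inten = np.zeros_like(mz)
        np.maximum.at(inten, inv, arr[:, 1])
        return cls(key, mz, inten)


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide in one LC-ESI sample file."""

    key: SampleKey
    core_sequence: str
    n_flank: str = "-"
    c_flank: str = "-"
    modifications: tuple[tuple[int, str, float], ...] = ()
    protein_accession: str = ""
    protein_name: str = ""
    reported_mass: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.core_sequence or not set(self.core_sequence) <= CANONICAL_RESIDUES:
            bad = set(self.core_sequence) - CANONICAL_RESIDUES
            raise ValueError(
                f"core sequence must be non-empty canonical amino acids; offending: {sorted(bad)!r}"
            )
        for pos, _name, _delta in self.modifications:
            if not (1 <= pos <= len(self.core_sequence)):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.core_sequence)}"
                )


# ---------------------------------------------------------------------------
# flanked-sequence dialect

_MOD_TAG = re.compile(r"\(ox\)", re.IGNORECASE)


def parse_flanked_sequence(s: str) -> tuple[str, str, str, list[tuple[int, str, float]]]:
    """Parse ``K.GFTLPTTNSR.G`` notation into (n_flank, core, c_flank, mods).

    The core may carry inline oxidation tags, e.g. ``K.VAFNQVADIM(ox)R.A``;
    each tag becomes ``(position, "Oxidation", +15.994915)`` with the position
    counted on the stripped core (1-based).
    """
    parts = s.strip().split(".")
    if len(parts) != 3:
        raise ParseError(
            f"flanked sequence must have form X.CORE.Z with exactly two dots: {s!r}"
        )
    n_flank, tagged, c_flank = parts
    for flank in (n_flank, c_flank):
        if not (flank == "-" or (len(flank) == 1 and flank in CANONICAL_RESIDUES)):
            raise ParseError(f"flank must be one canonical residue or '-': {flank!r} in {s!r}")
    mods: list[tuple[int, str, float]] = []
    core_chars: list[str] = []
    i = 0
    while i < len(tagged):
        ch = tagged[i]
        m = _MOD_TAG.match(tagged, i)
        if m:
            if not core_chars or core_chars[-1] != "M":
                raise ParseError(f"oxidation tag not following M in {s!r}")
            mods.append((len(core_chars), "Oxidation", OXIDATION_DELTA))
            i = m.end()
            continue
        core_chars.append(ch)
        i += 1
    core = "".join(core_chars)
    if not core or not set(core) <= CANONICAL_RESIDUES:
        bad = sorted(set(core) - CANONICAL_RESIDUES)
        raise ParseError(f"non-canonical residue(s) {bad!r} in core of {s!r}")
    return n_flank, core, c_flank, mods


def format_flanked_sequence(
    n_flank: str, core: str, c_flank: str, modifications: Sequence[tuple[int, str, float]] = ()
) -> str:
    """Inverse of :func:`parse_flanked_sequence` (oxidation tags re-inserted)."""
    chars = list(core)
    for pos, name, _delta in sorted(modifications, reverse=True):
        if name.lower() == "oxidation":
            chars[pos - 1] = chars[pos - 1] + "(ox)"
    return f"{n_flank}.{''.join(chars)}.{c_flank}"


# ---------------------------------------------------------------------------
# delimited-text helpers

def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text().splitlines()
    for line in head:
        if "\t" in line:
            return "\t"
        if "," in line:
            return ","
    return ","


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# peak lists

def read_peaklist(path, key: SampleKey) -> PeakList:
    """Read a centroid peak list (columns ``mz[,intensity]``, header optional).

    Missing intensities default to 1.0; duplicate m/z rows collapse to the
    maximum intensity; output is sorted ascending in m/z.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    sep = _sniff_sep(path)
    pairs: list[tuple[float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        toks = [t.strip() for t in line.split(sep)]
        if lineno == 1 and toks[0].lower() in ("mz", "m/z", "mass"):
            continue  # header row
        if not _is_number(toks[0]):
            raise ParseError(f"{path}: non-numeric m/z at line {lineno}: {toks[0]!r}")
        mz = float(toks[0])
        if len(toks) > 1 and toks[1]:
            if not _is_number(toks[1]):
                raise ParseError(f"{path}: non-numeric intensity at line {lineno}: {toks[1]!r}")
            inten = float(toks[1])
        else:
            inten = 1.0
        pairs.append((mz, inten))
    if not pairs:
        warnings.warn(f"empty peak list: {path}", stacklevel=2)
        return PeakList(key, np.empty(0), np.empty(0))
    return PeakList.from_pairs(key, pairs)


def write_peaklist(pl: PeakList, path) -> None:
    df = pd.DataFrame({"mz": pl.mz, "intensity": pl.intensity})
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# peptide tables

_SEQ_COLS = ("sequence", "peptide", "flanked_sequence")
_ACC_COLS = ("accession", "access_code", "protein_accession")
_NAME_COLS = ("protein", "protein_name")
_MASS_COLS = ("mass", "calc_mass", "m_fragment")


def _find_col(columns: Sequence[str], wanted: Sequence[str]) -> Optional[str]:
    lower = {c.lower().strip(): c for c in columns}
    for w in wanted:
        if w in lower:
            return lower[w]
    return None


def read_peptide_table(path, key: SampleKey) -> list[PeptideObservation]:
    """Read one search-engine-export-style peptide table for one sample.

    Mandatory columns: flanked sequence, accession, protein name (synonyms
    accepted).  Optional: mass.  Raises :class:`SchemaError` if a mandatory
    column is absent and :class:`ParseError` (with the row index) for a
    malformed sequence.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    seq_c = _find_col(df.columns, _SEQ_COLS)
    acc_c = _find_col(df.columns, _ACC_COLS)
    name_c = _find_col(df.columns, _NAME_COLS)
    if seq_c is None or acc_c is None or name_c is None:
        raise SchemaError(
            f"{path}: need sequence, accession and protein columns; found {list(df.columns)}"
        )
    mass_c = _find_col(df.columns, _MASS_COLS)
    out: list[PeptideObservation] = []
    for i in range(len(df)):
        raw_seq = str(df.iloc[i][seq_c])
        try:
            n_flank, core, c_flank, mods = parse_flanked_sequence(raw_seq)
        except ParseError as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from exc
        mass = None
        if mass_c is not None:
            v = df.iloc[i][mass_c]
            if pd.notna(v):
                mass = float(v)
        out.append(
            PeptideObservation(
                key=key,
                core_sequence=core,
                n_flank=n_flank,
                c_flank=c_flank,
                modifications=tuple(mods),
                protein_accession=str(df.iloc[i][acc_c]),
                protein_name=str(df.iloc[i][name_c]),
                reported_mass=mass,
            )
        )
    return out


def write_peptide_table(observations: Sequence[PeptideObservation], path) -> None:
    rows = []
    for o in observations:
        rows.append(
            {
                "sequence": format_flanked_sequence(
                    o.n_flank, o.core_sequence, o.c_flank, o.modifications
                ),
                "accession": o.protein_accession,
                "protein": o.protein_name,
                "mass": "" if o.reported_mass is None else f"{o.reported_mass:.5f}",
            }
        )
    pd.DataFrame(rows, columns=["sequence", "accession", "protein", "mass"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# manifests

_MANIFEST_COLS = ["path", "species", "state", "individual", "technical_replicate", "spot"]


def read_manifest(path) -> list[tuple[Path, SampleKey]]:
    """Read a manifest CSV (one row per measurement file).

    Relative paths are resolved against the manifest's own directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        spot = row["spot"]
        spot = None if pd.isna(spot) or str(spot).strip() == "" else int(spot)
        key = SampleKey(
            species=str(row["species"]),
            state=str(row["state"]),
            individual=int(row["individual"]),
            technical_replicate=int(row["technical_replicate"]),
            spot=spot,
        )
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = path.parent / p
        out.append((p, key))
    return out


def write_manifest(entries: Sequence[tuple], path) -> None:
    rows = []
    for p, key in entries:
        rows.append(
            {
                "path": str(p),
                "species": key.species,
                "state": key.state,
                "individual": key.individual,
                "technical_replicate": key.technical_replicate,
                "spot": "" if key.spot is None else key.spot,
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# marker reports

_REPORT_COLS = ["species", "state", "mode", "mz", "frequency", "n_spectra"]


def write_marker_report(panels, path) -> None:
    """Write one or more marker panels as a deterministic TSV.

    Rows sort by (species, state, mode, m/z ascending); writing the result of
    :func:`read_marker_report` back reproduces the file byte for byte.
    """
    from .maldi_markers import MarkerPanel  # local import to avoid cycle

    if isinstance(panels, MarkerPanel):
        panels = [panels]
    rows = []
    for panel in panels:
        species, state = panel.species, panel.state or ""
        for mz, freq, n in panel.markers:
            rows.append(
                {
                    "species": species,
                    "state": state,
                    "mode": panel.mode,
                    "mz": f"{mz:.4f}",
                    "frequency": freq,
                    "n_spectra": n,
                }
            )
    df = pd.DataFrame(rows, columns=_REPORT_COLS)
    if len(df):
        df = df.sort_values(
            ["species", "state", "mode", "mz"], key=lambda c: c.astype(float) if c.name == "mz" else c
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_marker_report(path) -> list:
    """Read a marker-report TSV back into a list of MarkerPanel objects."""
    from .maldi_markers import MarkerPanel

    df = pd.read_csv(path, sep="\t")
    panels = []
    if not len(df):
        return panels
    df["state"] = df["state"].fillna("")
    for (species, state, mode), sub in df.groupby(["species", "state", "mode"], sort=True):
        markers = [
            (float(r.mz), int(r.frequency), int(r.n_spectra))
            for r in sub.itertuples(index=False)
        ]
        markers.sort()
        panels.append(
            MarkerPanel(species=species, state=state or None, mode=mode, markers=tuple(markers))
        )
    return panels
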