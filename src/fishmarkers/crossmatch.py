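"""Cross-platform matching of MALDI m/z markers to peptide sequence masses.

MALDI ions are singly protonated, so a marker m/z maps to a neutral mass by
subtracting one proton; that neutral mass is compared to the computed
monoisotopic masses of the characteristic peptides within a tolerance
(default +-0.3 Da, inclusive).  All peptides matching one marker are
reported, sorted by mass error; the matched-marker count tallies distinct
markers, not pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .masscalc import PROTON, peptide_mass

__all__ = ["CrossMatch", "match_markers", "count_matched_markers"]


@dataclass(frozen=True)
class CrossMatch:
    """One MALDI marker paired with one peptide within tolerance."""

    maldi_mz: float
    neutral_mass: float  # maldi_mz minus one proton
    peptide: str
    peptide_mass: float
    delta: float  # |neutral_mass - peptide_mass|
    protein_name: str = ""


def _normalise_peptides(peptides) -> list[tuple[str, tuple, str]]:
    """Accept 'SEQ', (seq, mods), or (seq, mods, protein_name)."""
    out = []
    for p in peptides:
        if isinstance(p, str):
            out.append((p, (), ""))
        else:
            seq = p[0]
            mods = tuple(p[1]) if len(p) > 1 and p[1] else ()
            name = str(p[2]) if len(p) > 2 else ""
            out.append((seq, mods, name))
    return out


def match_markers(
    maldi_panel: Sequence[float],
    peptides,
    tol: float = 0.3,
    proton: float = PROTON,
) -> list[CrossMatch]:
    """Match each MALDI marker m/z against computed peptide masses.

    ``peptides`` items may be bare sequences or ``(sequence, modifications[,
    protein_name])`` tuples.  ``proton`` defaults to the physical proton mass;
    pass ``proton=1.0`` to reproduce legacy integer charge subtraction — the
    +-0.3 Da tolerance absorbs the 0.007 Da difference either way.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pep = [
        (seq, mods, name, peptide_mass(seq, mods))
        for seq, mods, name in _normalise_peptides(peptides)
    ]
    matches: list[CrossMatch] = []
    for mz in maldi_panel:
        neutral = float(mz) - proton
        hits = []
        for seq, _mods, name, mass in pep:
            delta = abs(neutral - mass)
            if delta <= tol:
                hits.append(
                    CrossMatch(
                        maldi_mz=float(mz),
                        neutral_mass=neutral,
                        peptide=seq,
                        peptide_mass=mass,
                        delta=delta,
                        protein_name=name,
                    )
                )
        hits.sort(key=lambda m: (m.delta, m.peptide))
        matches.extend(hits)
    return matches


def count_matched_markers(
    matches: Sequence[CrossMatch], maldi_panel: Optional[Sequence[float]] = None
) -> int:
    """Number of distinct MALDI marker values with at least one match."""
    matched = {m.maldi_mz for m in matches}
    if maldi_panel is not None:
        matched &= {float(v) for v in maldi_panel}
    return len(matched)
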