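"""Monoisotopic peptide mass arithmetic and in-silico tryptic digestion.

Residue masses are the standard monoisotopic values, pinned in code at
5-decimal precision for reproducibility.  A peptide's neutral mass is the sum
of its residue masses plus one water; the singly protonated ion observed in
MALDI adds one proton.  Trypsin cleaves C-terminal to K or R unless the next
residue is P (the classical rule used by most search engines).
"""

from __future__ import annotations

from typing import Sequence

__all__ = [
    "RESIDUE_MASSES",
    "WATER",
    "PROTON",
    "OXIDATION_DELTA",
    "peptide_mass",
    "mh_plus",
    "digest_trypsin",
]

# standard amino-acid residue monoisotopic masses, Da
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565  # H2O monoisotopic, Da
PROTON = 1.007276  # mass of H+, Da
OXIDATION_DELTA = 15.994915  # +O, Da (methionine oxidation)


def peptide_mass(seq: str, modifications: Sequence = ()) -> float:
    """Neutral monoisotopic mass of a peptide in Da.

    Parameters
    ----------
    seq:
        Canonical amino-acid string (uppercase).
    modifications:
        Items of the form ``(position, name, delta_da)`` or bare deltas; only
        the mass delta is used.

    >>> round(peptide_mass("G"), 5)
    75.03203
    """
    if not seq:
        raise ValueError("peptide sequence must be non-empty")
    try:
        total = sum(RESIDUE_MASSES[ch] for ch in seq)
    except KeyError as exc:
        raise ValueError(f"unknown amino-acid letter {exc.args[0]!r} in {seq!r}") from None
    for mod in modifications:
        if isinstance(mod, (int, float)):
            total += float(mod)
        else:
            total += float(mod[-1])
    return total + WATER


def mh_plus(neutral_mass: float, proton: float = PROTON) -> float:
    """m/z of the singly protonated ion: neutral mass plus one proton."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + proton


def _cleavage_sites(seq: str) -> list[int]:
    """Indices i such that trypsin cuts between seq[i-1] and seq[i]."""
    return [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "KR" and seq[i] != "P"
    ]


def digest_trypsin(
    protein_seq: str,
    max_missed: int = 1,
    min_len: int | None = 7,
    max_len: int | None = 30,
) -> list[str]:
    """In-silico tryptic digest with missed cleavages and a length window.

    Cleaves after K/R except before P.  Returns every peptide spanning at
    most ``max_missed`` internal uncut sites, filtered to
    ``min_len <= len <= max_len`` (pass ``None`` to disable either bound),
    ordered by start position then length.  Peptides are reported once even
    if reachable from several cleavage patterns.
    """
    if not protein_seq:
        return []
    bad = set(protein_seq) - set(RESIDUE_MASSES)
    if bad:
        raise ValueError(f"unknown amino-acid letter(s) {sorted(bad)!r}")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + _cleavage_sites(protein_seq) + [len(protein_seq)]
    peptides: list[str] = []
    seen: set[tuple[int, int]] = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(bounds))):
            start, end = bounds[i], bounds[j]
            n = end - start
            if min_len is not None and n < min_len:
                continue
            if max_len is not None and n > max_len:
                continue
            if (start, end) not in seen:
                seen.add((start, end))
                peptides.append(protein_seq[start:end])
    return peptides
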