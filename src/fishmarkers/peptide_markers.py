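"""Sequence-level marker mining on peptide-identification tables.

A peptide is *characteristic* of a cohort when it is identified in every one
of the cohort's sample files (normally 9: three individuals x three
technical replicates) and in no sample file of any compared cohort.  The
four-way variant compares raw and cooked cohorts of two species
simultaneously, so a characteristic sequence then also pins down the
processing state.  Per-protein aggregation ranks the proteins contributing
the most characteristic sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence
import warnings

import numpy as np

from .io_meta import PeptideObservation, SampleKey, format_flanked_sequence

__all__ = [
    "PresenceSet",
    "CharacteristicSequenceSet",
    "build_presence",
    "characteristic_sequences",
    "four_way_characteristic",
    "protein_peptide_stats",
    "protein_report_filter",
]


def _seq_id(obs: PeptideObservation, collapse_mods: bool) -> str:
    if collapse_mods or not obs.modifications:
        return obs.core_sequence
    return format_flanked_sequence("-", obs.core_sequence, "-", obs.modifications)[2:-2]


@dataclass(frozen=True)
class PresenceSet:
    """Which peptide sequences were seen in which sample files of one cohort."""

    cohort_label: str
    samples: tuple[SampleKey, ...]
    presence: Mapping[str, frozenset[SampleKey]]  # sequence -> files containing it
    proteins: Mapping[str, frozenset[tuple[str, str]]]  # sequence -> {(accession, name)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def count(self, sequence: str) -> int:
        return len(self.presence.get(sequence, ()))

    def sequences_in_all(self) -> set[str]:
        """Sequences identified in every sample file of the cohort."""
        n = self.n_samples
        return {s for s, files in self.presence.items() if len(files) == n}


@dataclass(frozen=True)
class CharacteristicSequenceSet:
    """Cohort-characteristic sequences plus their per-protein tally."""

    cohort_label: str
    sequences: frozenset[str]
    per_protein: Mapping[str, tuple[str, int]]  # accession -> (name, n characteristic)

    def top_proteins(self, n: int = 5) -> list[tuple[str, str, int]]:
        """The n proteins contributing the most characteristic sequences."""
        ranked = sorted(
            ((acc, name, cnt) for acc, (name, cnt) in self.per_protein.items()),
            key=lambda t: (-t[2], t[0]),
        )
        return ranked[:n]

    def __len__(self) -> int:
        return len(self.sequences)


def build_presence(
    observations: Iterable[PeptideObservation],
    cohort: Iterable[SampleKey],
    collapse_mods: bool = True,
    cohort_label: Optional[str] = None,
) -> PresenceSet:
    """Tabulate which sequences were identified in which cohort sample files.

    With ``collapse_mods`` (default) modified and unmodified forms of a
    peptide count as one entry keyed by the stripped core sequence; without
    it, an oxidized form is a distinct entry.  Observations whose key is not
    in the cohort are ignored with a warning.
    """
    cohort_set = {k.drop_spot() for k in cohort}
    if not cohort_set:
        raise ValueError("cohort must be non-empty")
    presence: dict[str, set[SampleKey]] = {}
    proteins: dict[str, set[tuple[str, str]]] = {}
    n_outside = 0
    for obs in observations:
        k = obs.key.drop_spot()
        if k not in cohort_set:
            n_outside += 1
            continue
        sid = _seq_id(obs, collapse_mods)
        presence.setdefault(sid, set()).add(k)
        proteins.setdefault(sid, set()).add((obs.protein_accession, obs.protein_name))
    if n_outside:
        warnings.warn(f"ignored {n_outside} observations outside the cohort", stacklevel=2)
    label = cohort_label or "+".join(
        sorted({f"{k.species}:{k.state}" for k in cohort_set})
    )
    return PresenceSet(
        cohort_label=label,
        samples=tuple(sorted(cohort_set)),
        presence={s: frozenset(f) for s, f in presence.items()},
        proteins={s: frozenset(p) for s, p in proteins.items()},
    )


def characteristic_sequences(
    target: PresenceSet, others: Sequence[PresenceSet]
) -> CharacteristicSequenceSet:
    """Sequences in *all* target samples and in *no* sample of any other cohort.

    "Characteristic" is always relative to the cohorts supplied.  A sequence
    reported under several protein accessions is credited to each of them, so
    per-protein counts can sum to more than the number of sequences (a note
    is emitted when that happens).
    """
    target_samples = set(target.samples)
    for other in others:
        overlap = target_samples & set(other.samples)
        if overlap:
            raise ValueError(
                f"cohorts overlap: {sorted(overlap)[0]} in both "
                f"{target.cohort_label!r} and {other.cohort_label!r}"
            )
    chars = {
        s
        for s in target.sequences_in_all()
        if all(s not in other.presence for other in others)
    }
    per_protein: dict[str, tuple[str, int]] = {}
    degenerate = 0
    for s in chars:
        attributions = target.proteins.get(s, frozenset())
        if len(attributions) > 1:
            degenerate += 1
        for acc, name in attributions:
            prev = per_protein.get(acc)
            per_protein[acc] = (name, (prev[1] if prev else 0) + 1)
    if degenerate:
        warnings.warn(
            f"{degenerate} characteristic sequence(s) shared by multiple proteins; "
            "per-protein counts may exceed the sequence total",
            stacklevel=2,
        )
    return CharacteristicSequenceSet(
        cohort_label=target.cohort_label,
        sequences=frozenset(chars),
        per_protein=per_protein,
    )


def four_way_characteristic(
    presence_sets: Sequence[PresenceSet],
) -> dict[str, CharacteristicSequenceSet]:
    """Each cohort against the other three (e.g. raw/cooked carp vs salmon).

    A sequence characteristic here pins down both the species and the
    processing state: present in all samples of its cohort and in not a
    single sample of any of the others.
    """
    if len(presence_sets) != 4:
        raise ValueError(f"expected exactly 4 cohorts, got {len(presence_sets)}")
    out = {}
    for i, target in enumerate(presence_sets):
        others = [p for j, p in enumerate(presence_sets) if j != i]
        out[target.cohort_label] = characteristic_sequences(target, others)
    return out


def protein_peptide_stats(
    observations: Iterable[PeptideObservation],
    cohort: Iterable[SampleKey],
    collapse_mods: bool = True,
) -> dict[str, tuple[str, float, float]]:
    """Per-protein distinct-peptide counts: accession -> (name, mean, sd).

    Counts distinct core sequences per accession in each sample file (zero
    for files where the protein was not seen) and reports the mean and the
    sample standard deviation (n-1) across the cohort's files.
    """
    cohort_set = sorted({k.drop_spot() for k in cohort})
    if not cohort_set:
        raise ValueError("cohort must be non-empty")
    per_file: dict[str, dict[SampleKey, set[str]]] = {}
    names: dict[str, str] = {}
    for obs in observations:
        k = obs.key.drop_spot()
        if k not in set(cohort_set):
            continue
        acc = obs.protein_accession
        per_file.setdefault(acc, {}).setdefault(k, set()).add(
            _seq_id(obs, collapse_mods)
        )
        names.setdefault(acc, obs.protein_name)
    out: dict[str, tuple[str, float, float]] = {}
    for acc, files in per_file.items():
        counts = np.array([len(files.get(k, ())) for k in cohort_set], dtype=float)
        sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
        out[acc] = (names[acc], float(np.mean(counts)), sd)
    return out


def protein_report_filter(
    observations: Iterable[PeptideObservation],
    cohort: Iterable[SampleKey],
    min_peptides: int = 2,
    collapse_mods: bool = True,
) -> dict[str, tuple[str, float, float]]:
    """Proteins confidently detected: >= ``min_peptides`` distinct peptides
    in *every* sample file of the cohort.  Returns the same mapping as
    :func:`protein_peptide_stats`, restricted to the retained accessions.
    """
    cohort_set = sorted({k.drop_spot() for k in cohort})
    stats = protein_peptide_stats(observations, cohort_set, collapse_mods)
    if min_peptides <= 0:
        return stats
    per_file: dict[str, dict[SampleKey, set[str]]] = {}
    for obs in observations:
        k = obs.key.drop_spot()
        if k not in set(cohort_set):
            continue
        per_file.setdefault(obs.protein_accession, {}).setdefault(k, set()).add(
            _seq_id(obs, collapse_mods)
        )
    keep = {
        acc
        for acc, files in per_file.items()
        if all(len(files.get(k, ())) >= min_peptides for k in cohort_set)
    }
    return {acc: v for acc, v in stats.items() if acc in keep}
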