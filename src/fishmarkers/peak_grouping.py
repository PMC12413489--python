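"""Tolerance-based m/z grouping across spectra and the occurrence matrix.

Peaks from many spectra that represent the same underlying ion are merged by
single-linkage on sorted m/z gaps: pool every (spectrum, m/z) pair, sort by
m/z, and split wherever the gap between consecutive values exceeds
``gap_tol``.  This is equivalent to the connected components of the pairwise
|dmz| <= gap_tol graph and avoids the edge-splitting artifacts of fixed-width
binning.  If one spectrum contributes several peaks to a group, the peak
closest to the group median is kept (ties break to the lower m/z) and the
remainder are re-split into their own groups, which bounds chaining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_meta import PeakList, SampleKey

__all__ = ["PeakGroup", "OccurrenceMatrix", "group_peaks", "occurrence_matrix"]


@dataclass(frozen=True)
class PeakGroup:
    """A set of peaks from different spectra judged to be the same ion."""

    consensus_mz: float  # median of member m/z values
    members: tuple[tuple[SampleKey, float], ...]

    @property
    def spread(self) -> float:
        mzs = [m for _, m in self.members]
        return max(mzs) - min(mzs)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Presence/absence of each peak group in each spectrum."""

    groups: tuple[PeakGroup, ...]
    spectra: tuple[SampleKey, ...]
    present: np.ndarray  # bool, shape (n_groups, n_spectra)

    def __post_init__(self) -> None:
        p = np.asarray(self.present, dtype=bool)
        object.__setattr__(self, "present", p)
        if p.shape != (len(self.groups), len(self.spectra)):
            raise ValueError("present matrix shape mismatch")

    def column_index(self, keys) -> np.ndarray:
        """Column indices of the given sample keys (consistency-checked)."""
        pos = {k: i for i, k in enumerate(self.spectra)}
        missing = [k for k in keys if k not in pos]
        if missing:
            raise ValueError(f"keys not in matrix: {missing[:3]}...")
        return np.asarray([pos[k] for k in keys], dtype=int)


def _gap_split(pool: list[tuple[float, SampleKey]], gap_tol: float):
    """Split an m/z-sorted pool at gaps > gap_tol; yields runs (sublists)."""
    if not pool:
        return
    start = 0
    for i in range(1, len(pool)):
        if pool[i][0] - pool[i - 1][0] > gap_tol:
            yield pool[start:i]
            start = i
    yield pool[start:]


def _dedupe(run: list[tuple[float, SampleKey]], gap_tol: float) -> list[PeakGroup]:
    """Enforce one member per spectrum; leftovers are re-split recursively."""
    counts: dict[SampleKey, int] = {}
    for _, k in run:
        counts[k] = counts.get(k, 0) + 1
    if all(c == 1 for c in counts.values()):
        mzs = [m for m, _ in run]
        return [
            PeakGroup(
                consensus_mz=float(np.median(mzs)),
                members=tuple((k, m) for m, k in run),
            )
        ]
    median = float(np.median([m for m, _ in run]))
    kept: list[tuple[float, SampleKey]] = []
    leftovers: list[tuple[float, SampleKey]] = []
    best: dict[SampleKey, tuple[float, float]] = {}  # key -> (distance, mz)
    for m, k in run:
        cand = (abs(m - median), m)  # tie on distance -> lower m/z wins
        if k not in best or cand < best[k]:
            best[k] = cand
    for m, k in run:
        if best[k][1] == m and (abs(m - median), m) == best[k]:
            kept.append((m, k))
            best[k] = (float("inf"), float("nan"))  # consume so duplicates of same mz split off
        else:
            leftovers.append((m, k))
    mzs = [m for m, _ in kept]
    groups = [
        PeakGroup(
            consensus_mz=float(np.median(mzs)),
            members=tuple((k, m) for m, k in kept),
        )
    ]
    for sub in _gap_split(sorted(leftovers), gap_tol):
        groups.extend(_dedupe(sub, gap_tol))
    return groups


def group_peaks(spectra: list[PeakList], gap_tol: float = 0.1) -> list[PeakGroup]:
    """Merge peaks across spectra into consensus groups (see module docstring).

    The result is sorted by consensus m/z and is invariant to the order of the
    input spectra.  Every input peak lands in exactly one group.
    """
    if gap_tol <= 0:
        raise ValueError("gap_tol must be positive")
    pool: list[tuple[float, SampleKey]] = []
    for pl in spectra:
        pool.extend((float(m), pl.key) for m in pl.mz)
    pool.sort()
    groups: list[PeakGroup] = []
    for run in _gap_split(pool, gap_tol):
        groups.extend(_dedupe(run, gap_tol))
    groups.sort(key=lambda g: g.consensus_mz)
    return groups


def occurrence_matrix(groups: list[PeakGroup], spectra: list[SampleKey]) -> OccurrenceMatrix:
    """Boolean groups x spectra matrix: did this spectrum contribute a member?

    Raises if a group member references a spectrum absent from ``spectra``.
    """
    spectra = tuple(spectra)
    pos = {k: i for i, k in enumerate(spectra)}
    present = np.zeros((len(groups), len(spectra)), dtype=bool)
    for gi, g in enumerate(groups):
        for k, _mz in g.members:
            if k not in pos:
                raise ValueError(f"group member references unknown spectrum {k}")
            present[gi, pos[k]] = True
    return OccurrenceMatrix(tuple(groups), spectra, present)
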