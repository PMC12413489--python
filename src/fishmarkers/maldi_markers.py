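"""MALDI marker mining: frequent peaks, exclusivity, state differences.

The mining logic works on presence/absence only.  A consensus m/z is
*frequent* in a cohort (one species x processing state, normally 27 spectra)
when it occurs in at least ``min_count`` of the cohort's spectra (default
23 of 27).  A frequent value is a *species-exclusive marker* when no other
species shows it; raw and cooked analyses are run independently, and markers
shared by both states of a species are detected only post hoc by pairing the
two panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_meta import SampleKey
from .peak_grouping import OccurrenceMatrix

__all__ = [
    "DEFAULT_MIN_FRACTION",
    "MarkerPanel",
    "min_count_for",
    "frequent_mz",
    "species_exclusive_markers",
    "state_differential_markers",
    "dual_markers",
    "shared_raw_cooked",
]

# the canonical frequency threshold expressed as a fraction (23 of 27 spectra),
# so cohorts of other sizes scale
DEFAULT_MIN_FRACTION = 23 / 27


def min_count_for(n_cohort: int, min_fraction: float = DEFAULT_MIN_FRACTION) -> int:
    """Smallest integer count implementing ``min_fraction`` for a cohort size."""
    return int(math.ceil(min_fraction * n_cohort - 1e-9))


@dataclass(frozen=True)
class MarkerPanel:
    """Discovered markers for one cohort, with provenance counts.

    ``markers`` holds ``(consensus_mz, frequency, n_spectra)`` triples sorted
    ascending in m/z; ``mode`` records the mining mode that produced them.
    """

    species: str
    markers: tuple[tuple[float, int, int], ...]
    state: Optional[str] = None
    mode: str = "species_exclusive"

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(sorted(self.markers)))

    @property
    def mz_values(self) -> list[float]:
        return [m for m, _f, _n in self.markers]

    def __len__(self) -> int:
        return len(self.markers)


def _as_mz(values) -> np.ndarray:
    """Accept a MarkerPanel, (mz, freq) pairs, or bare floats."""
    if isinstance(values, MarkerPanel):
        return np.asarray(values.mz_values, dtype=float)
    out = []
    for v in values:
        out.append(float(v[0]) if isinstance(v, (tuple, list)) else float(v))
    return np.asarray(sorted(out), dtype=float)


def _within(value: float, pool: np.ndarray, tol: float) -> bool:
    return bool(pool.size) and bool(np.min(np.abs(pool - value)) <= tol)


def frequent_mz(
    matrix: OccurrenceMatrix,
    cohort: Iterable[SampleKey],
    min_count: int = 23,
) -> list[tuple[float, int]]:
    """Consensus m/z values present in at least ``min_count`` cohort spectra.

    Returns ``(consensus_mz, frequency)`` pairs sorted by m/z.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if min_count > len(cohort):
        raise ValueError(f"min_count {min_count} exceeds cohort size {len(cohort)}")
    cols = matrix.column_index(cohort)
    counts = matrix.present[:, cols].sum(axis=1)
    out = [
        (g.consensus_mz, int(c))
        for g, c in zip(matrix.groups, counts)
        if c >= min_count
    ]
    out.sort()
    return out


def species_exclusive_markers(
    frequent_lists: Mapping[str, Sequence[tuple[float, int]]],
    match_tol: float = 0.1,
    mode: str = "list_exclusive",
    state: Optional[str] = None,
    n_spectra: int = 27,
    other_peaks: Optional[Mapping[str, Sequence[float]]] = None,
) -> dict[str, MarkerPanel]:
    """Per-species markers absent from every other species.

    ``list_exclusive`` (default): a frequent value is a marker unless another
    species' *frequency-filtered* list holds a value within ``match_tol``.
    ``strict``: additionally no *individual spectrum* of any other species may
    contain a peak within ``match_tol``; supply ``other_peaks`` mapping each
    species to the pooled m/z values of all its spectra.  Strict panels are
    always subsets of list-exclusive panels.
    """
    if len(frequent_lists) < 2:
        raise ValueError("need at least two species to mine exclusivity")
    if mode not in ("list_exclusive", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "strict" and other_peaks is None:
        raise ValueError("strict mode requires other_peaks (per-species peak pools)")
    pools = {
        sp: _as_mz([mz for mz, _f in lst]) for sp, lst in frequent_lists.items()
    }
    raw_pools = (
        {sp: np.asarray(sorted(map(float, v))) for sp, v in other_peaks.items()}
        if other_peaks
        else {}
    )
    panels: dict[str, MarkerPanel] = {}
    for sp, lst in frequent_lists.items():
        kept = []
        for mz, freq in lst:
            clash = any(
                _within(mz, pools[other], match_tol)
                for other in frequent_lists
                if other != sp
            )
            if not clash and mode == "strict":
                clash = any(
                    _within(mz, raw_pools.get(other, np.empty(0)), match_tol)
                    for other in frequent_lists
                    if other != sp
                )
            if not clash:
                kept.append((float(mz), int(freq), n_spectra))
        panels[sp] = MarkerPanel(
            species=sp, state=state, mode=f"species_exclusive[{mode}]", markers=tuple(kept)
        )
    return panels


def state_differential_markers(
    matrix_raw: OccurrenceMatrix,
    matrix_cooked: OccurrenceMatrix,
    cohort_raw: Iterable[SampleKey],
    cohort_cooked: Iterable[SampleKey],
    species: str,
    min_count: int = 23,
    match_tol: float = 0.1,
) -> tuple[MarkerPanel, MarkerPanel]:
    """Markers separating raw from cooked meat of the *same* species.

    A raw marker is frequent in the raw cohort and absent (within
    ``match_tol``) from the species' cooked frequent list; symmetrically for
    cooked.  Both cohorts must belong to ``species``.
    """
    cohort_raw, cohort_cooked = list(cohort_raw), list(cohort_cooked)
    for cohort, want_state in ((cohort_raw, "raw"), (cohort_cooked, "cooked")):
        bad = [k for k in cohort if k.species != species or k.state != want_state]
        if bad:
            raise ValueError(f"cohort key {bad[0]} does not belong to {species}/{want_state}")
    freq_raw = frequent_mz(matrix_raw, cohort_raw, min_count)
    freq_cooked = frequent_mz(matrix_cooked, cohort_cooked, min_count)
    pool_raw = _as_mz([m for m, _ in freq_raw])
    pool_cooked = _as_mz([m for m, _ in freq_cooked])
    raw_markers = tuple(
        (float(mz), int(f), len(cohort_raw))
        for mz, f in freq_raw
        if not _within(mz, pool_cooked, match_tol)
    )
    cooked_markers = tuple(
        (float(mz), int(f), len(cohort_cooked))
        for mz, f in freq_cooked
        if not _within(mz, pool_raw, match_tol)
    )
    return (
        MarkerPanel(species, raw_markers, state="raw", mode="state_differential"),
        MarkerPanel(species, cooked_markers, state="cooked", mode="state_differential"),
    )


def dual_markers(
    species_panel: MarkerPanel, state_panel: MarkerPanel, match_tol: float = 0.1
) -> MarkerPanel:
    """Markers that pin down both the species and the processing state.

    The intersection (within ``match_tol``) of a species-exclusive panel and
    the same cohort's state-differential panel.
    """
    if species_panel.species != state_panel.species:
        raise ValueError("panels must describe the same species")
    species_pool = _as_mz(species_panel)
    kept = tuple(
        m for m in state_panel.markers if _within(m[0], species_pool, match_tol)
    )
    return MarkerPanel(
        species_panel.species, kept, state=state_panel.state, mode="dual"
    )


def shared_raw_cooked(
    panel_raw, panel_cooked, match_tol: float = 0.1
) -> list[tuple[float, float]]:
    """Pair marker values shared by the raw and cooked panels of one species.

    Greedy nearest pairing: candidate pairs within ``match_tol`` are taken in
    order of increasing |dmz|, each value used at most once.  Accepts
    MarkerPanels or plain m/z sequences.  Returns ``(mz_raw, mz_cooked)``
    pairs sorted by the raw value.
    """
    raw = _as_mz(panel_raw)
    cooked = _as_mz(panel_cooked)
    cands = [
        (abs(r - c), float(r), float(c))
        for r in raw
        for c in cooked
        if abs(r - c) <= match_tol
    ]
    cands.sort()
    used_r: set[float] = set()
    used_c: set[float] = set()
    pairs = []
    for _d, r, c in cands:
        if r in used_r or c in used_c:
            continue
        used_r.add(r)
        used_c.add(c)
        pairs.append((r, c))
    pairs.sort()
    return pairs
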