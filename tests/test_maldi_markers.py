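import numpy as np
import pytest

from conftest import make_peaklist
from fishmarkers.io_meta import SampleKey
from fishmarkers.maldi_markers import (
    MarkerPanel,
    dual_markers,
    frequent_mz,
    min_count_for,
    shared_raw_cooked,
    species_exclusive_markers,
    state_differential_markers,
)
from fishmarkers.peak_grouping import group_peaks, occurrence_matrix


def cohort_keys(species, state="raw"):
    return [
        SampleKey(species, state, i, r, s)
        for i in (1, 2, 3)
        for r in (1, 2, 3)
        for s in (1, 2, 3)
    ]


def build_matrix(peak_sets, state="raw"):
    """peak_sets: {species: list-of-27 lists of m/z}; returns (matrix, cohorts)."""
    lists = []
    cohorts = {}
    for sp, per_spectrum in peak_sets.items():
        keys = cohort_keys(sp, state)
        assert len(per_spectrum) == len(keys)
        cohorts[sp] = keys
        for key, mzs in zip(keys, per_spectrum):
            mzs = sorted(mzs)
            lists.append(
                make_peaklist(mzs, species=sp, state=state, individual=key.individual,
                              rep=key.technical_replicate, spot=key.spot)
            )
    groups = group_peaks(lists, 0.1)
    return occurrence_matrix(groups, [p.key for p in lists]), cohorts


def spectra_with(mz, n_present, filler_start=2000.0):
    """27 peak lists; the first n_present contain mz, all contain a filler."""
    out = []
    for i in range(27):
        peaks = [filler_start + 5.0 * i]
        if i < n_present:
            peaks.append(mz)
        out.append(peaks)
    return out


class TestFrequentMz:
    @pytest.mark.parametrize("n_present, expected", [(23, True), (22, False), (27, True)])
    def test_threshold_boundary(self, n_present, expected):
        matrix, cohorts = build_matrix({"carp": spectra_with(1000.0, n_present)})
        freq = frequent_mz(matrix, cohorts["carp"], min_count=23)
        found = any(abs(mz - 1000.0) <= 0.1 for mz, _ in freq)
        assert found is expected
        if expected:
            f = next(f for mz, f in freq if abs(mz - 1000.0) <= 0.1)
            assert f == n_present

    def test_min_count_equal_cohort_size_keeps_only_ubiquitous(self):
        matrix, cohorts = build_matrix({"carp": spectra_with(1000.0, 26)})
        assert all(
            abs(mz - 1000.0) > 0.1
            for mz, _ in frequent_mz(matrix, cohorts["carp"], min_count=27)
        )

    def test_empty_cohort_rejected(self):
        matrix, _ = build_matrix({"carp": spectra_with(1000.0, 27)})
        with pytest.raises(ValueError):
            frequent_mz(matrix, [], 23)

    def test_min_count_fraction_scales_with_cohort_size(self):
        assert min_count_for(27) == 23
        assert min_count_for(9) == 8  # ceil(9 * 23/27)


class TestSpeciesExclusive:
    def test_tolerant_set_difference(self):
        freq = {"A": [(1000.0, 25), (1200.0, 24)], "B": [(1200.05, 26)]}
        panels = species_exclusive_markers(freq, match_tol=0.1)
        assert panels["A"].mz_values == [1000.0]
        assert panels["B"].mz_values == []

    def test_value_in_both_lists_in_neither_panel(self):
        freq = {"A": [(1500.0, 27)], "B": [(1500.0, 27)]}
        panels = species_exclusive_markers(freq, match_tol=0.1)
        assert len(panels["A"]) == 0 and len(panels["B"]) == 0

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(ValueError):
            species_exclusive_markers({"A": [(1000.0, 27)]})

    def test_strict_mode_consults_raw_spectra(self):
        # 1000.0 frequent only in A, but B shows it in a single spectrum:
        # list-exclusive keeps it, strict rejects it
        freq = {"A": [(1000.0, 27)], "B": [(1600.0, 27)]}
        other_peaks = {"A": [1000.0] * 27, "B": [1600.0] * 27 + [1000.02]}
        loose = species_exclusive_markers(freq, mode="list_exclusive")
        strict = species_exclusive_markers(freq, mode="strict", other_peaks=other_peaks)
        assert loose["A"].mz_values == [1000.0]
        assert strict["A"].mz_values == []
        # strict panels are subsets of list-exclusive panels
        for sp in freq:
            assert set(strict[sp].mz_values) <= set(loose[sp].mz_values)

    def test_panels_pairwise_disjoint_within_tolerance(self):
        rng = np.random.default_rng(2)
        freq = {
            sp: [(float(m), 27) for m in np.sort(rng.uniform(900, 1100, 20))]
            for sp in ("A", "B", "C")
        }
        panels = species_exclusive_markers(freq, match_tol=0.1)
        values = [(sp, m) for sp, p in panels.items() for m in p.mz_values]
        for i, (sp1, m1) in enumerate(values):
            for sp2, m2 in values[i + 1:]:
                if sp1 != sp2:
                    assert abs(m1 - m2) > 0.1


class TestStateDifferential:
    def _matrices(self):
        raw = build_matrix(
            {"carp": spectra_with(1000.0, 27), "pike": spectra_with(3000.0, 27)}, "raw"
        )
        cooked = build_matrix(
            {"carp": spectra_with(1500.0, 27), "pike": spectra_with(3000.0, 27)},
            "cooked",
        )
        return raw, cooked

    def test_peak_frequent_in_one_state_only_is_differential(self):
        (m_raw, c_raw), (m_cooked, c_cooked) = self._matrices()
        raw_p, cooked_p = state_differential_markers(
            m_raw, m_cooked, c_raw["carp"], c_cooked["carp"], "carp", 23, 0.1
        )
        assert any(abs(m - 1000.0) <= 0.1 for m in raw_p.mz_values)
        assert any(abs(m - 1500.0) <= 0.1 for m in cooked_p.mz_values)
        # the shared filler ladder is frequent in neither state (each filler
        # value occurs in one spectrum) and in both panels absent
        assert all(m < 1990 for m in raw_p.mz_values)

    def test_peak_frequent_in_both_states_excluded(self):
        raw = build_matrix({"carp": spectra_with(1000.0, 27)}, "raw")
        cooked = build_matrix({"carp": spectra_with(1000.03, 27)}, "cooked")
        raw_p, cooked_p = state_differential_markers(
            raw[0], cooked[0], raw[1]["carp"], cooked[1]["carp"], "carp", 23, 0.1
        )
        assert all(abs(m - 1000.0) > 0.1 for m in raw_p.mz_values)
        assert all(abs(m - 1000.03) > 0.1 for m in cooked_p.mz_values)

    def test_wrong_species_cohort_rejected(self):
        (m_raw, c_raw), (m_cooked, c_cooked) = self._matrices()
        with pytest.raises(ValueError):
            state_differential_markers(
                m_raw, m_cooked, c_raw["pike"], c_cooked["carp"], "carp", 23, 0.1
            )


class TestDualAndShared:
    def test_dual_is_tolerant_intersection(self):
        species = MarkerPanel("carp", ((1092.7, 25, 27), (1500.0, 24, 27)), state="raw")
        state = MarkerPanel(
            "carp", ((1092.75, 25, 27), (1800.0, 23, 27)), state="raw",
            mode="state_differential",
        )
        dual = dual_markers(species, state, match_tol=0.1)
        assert dual.mz_values == [1092.75]

    def test_disjoint_panels_give_empty_dual(self):
        a = MarkerPanel("carp", ((1000.0, 27, 27),), state="raw")
        b = MarkerPanel("carp", ((2000.0, 27, 27),), state="raw")
        assert len(dual_markers(a, b)) == 0

    def test_state_subset_of_species_gives_state_panel(self):
        species = MarkerPanel("carp", ((1000.0, 27, 27), (2000.0, 27, 27)), state="raw")
        state = MarkerPanel("carp", ((1000.0, 27, 27),), state="raw")
        assert dual_markers(species, state).mz_values == [1000.0]

    def test_shared_pairing_greedy_nearest_each_value_once(self):
        pairs = shared_raw_cooked([1000.0, 1000.09], [1000.05], match_tol=0.1)
        assert pairs == [(1000.09, 1000.05)]  # nearest wins, single use

    @pytest.mark.parametrize("tol, paired", [(0.1, True), (0.05, False)])
    def test_tolerance_boundary(self, tol, paired):
        pairs = shared_raw_cooked([1269.7], [1269.8], match_tol=tol)
        assert bool(pairs) is paired
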