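import numpy as np
import pytest

from fishmarkers.io_meta import PeptideObservation, SampleKey
from fishmarkers.peptide_markers import (
    build_presence,
    characteristic_sequences,
    four_way_characteristic,
    protein_peptide_stats,
    protein_report_filter,
)


def keys9(species, state="raw"):
    return [SampleKey(species, state, i, r) for i in (1, 2, 3) for r in (1, 2, 3)]


def obs(key, seq, acc="P1", name="protein one", mods=()):
    return PeptideObservation(
        key, seq, protein_accession=acc, protein_name=name, modifications=mods
    )


def cohort_obs(species, seq_by_sample, state="raw", acc="P1"):
    """seq_by_sample: list of 9 sequence lists, one per sample file."""
    out = []
    for key, seqs in zip(keys9(species, state), seq_by_sample):
        out.extend(obs(key, s, acc=acc) for s in seqs)
    return out


class TestBuildPresence:
    def test_presence_in_all_nine_files(self):
        observations = cohort_obs("carp", [["GFTLPTTNSR"]] * 9)
        ps = build_presence(observations, keys9("carp"))
        assert ps.count("GFTLPTTNSR") == 9
        assert ps.sequences_in_all() == {"GFTLPTTNSR"}

    def test_collapse_mods_merges_oxidized_form(self):
        ox = ((10, "Oxidation", 15.994915),)
        observations = [
            obs(k, "VAFNQVADIMR", mods=ox if i == 2 else ())
            for i, k in enumerate(keys9("carp"))
        ]
        collapsed = build_presence(observations, keys9("carp"), collapse_mods=True)
        assert collapsed.count("VAFNQVADIMR") == 9
        strict = build_presence(observations, keys9("carp"), collapse_mods=False)
        counts = sorted(len(files) for files in strict.presence.values())
        assert counts == [1, 8]

    def test_collapse_never_increases_entry_count(self):
        ox = ((10, "Oxidation", 15.994915),)
        observations = [
            obs(k, "VAFNQVADIMR", mods=ox if i % 2 else ()) for i, k in enumerate(keys9("carp"))
        ]
        n_collapsed = len(build_presence(observations, keys9("carp"), True).presence)
        n_strict = len(build_presence(observations, keys9("carp"), False).presence)
        assert n_collapsed <= n_strict

    def test_observation_outside_cohort_ignored_with_warning(self):
        stray = obs(SampleKey("pike", "raw", 1, 1), "GFTLPTTNSR")
        with pytest.warns(UserWarning, match="outside"):
            ps = build_presence([stray] + cohort_obs("carp", [["AAAAAAK"]] * 9),
                                keys9("carp"))
        assert "GFTLPTTNSR" not in ps.presence


class TestCharacteristic:
    @pytest.mark.parametrize(
        "n_target, n_other, expected", [(9, 0, True), (8, 0, False), (9, 1, False)]
    )
    def test_all_target_none_elsewhere(self, n_target, n_other, expected):
        seq = "GFTLPTTNSR"
        a = cohort_obs("carp", [[seq]] * n_target + [[]] * (9 - n_target))
        b = cohort_obs("salmon", [[seq]] * n_other + [[]] * (9 - n_other))
        # both cohorts also share an uninformative sequence so presence sets exist
        a += cohort_obs("carp", [["AAAAAAK"]] * 9)
        b += cohort_obs("salmon", [["AAAAAAK"]] * 9)
        pa = build_presence(a, keys9("carp"))
        pb = build_presence(b, keys9("salmon"))
        cs = characteristic_sequences(pa, [pb])
        assert (seq in cs.sequences) is expected
        assert "AAAAAAK" not in cs.sequences  # shared sequence never characteristic

    def test_characteristic_sets_pairwise_disjoint(self):
        a = cohort_obs("carp", [["AAAAAAK", "CCCCCCCK"]] * 9)
        b = cohort_obs("salmon", [["DDDDDDR"]] * 9)
        pa, pb = build_presence(a, keys9("carp")), build_presence(b, keys9("salmon"))
        ca = characteristic_sequences(pa, [pb])
        cb = characteristic_sequences(pb, [pa])
        assert not (ca.sequences & cb.sequences)

    def test_overlapping_cohorts_rejected(self):
        a = cohort_obs("carp", [["AAAAAAK"]] * 9)
        pa = build_presence(a, keys9("carp"))
        with pytest.raises(ValueError, match="overlap"):
            characteristic_sequences(pa, [pa])

    def test_per_protein_counts_sum_to_sequences(self):
        a = cohort_obs("carp", [["AAAAAAK"]] * 9, acc="P1") + cohort_obs(
            "carp", [["CCCCCCCK"]] * 9, acc="P2"
        )
        b = cohort_obs("salmon", [["DDDDDDR"]] * 9)
        cs = characteristic_sequences(
            build_presence(a, keys9("carp")), [build_presence(b, keys9("salmon"))]
        )
        assert sum(c for _, c in cs.per_protein.values()) == len(cs.sequences) == 2


class TestFourWay:
    def _presence(self, layout):
        """layout: {(species,state): list of sequences present in all 9 files}."""
        out = []
        for (sp, st), seqs in layout.items():
            observations = cohort_obs(sp, [list(seqs)] * 9, state=st)
            out.append(build_presence(observations, keys9(sp, st)))
        return out

    def test_state_exclusivity_required(self):
        sets = self._presence({
            ("carp", "raw"): ["AAAAAAK", "EEEEEEK"],   # EEEEEEK raw-carp only
            ("carp", "cooked"): ["AAAAAAK"],            # AAAAAAK spans both carp states
            ("salmon", "raw"): ["DDDDDDR"],
            ("salmon", "cooked"): ["DDDDDDR"],
        })
        result = four_way_characteristic(sets)
        assert result["carp:raw"].sequences == {"EEEEEEK"}
        assert result["carp:cooked"].sequences == set()

    def test_four_way_subset_of_two_way(self):
        sets = self._presence({
            ("carp", "raw"): ["AAAAAAK", "EEEEEEK"],
            ("carp", "cooked"): ["AAAAAAK"],
            ("salmon", "raw"): ["DDDDDDR"],
            ("salmon", "cooked"): ["DDDDDDR"],
        })
        four = four_way_characteristic(sets)
        two = characteristic_sequences(sets[0], [sets[2]])  # raw carp vs raw salmon
        assert four["carp:raw"].sequences <= two.sequences

    def test_requires_exactly_four_cohorts(self):
        sets = self._presence({("carp", "raw"): ["AAAAAAK"]})
        with pytest.raises(ValueError):
            four_way_characteristic(sets)


class TestProteinStats:
    def test_zero_variance(self):
        observations = []
        for k in keys9("carp")[:3]:
            observations += [obs(k, s) for s in ("AAAAAAK", "CCCCCCCK", "DDDDDDR")]
        stats = protein_peptide_stats(observations, keys9("carp")[:3])
        name, mean, sd = stats["P1"]
        assert (mean, sd) == (3.0, 0.0)

    def test_sample_standard_deviation(self):
        k1, k2 = keys9("carp")[:2]
        observations = [obs(k1, s) for s in ("AAAAAAK", "CCCCCCCK")] + [
            obs(k2, s) for s in ("DDDDDDR", "EEEEEEK", "FFFFFFR", "GGGGGGGK")
        ]
        _, mean, sd = protein_peptide_stats(observations, [k1, k2])["P1"]
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.std([2, 4], ddof=1))  # 1.414...

    def test_poisson_detection_mean_recovered(self):
        rng = np.random.default_rng(21)
        observations = []
        for k in keys9("carp"):
            n = rng.poisson(30)
            seqs = {"".join(rng.choice(list("ACDEFGHILMNPQSTVWY"), 8)) + "K" for _ in range(n)}
            observations += [obs(k, s) for s in seqs]
        _, mean, sd = protein_peptide_stats(observations, keys9("carp"))["P1"]
        assert abs(mean - 30) <= 3

    def test_report_filter_requires_min_peptides_everywhere(self):
        # P1 has 2 peptides in every file; P2 has 1 everywhere; P3 misses a file
        observations = []
        for i, k in enumerate(keys9("carp")):
            observations += [obs(k, "AAAAAAK", "P1"), obs(k, "CCCCCCCK", "P1")]
            observations += [obs(k, "DDDDDDR", "P2")]
            if i > 0:
                observations += [obs(k, "EEEEEEK", "P3"), obs(k, "FFFFFFR", "P3")]
        kept = protein_report_filter(observations, keys9("carp"), min_peptides=2)
        assert set(kept) == {"P1"}
        everything = protein_report_filter(observations, keys9("carp"), min_peptides=0)
        assert set(everything) == {"P1", "P2", "P3"}
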