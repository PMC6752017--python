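import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from fermstoich.community_response import (
    AbundanceTable,
    SampleMeta,
    aggregate_by_rank,
    bray_curtis,
    chao1,
    cluster_group_phylotypes,
    net_increase,
    net_increase_matrix,
    pairwise_identity,
    rarefaction_curve,
    screen_phylotypes,
    shannon,
)
from fermstoich.synthetic_data import simulate_sequences


def _table(columns, samples, taxa=("ptA", "ptB", "ptC"), lineage=None, validate=True):
    data = pd.DataFrame(columns, index=list(taxa))
    return AbundanceTable(data, samples, lineage=lineage, validate=validate)


class TestSampleMeta:
    def test_pooled_has_no_replicate(self):
        assert SampleMeta("glu", "t0", "DNA").replicate is None

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"time": "start"},
            {"molecule": "protein"},
            {"replicate": 0},
        ],
    )
    def test_invalid(self, kwargs):
        base = dict(treatment="glu", time="t0", molecule="DNA")
        with pytest.raises(ValueError):
            SampleMeta(**{**base, **kwargs})


class TestAbundanceTable:
    def test_rejects_bad_sums(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _table(
                {"s1": [0.5, 0.2, 0.1]},
                {"s1": SampleMeta("glu", "t0", "DNA")},
            )

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            _table(
                {"s1": [1.2, -0.1, -0.1]},
                {"s1": SampleMeta("glu", "t0", "DNA")},
            )

    def test_missing_meta(self):
        with pytest.raises(ValueError, match="metadata"):
            _table({"s1": [0.5, 0.3, 0.2]}, {})

    def test_missing_cell_named_in_error(self, hand_table):
        with pytest.raises(KeyError, match="RNA"):
            hand_table.mean_profile("glu", "t0", "RNA")


class TestNetIncrease:
    def test_hand_worked_steps(self, hand_table):
        """2%->10% treatment vs 3%->4% control gives a 7-point net."""
        res = net_increase(hand_table, "glu", "control", "DNA")
        assert res.net["ptA"] == pytest.approx(7.0, abs=1e-12)
        assert res.delta_treatment["ptA"] == pytest.approx(8.0, abs=1e-12)
        assert res.delta_control["ptA"] == pytest.approx(1.0, abs=1e-12)

    def test_negative_control_delta_ignored(self):
        samples = {
            "g0": SampleMeta("glu", "t0", "DNA"),
            "g1": SampleMeta("glu", "t_end", "DNA"),
            "c0": SampleMeta("control", "t0", "DNA"),
            "c1": SampleMeta("control", "t_end", "DNA"),
        }
        table = _table(
            {
                "g0": [0.02, 0.5, 0.48],
                "g1": [0.08, 0.5, 0.42],
                "c0": [0.03, 0.5, 0.47],
                "c1": [0.02, 0.5, 0.48],
            },
            samples,
        )
        res = net_increase(table, "glu", "control", "DNA")
        assert res.net["ptA"] == pytest.approx(6.0, abs=1e-12)

    def test_identical_treatment_and_control(self, hand_table):
        data = hand_table.data.copy()
        data[["glu_t0", "glu_t1"]] = data[["ctl_t0", "ctl_t1"]].values
        table = AbundanceTable(data, hand_table.samples)
        res = net_increase(table, "glu", "control", "DNA")
        # control delta is positive for ptA, negative deltas ignored elsewhere
        assert res.net["ptA"] == pytest.approx(0.0, abs=1e-12)

    def test_replicate_means_vs_pooled(self):
        samples = {
            "g0": SampleMeta("glu", "t0", "DNA"),  # pooled single
            "g1a": SampleMeta("glu", "t_end", "DNA", 1),
            "g1b": SampleMeta("glu", "t_end", "DNA", 2),
            "c0": SampleMeta("control", "t0", "DNA"),
            "c1": SampleMeta("control", "t_end", "DNA"),
        }
        table = _table(
            {
                "g0": [0.02, 0.5, 0.48],
                "g1a": [0.06, 0.5, 0.44],
                "g1b": [0.10, 0.5, 0.40],
                "c0": [0.02, 0.5, 0.48],
                "c1": [0.02, 0.5, 0.48],
            },
            samples,
        )
        res = net_increase(table, "glu", "control", "DNA")
        assert res.net["ptA"] == pytest.approx(6.0, abs=1e-12)  # mean of 4 and 8

    def test_compositional_closure(self, hand_table):
        """Signed time-corrected deltas sum to zero within one sample pair."""
        res = net_increase(hand_table, "glu", "control", "DNA")
        assert res.delta_treatment.sum() == pytest.approx(0.0, abs=1e-9)
        assert res.delta_control.sum() == pytest.approx(0.0, abs=1e-9)

    def test_constant_taxon_invariance(self, hand_table):
        """A taxon flat across all samples leaves other nets unchanged."""
        res0 = net_increase(hand_table, "glu", "control", "DNA")
        data = hand_table.data.copy()
        data.loc["ptD"] = 0.05  # constant; sums now 1.05, renormalization off
        table = AbundanceTable(data, hand_table.samples, validate=False)
        res1 = net_increase(table, "glu", "control", "DNA")
        for taxon in ("ptA", "ptB", "ptC"):
            assert res1.signed[taxon] == pytest.approx(res0.signed[taxon], abs=1e-12)
        assert res1.signed["ptD"] == pytest.approx(0.0, abs=1e-12)


class TestAggregateByRank:
    def _family_table(self):
        samples = {
            "g0": SampleMeta("glu", "t0", "DNA"),
            "g1": SampleMeta("glu", "t_end", "DNA"),
            "c0": SampleMeta("control", "t0", "DNA"),
            "c1": SampleMeta("control", "t_end", "DNA"),
        }
        # two phylotypes of one family with nets 3 and 2 -> family net 5
        data = pd.DataFrame(
            {
                "g0": [0.02, 0.03, 0.95],
                "g1": [0.05, 0.05, 0.90],
                "c0": [0.02, 0.03, 0.95],
                "c1": [0.02, 0.03, 0.95],
            },
            index=["pt1", "pt2", "pt3"],
        )
        lineage = {
            "pt1": "PhylumX;FamilyA",
            "pt2": "PhylumX;FamilyA",
            "pt3": "PhylumY;FamilyB",
        }
        return AbundanceTable(data, samples, lineage=lineage)

    def test_sum_before_screen(self):
        table = self._family_table()
        fams = aggregate_by_rank(table, "family", 4.0, ["glu"], "control", ["DNA"])
        assert list(fams.index) == ["FamilyA"]
        assert fams.loc["FamilyA", ("glu", "DNA")] == pytest.approx(5.0, abs=1e-12)

    def test_threshold_zero_keeps_all(self):
        table = self._family_table()
        fams = aggregate_by_rank(table, "family", 0.0, ["glu"], "control", ["DNA"])
        assert set(fams.index) == {"FamilyA", "FamilyB"}

    def test_sum_after_alternative(self):
        table = self._family_table()
        fams = aggregate_by_rank(
            table, "family", 4.0, ["glu"], "control", ["DNA"], order="sum-after"
        )
        assert fams.loc["FamilyA", ("glu", "DNA")] == pytest.approx(5.0, abs=1e-12)

    def test_unresolved_rank_labelled(self):
        table = self._family_table()
        table.lineage["pt3"] = "PhylumY"
        labels = table.rank_labels("family")
        assert labels["pt3"] == "unclassified-PhylumY"


class TestScreenPhylotypes:
    def _result(self, nets):
        samples = {
            "g0": SampleMeta("glu", "t0", "DNA"),
            "g1": SampleMeta("glu", "t_end", "DNA"),
            "c0": SampleMeta("control", "t0", "DNA"),
            "c1": SampleMeta("control", "t_end", "DNA"),
        }
        taxa = list(nets)
        fractions = np.array([nets[t] / 100.0 for t in taxa])
        filler = 1.0 - fractions.sum()
        g0 = [0.0] * len(taxa) + [1.0]
        g1 = list(fractions) + [filler]
        base = [0.0] * len(taxa) + [1.0]
        data = pd.DataFrame(
            {"g0": g0, "g1": g1, "c0": base, "c1": base}, index=taxa + ["filler"]
        )
        return net_increase(
            AbundanceTable(data, samples), "glu", "control", "DNA"
        )

    def test_threshold_is_inclusive(self):
        res = self._result({"pt_hit": 2.0, "pt_miss": 1.99})
        assert screen_phylotypes([res]) == ["pt_hit"]

    def test_all_zero_empty(self):
        res = self._result({"ptX": 0.0})
        assert screen_phylotypes([res]) == []


class TestClustering:
    def test_identical_pair_one_group(self):
        seqs = simulate_sequences(2, 250, [1.0, 1.0], seed=0)
        groups = cluster_group_phylotypes(seqs)
        assert len(groups) == 1 and len(groups[0].members) == 2

    def test_96_percent_not_merged_at_97(self):
        seqs = simulate_sequences(2, 250, [1.0, 0.96], seed=1)
        groups = cluster_group_phylotypes(seqs, identity_threshold=0.97)
        assert len(groups) == 2

    def test_three_sequence_expected_grouping(self):
        # A~B at 98%, C at 90% to both -> {A,B},{C}
        seqs = simulate_sequences(3, 250, [1.0, 0.98, 0.90], seed=2)
        groups = cluster_group_phylotypes(seqs, {"pt001": 9.0, "pt002": 5.0, "pt003": 3.0})
        membership = {g.representative: sorted(g.members) for g in groups}
        assert membership == {"pt001": ["pt001", "pt002"], "pt003": ["pt003"]}

    def test_seed_order_by_net_then_id(self):
        seqs = simulate_sequences(2, 250, [1.0, 0.98], seed=3)
        groups = cluster_group_phylotypes(seqs, {"pt001": 1.0, "pt002": 8.0})
        assert groups[0].representative == "pt002"

    def test_within_group_identity_bound(self):
        seqs = {}
        for fam_seed in range(3):
            fam = simulate_sequences(
                3, 200, [1.0, 0.99, 0.98], seed=fam_seed, prefix=f"f{fam_seed}_"
            )
            seqs.update(fam)
        groups = cluster_group_phylotypes(seqs)
        for g in groups:
            for member in g.members:
                assert (
                    pairwise_identity(seqs[g.representative], seqs[member]) >= 0.97
                )

    def test_rejects_bad_alphabet_and_empty(self):
        with pytest.raises(ValueError, match="pt_bad"):
            cluster_group_phylotypes({"pt_bad": "ACGTZZ"})
        with pytest.raises(ValueError):
            cluster_group_phylotypes({})

    def test_identity_end_gaps_free(self):
        # a 5' overhang must not count against identity
        assert pairwise_identity("AAAACGTACGT", "CGTACGT") == pytest.approx(1.0)


class TestDiversity:
    def test_shannon_single_and_uniform(self):
        assert shannon([1.0]) == 0.0
        assert shannon([0.1] * 10) == pytest.approx(np.log(10))

    def test_shannon_hand_value(self):
        p = [0.5, 0.3, 0.2]
        expected = -sum(x * np.log(x) for x in p)
        assert shannon(p) == pytest.approx(expected, abs=1e-12)

    def test_shannon_matches_skbio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = [20, 10, 5, 1, 1]
        assert shannon(counts) == pytest.approx(
            skbio_alpha.shannon(counts, base=np.e)
        )

    def test_shannon_rejects_negative(self):
        with pytest.raises(ValueError):
            shannon([0.5, -0.5])

    def test_chao1_cases(self):
        assert chao1([5, 4, 3]) == 3  # no singletons -> S_obs
        counts = [1] * 4 + [2] * 2 + [5] * 4  # S=10, F1=4, F2=2
        assert chao1(counts) == pytest.approx(12.0)
        assert chao1([1] * 5) == pytest.approx(15.0)

    def test_chao1_matches_skbio(self):
        skbio_alpha = pytest.importorskip("skbio.diversity.alpha")
        counts = [1, 1, 2, 3, 10, 1, 2]
        assert chao1(counts) == pytest.approx(skbio_alpha.chao1(counts, bias_corrected=True))

    def test_chao1_rejects_non_integer(self):
        with pytest.raises(ValueError):
            chao1([1.5, 2.0])

    def test_rarefaction_endpoints(self):
        counts = [5, 3, 2]
        assert rarefaction_curve(counts, [10])[0] == pytest.approx(3.0)
        assert rarefaction_curve(counts, [1])[0] == pytest.approx(1.0)

    def test_rarefaction_matches_monte_carlo(self):
        counts = np.array([12, 6, 3, 2, 1, 1])
        depth = 10
        rng = np.random.default_rng(7)
        pool = np.repeat(np.arange(len(counts)), counts)
        draws = np.array(
            [
                len(np.unique(rng.choice(pool, size=depth, replace=False)))
                for _ in range(10_000)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert rarefaction_curve(counts, [depth])[0] == pytest.approx(
            draws.mean(), abs=3 * se
        )

    def test_rarefaction_depth_bound(self):
        with pytest.raises(ValueError):
            rarefaction_curve([3, 2], [6])

    def test_bray_curtis_cases(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0, 0], [0, 2, 3]) == 1.0
        assert bray_curtis([3, 1, 0], [1, 1, 2]) == pytest.approx(0.5)

    def test_bray_curtis_matches_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b = rng.random(6), rng.random(6)
            assert bray_curtis(a, b) == pytest.approx(scipy_braycurtis(a, b))

    def test_bray_curtis_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])
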