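import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from driftome.community import (
    CommunityTable,
    alpha_diversity,
    bray_curtis,
    classify_and_partition,
    core_taxa,
    dysbiosis_score,
    merge_replicates,
    rarefy,
    weighted_rrna_trait,
)
from conftest import toy_community


class TestRarefy:
    def make_table(self, totals, n_taxa=6, seed=0):
        rng = np.random.default_rng(seed)
        counts = {}
        for i, tot in enumerate(totals):
            v = rng.multinomial(tot, np.full(n_taxa, 1 / n_taxa))
            counts[f"s{i}"] = dict(zip([f"t{j}" for j in range(n_taxa)], v))
        status = {f"s{i}": "non_raft" for i in range(len(totals))}
        return toy_community(counts, status)

    def test_sums_equal_depth(self):
        t = rarefy(self.make_table([5000, 6000, 4500]), depth=4000, seed=1)
        assert (t.counts.sum(axis=1) == 4000).all()

    def test_shallow_sample_dropped(self):
        t = rarefy(self.make_table([5000, 3999]), depth=4000, seed=1)
        assert list(t.counts.index) == ["s0"]

    def test_exact_depth_unchanged(self):
        tab = self.make_table([4000, 5000])
        t = rarefy(tab, depth=4000, seed=1)
        np.testing.assert_array_equal(
            t.counts.loc["s0"].to_numpy(), tab.counts.loc["s0"].to_numpy()
        )

    def test_support_preserved(self):
        tab = self.make_table([8000, 9000])
        tab.counts.iloc[:, 2] = 0
        t = rarefy(tab, depth=4000, seed=2)
        assert (t.counts.iloc[:, 2] == 0).all()

    def test_deterministic(self):
        tab = self.make_table([9000, 9001])
        a = rarefy(tab, depth=4000, seed=3)
        b = rarefy(tab, depth=4000, seed=3)
        assert a.counts.equals(b.counts)

    def test_richness_monotone_in_depth_expectation(self):
        rng = np.random.default_rng(4)
        v = rng.multinomial(20000, np.full(40, 1 / 40))
        tab = toy_community({"s0": dict(zip([f"t{j}" for j in range(40)], v))},
                            {"s0": "non_raft"})
        rich = []
        for depth in (50, 500, 5000):
            r = [
                (rarefy(tab, depth=depth, seed=s).counts.loc["s0"] > 0).sum()
                for s in range(10)
            ]
            rich.append(np.mean(r))
        assert rich[0] <= rich[1] <= rich[2]

    def test_bad_depth(self):
        with pytest.raises(ValueError):
            rarefy(self.make_table([5000]), depth=0)


class TestAlpha:
    def test_uniform_community(self):
        t = toy_community({"s": {"a": 10, "b": 10, "c": 10, "d": 10}}, {"s": "raft"})
        rec = alpha_diversity(t).loc["s"]
        assert rec.richness == 4
        assert rec.shannon == pytest.approx(np.log(4))
        assert rec.pielou == pytest.approx(1.0)

    def test_dominated_community(self):
        t = toy_community({"s": {"a": 3997, "b": 1, "c": 1, "d": 1}}, {"s": "raft"})
        rec = alpha_diversity(t).loc["s"]
        p = np.array([3997, 1, 1, 1]) / 4000
        assert rec.shannon == pytest.approx(-(p * np.log(p)).sum())
        assert rec.pielou < 0.01

    def test_single_taxon_undefined_pielou(self):
        t = toy_community({"s": {"a": 100, "b": 0}}, {"s": "raft"})
        assert np.isnan(alpha_diversity(t).loc["s"].pielou)


class TestBrayCurtis:
    def test_identical_zero(self):
        t = toy_community({"x": {"a": 5, "b": 5}, "y": {"a": 5, "b": 5}},
                          {"x": "raft", "y": "raft"})
        assert bray_curtis(t)["x", "y"] == 0.0

    def test_disjoint_one(self):
        t = toy_community({"x": {"a": 5, "b": 0}, "y": {"a": 0, "b": 5}},
                          {"x": "raft", "y": "raft"})
        assert bray_curtis(t)["x", "y"] == 1.0

    def test_closed_form(self):
        t = toy_community({"x": {"a": 5, "b": 5, "c": 0}, "y": {"a": 0, "b": 5, "c": 5}},
                          {"x": "raft", "y": "raft"})
        assert bray_curtis(t)["x", "y"] == pytest.approx(0.5)

    def test_empty_sample_errors(self):
        t = toy_community({"x": {"a": 5}, "y": {"a": 0}}, {"x": "raft", "y": "raft"})
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(t)

    def test_range(self):
        rng = np.random.default_rng(1)
        counts = {f"s{i}": dict(zip("abcdef", rng.multinomial(100, [1 / 6] * 6)))
                  for i in range(8)}
        t = toy_community(counts, {f"s{i}": "raft" for i in range(8)})
        d = bray_curtis(t).data
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)


class TestDysbiosis:
    def test_one_dimensional_arithmetic(self):
        # points on a line: non-rafts at 0/0.2, rafts at 2/2.2, probe at 3
        pts = np.array([0.0, 0.2, 2.0, 2.2, 3.0])
        d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]),
                           ids=["n1", "n2", "r1", "r2", "p"])
        labels = {"n1": "non_raft", "n2": "non_raft", "r1": "raft", "r2": "raft",
                  "p": "raft"}
        scores = dysbiosis_score(d, labels)
        # probe at 3: |3-0.1| - |3-~2.4| -> positive (dysbiotic)
        assert scores["p"] > 0
        assert scores["n1"] < 0

    def test_equidistant_sample_scores_zero(self):
        # raft centroid (2.5+2.5+1)/3 = 2, non-raft centroid 0; probe at 1
        # is equidistant from both
        pts = np.array([0.0, 0.0, 2.5, 2.5, 1.0])
        d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]),
                           ids=["n1", "n2", "r1", "r2", "m"])
        labels = {"n1": "non_raft", "n2": "non_raft", "r1": "raft", "r2": "raft",
                  "m": "raft"}
        scores = dysbiosis_score(d, labels)
        assert scores["m"] == pytest.approx(0.0, abs=1e-9)

    def test_group_too_small(self):
        d = DistanceMatrix(np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]]),
                           ids=["a", "b", "c"])
        with pytest.raises(ValueError, match=">= 2"):
            dysbiosis_score(d, {"a": "non_raft", "b": "raft", "c": "raft"})

    def test_reference_filter_restricts_centroid(self):
        pts = np.array([0.0, 0.1, 10.0, 2.0, 2.1, 3.0])
        ids = ["n1", "n2", "n3", "r1", "r2", "p"]
        d = DistanceMatrix(np.abs(pts[:, None] - pts[None, :]), ids=ids)
        labels = dict(zip(ids, ["non_raft"] * 3 + ["raft"] * 3))
        full = dysbiosis_score(d, labels)
        filt = dysbiosis_score(d, labels, reference_filter=["n1", "n2"])
        assert filt["p"] != pytest.approx(full["p"])


class TestCore:
    def test_single_driver_taxon(self):
        # taxon a (dominant) varies, b constant -> core = {a}
        counts = {f"s{i}": {"a": 150 + 20 * i, "b": 100} for i in range(6)}
        t = toy_community(counts, {s: "non_raft" for s in counts})
        core = core_taxa(t, stop_fraction=0.03)
        assert list(core.index) == ["a"] or set(core.index) == {"a"}

    def test_column_order_invariance(self):
        rng = np.random.default_rng(2)
        base = np.array([40.0, 30, 15, 10, 5])
        counts = {}
        for i in range(8):
            v = rng.multinomial(1000, base / base.sum())
            counts[f"s{i}"] = dict(zip("abcde", v))
        t1 = toy_community(counts, {s: "non_raft" for s in counts})
        shuffled = {s: {k: counts[s][k] for k in "ecabd"} for s in counts}
        t2 = toy_community(shuffled, {s: "non_raft" for s in counts})
        c1 = core_taxa(t1)
        c2 = core_taxa(t2)
        assert list(c1.index) == list(c2.index)

    def test_too_few_samples(self):
        t = toy_community({"a": {"x": 1}, "b": {"x": 2}}, {"a": "non_raft", "b": "non_raft"})
        with pytest.raises(ValueError, match="4 samples"):
            core_taxa(t)

    def test_enforce_occupancy_filters(self):
        rng = np.random.default_rng(3)
        counts = {}
        for i in range(10):
            row = {"a": 500 + rng.integers(0, 200), "b": 300 + rng.integers(0, 200)}
            row["c"] = int(rng.integers(0, 400)) if i < 4 else 0  # occupancy 0.4
            counts[f"s{i}"] = row
        t = toy_community(counts, {s: "non_raft" for s in counts})
        core = core_taxa(t, stop_fraction=0.0001, enforce_occupancy=True)
        assert (core["occupancy"] >= 0.8).all()


class TestClassify:
    def make(self):
        counts = {
            "n1": {"a": 700, "b": 200, "c": 99, "d": 1},
            "n2": {"a": 650, "b": 250, "c": 100, "d": 0},
            "r1": {"a": 100, "b": 100, "c": 400, "d": 400},
        }
        return toy_community(counts, {"n1": "non_raft", "n2": "non_raft", "r1": "raft"})

    def test_threshold_classification(self):
        t = self.make()
        cls, fracs = classify_and_partition(t, core=["a"], abundance_cutoff=0.001)
        assert cls.classes["a"] == "core"
        assert cls.classes["b"] == "abundant"  # mean non-raft abundance ~22%
        assert cls.classes["c"] == "abundant"  # ~10%
        assert cls.classes["d"] == "rare"  # mean (0.1% + 0%) / 2 = 0.05%

    def test_fractions_sum_to_one(self):
        t = self.make()
        _, fracs = classify_and_partition(t, core=["a"])
        assert np.allclose(fracs.sum(axis=1), 1.0)

    def test_unknown_core_errors(self):
        t = self.make()
        with pytest.raises(ValueError, match="absent"):
            classify_and_partition(t, core=["zz"])

    def test_exact_cutoff_is_rare(self):
        counts = {
            "n1": {"a": 999, "b": 1},
            "n2": {"a": 999, "b": 1},
            "n3": {"a": 999, "b": 1},
            "n4": {"a": 999, "b": 1},
        }
        t = toy_community(counts, {s: "non_raft" for s in counts})
        cls, _ = classify_and_partition(t, core=[], abundance_cutoff=0.001)
        assert cls.classes["b"] == "rare"  # 0.1% is not > 0.1%


class TestTrait:
    def test_even_split(self):
        t = toy_community({"s": {"t1": 50, "t2": 50}}, {"s": "raft"},
                          taxonomy={"t1": "G1", "t2": "G2"})
        tr = weighted_rrna_trait(t, {"G1": 2.0, "G2": 4.0})
        assert tr["s"] == pytest.approx(3.0)

    def test_single_genus(self):
        t = toy_community({"s": {"t1": 80, "t2": 20}}, {"s": "raft"},
                          taxonomy={"t1": "G1", "t2": "G1"})
        tr = weighted_rrna_trait(t, {"G1": 7.0})
        assert tr["s"] == pytest.approx(7.0)

    def test_unknown_genus_renormalized(self):
        t = toy_community({"s": {"t1": 50, "t2": 50}}, {"s": "raft"},
                          taxonomy={"t1": "G1", "t2": "Gx"})
        tr = weighted_rrna_trait(t, {"G1": 2.0})
        assert tr["s"] == pytest.approx(2.0)

    def test_no_known_genus_flagged(self):
        t = toy_community({"s": {"t1": 50}}, {"s": "raft"}, taxonomy={"t1": "Gx"})
        tr = weighted_rrna_trait(t, {"G1": 2.0})
        assert np.isnan(tr["s"])

    def test_case_insensitive_match(self):
        t = toy_community({"s": {"t1": 50}}, {"s": "raft"}, taxonomy={"t1": "g1"})
        tr = weighted_rrna_trait(t, {"G1": 5.0})
        assert tr["s"] == pytest.approx(5.0)


class TestMerge:
    def test_replicates_summed(self):
        counts = {"a_1": {"x": 10, "y": 0}, "a_2": {"x": 5, "y": 5},
                  "b_1": {"x": 1, "y": 1}}
        t = toy_community(counts, {s: "non_raft" for s in counts})
        t.metadata["individual"] = ["a", "a", "b"]
        merged = merge_replicates(t, "individual")
        assert merged.counts.loc["a", "x"] == 15
        assert merged.counts.loc["a", "y"] == 5
        assert len(merged.samples) == 2
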