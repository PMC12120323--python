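"""Hour-bin grouping, simple-ratio index, assortativity and its null test."""

import numpy as np
import pandas as pd
import pytest

import telemeshare as tm
from telemeshare.social import AssociationNetwork, _mixing_r

from conftest import build_dataset, make_detections, make_receivers, make_tags

RX = [("R1", 25.8, "marine"), ("R2", 26.0, "marine"), ("R3", 26.4, "marine")]


def _dataset(rows, n_ind=2, species=None):
    specs = []
    for i in range(n_ind):
        specs.append(
            dict(
                transmitter_id=f"T{i + 1}",
                species=(species or ["C_taurus"] * n_ind)[i],
                tag_date="2014-01-01",
            )
        )
    return build_dataset(make_detections(rows), make_tags(specs), make_receivers(RX))


def _net_from_weights(W, individuals=None, traits=None):
    individuals = individuals or [f"I{i}" for i in range(len(W))]
    return AssociationNetwork(
        individuals=individuals,
        traits=traits,
        sri=pd.DataFrame(W, index=individuals, columns=individuals),
        counts={},
        zero_denominator_pairs=[],
    )


class TestGrouping:
    def test_same_bin_same_receiver_one_group(self):
        ds = _dataset(
            [("2015-01-01T10:10:00", "T1", "R1"), ("2015-01-01T10:50:00", "T2", "R1")]
        )
        groups = tm.group_by_window(ds)
        assert len(groups) == 1
        assert groups["members"].iloc[0] == frozenset({"T1", "T2"})

    def test_bin_boundary_splits_groups(self):
        ds = _dataset(
            [("2015-01-01T10:59:00", "T1", "R1"), ("2015-01-01T11:01:00", "T2", "R1")]
        )
        groups = tm.group_by_window(ds)
        assert len(groups) == 2
        assert all(len(m) == 1 for m in groups["members"])

    def test_empty_period_fatal(self, sim_dataset):
        with pytest.raises(ValueError):
            tm.group_by_window(sim_dataset, start="1990-01-01", end="1990-02-01")

    def test_matches_bruteforce_bucketing(self, sim_dataset):
        groups = tm.group_by_window(sim_dataset)
        det = sim_dataset.detections
        expected = {}
        for r in det.itertuples(index=False):
            key = (r.timestamp.floor("h"), r.receiver_id)
            expected.setdefault(key, set()).add(r.transmitter_id)
        got = {
            (r.bin, r.receiver_id): set(r.members)
            for r in groups.itertuples(index=False)
        }
        assert got == expected


class TestSimpleRatioIndex:
    def test_always_together_sri_one(self):
        rows = []
        for h in range(10):
            rows.append((f"2015-01-01T{h:02d}:05:00", "T1", "R1"))
            rows.append((f"2015-01-01T{h:02d}:45:00", "T2", "R1"))
        ds = _dataset(rows)
        net = tm.simple_ratio_index(tm.group_by_window(ds))
        assert net.sri.loc["T1", "T2"] == 1.0

    def test_never_together_sri_zero(self):
        rows = [(f"2015-01-01T{h:02d}:00:00", "T1", "R1") for h in range(5)]
        rows += [(f"2015-01-02T{h:02d}:00:00", "T2", "R2") for h in range(5)]
        ds = _dataset(rows)
        net = tm.simple_ratio_index(tm.group_by_window(ds))
        assert net.sri.loc["T1", "T2"] == 0.0

    def test_hand_counted_schedule(self):
        """x=2, y_AB=1, y_A=3, y_B=2 -> SRI = 2/8 = 0.25."""
        rows = []
        # two periods together at R1
        rows += [("2015-01-01T00:10:00", "T1", "R1"), ("2015-01-01T00:20:00", "T2", "R1")]
        rows += [("2015-01-01T01:10:00", "T1", "R1"), ("2015-01-01T01:20:00", "T2", "R1")]
        # one period both seen, different receivers
        rows += [("2015-01-01T02:10:00", "T1", "R1"), ("2015-01-01T02:20:00", "T2", "R2")]
        # three periods only T1
        rows += [(f"2015-01-01T0{h}:10:00", "T1", "R1") for h in (3, 4, 5)]
        # two periods only T2
        rows += [(f"2015-01-01T0{h}:10:00", "T2", "R2") for h in (6, 7)]
        ds = _dataset(rows)
        net = tm.simple_ratio_index(tm.group_by_window(ds))
        assert net.counts["x"].loc["T1", "T2"] == 2
        assert net.counts["y_ab"].loc["T1", "T2"] == 1
        assert net.counts["y_a"].loc["T1", "T2"] == 3
        assert net.counts["y_b"].loc["T1", "T2"] == 2
        assert net.sri.loc["T1", "T2"] == pytest.approx(0.25)

    def test_symmetry_range_and_zero_diagonal(self, sim_dataset):
        net = tm.simple_ratio_index(tm.group_by_window(sim_dataset))
        W = net.sri.to_numpy()
        np.testing.assert_allclose(W, W.T)
        assert (W >= 0).all() and (W <= 1).all()
        assert np.all(np.diag(W) == 0)

    def test_invariant_to_period_relabeling(self):
        rows = [
            ("2015-01-01T00:10:00", "T1", "R1"), ("2015-01-01T00:20:00", "T2", "R1"),
            ("2015-01-01T05:10:00", "T1", "R2"),
            ("2015-01-02T07:10:00", "T2", "R1"),
        ]
        ds = _dataset(rows)
        groups = tm.group_by_window(ds)
        shuffled = groups.copy()
        mapping = {p: 1000 - p for p in shuffled["sampling_period"].unique()}
        shuffled["sampling_period"] = shuffled["sampling_period"].map(mapping)
        a = tm.simple_ratio_index(groups).sri
        b = tm.simple_ratio_index(shuffled).sri
        pd.testing.assert_frame_equal(a, b)


def _assort_oracle(W, labels):
    """Brute-force weighted mixing-matrix assortativity (independent loops)."""
    classes = sorted(set(labels))
    e = {(a, b): 0.0 for a in classes for b in classes}
    n = len(W)
    for i in range(n):
        for j in range(n):
            e[(labels[i], labels[j])] += W[i][j]
    total = sum(e.values())
    e = {k: v / total for k, v in e.items()}
    a = {c: sum(e[(c, d)] for d in classes) for c in classes}
    b = {d: sum(e[(c, d)] for c in classes) for d in classes}
    trace = sum(e[(c, c)] for c in classes)
    ab = sum(a[c] * b[c] for c in classes)
    return (trace - ab) / (1 - ab)


class TestAssortativity:
    def test_within_class_only_r_one(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.7
        W[2, 3] = W[3, 2] = 0.2
        net = _net_from_weights(W)
        assert tm.assortativity(net, ["a", "a", "b", "b"]) == pytest.approx(1.0)

    def test_between_class_only_r_minus_one(self):
        W = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                W[i, j] = W[j, i] = 0.5
        net = _net_from_weights(W)
        assert tm.assortativity(net, ["a", "a", "b", "b"]) == pytest.approx(-1.0)

    def test_matches_bruteforce_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = 12
            W = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            labels = rng.choice(["x", "y", "z"], n)
            if len(set(labels)) < 2 or W.sum() == 0:
                continue
            net = _net_from_weights(W)
            assert tm.assortativity(net, labels) == pytest.approx(
                _assort_oracle(W, list(labels)), abs=1e-12
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        W = rng.random((10, 10))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = tm.assortativity(_net_from_weights(W), labels)
        r2 = tm.assortativity(_net_from_weights(2 * W), labels)
        assert r1 == pytest.approx(r2, abs=1e-14)

    def test_empty_network_error(self):
        net = _net_from_weights(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="empty network"):
            tm.assortativity(net, ["a", "a", "b", "b"])

    def test_single_class_error(self):
        W = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            tm.assortativity(_net_from_weights(W), ["a", "a", "a", "a"])


class TestNodePermutationTest:
    def test_perfect_assortment_small_p(self):
        n = 12
        W = np.zeros((n, n))
        labels = ["a"] * 6 + ["b"] * 6
        for i in range(n):
            for j in range(n):
                if i != j and labels[i] == labels[j]:
                    W[i, j] = 1.0
        res = tm.node_permutation_test(_net_from_weights(W), labels, n_perm=1000, seed=0)
        assert res.observed_r == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_scale_invariance_of_p(self):
        rng = np.random.default_rng(2)
        W = rng.random((14, 14))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        labels = ["a"] * 7 + ["b"] * 7
        r1 = tm.node_permutation_test(_net_from_weights(W), labels, n_perm=200, seed=5)
        r2 = tm.node_permutation_test(_net_from_weights(3 * W), labels, n_perm=200, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.observed_r == pytest.approx(r2.observed_r, abs=1e-14)

    def test_permuted_mean_near_zero(self):
        rng = np.random.default_rng(3)
        n = 30
        W = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        labels = rng.choice(["a", "b", "c"], n)
        res = tm.node_permutation_test(_net_from_weights(W), labels, n_perm=500, seed=4)
        assert abs(res.permuted_r.mean()) < 0.05

    def test_p_bounds_and_constant_trait_error(self):
        rng = np.random.default_rng(4)
        W = rng.random((8, 8))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        res = tm.node_permutation_test(
            _net_from_weights(W), ["a"] * 4 + ["b"] * 4, n_perm=100, seed=0
        )
        assert 1 / 101 <= res.p_value <= 1.0
        with pytest.raises(ValueError):
            tm.node_permutation_test(_net_from_weights(W), ["a"] * 8, n_perm=100)

    def test_generator_assortment_raises_observed_r(self):
        import dataclasses
        from conftest import SMALL_SCENARIO

        base = dataclasses.replace(
            SMALL_SCENARIO,
            study_span=("2014-10-01", "2015-09-30"),
            n_individuals={("C_taurus", "subadult"): 10, ("C_carcharias", "juvenile"): 10},
            seed=31,
        )
        rs = []
        for alpha in (0.0, 0.5):
            res = tm.simulate_detections(dataclasses.replace(base, assortment_strength=alpha))
            ds = tm.filter_dataset(res.detections, res.tags, res.receivers)
            net = tm.build_association_network(ds)
            rs.append(tm.assortativity(net, "species"))
        assert rs[1] > rs[0]


class TestEndToEnd:
    def test_traits_attached_and_only_detected_individuals(self, sim_dataset):
        net = tm.build_association_network(
            sim_dataset, start="2014-10-01", end="2015-10-01"
        )
        assert set(net.individuals) <= set(sim_dataset.individuals)
        assert list(net.traits.index) == net.individuals
        assert set(net.traits.columns) == {"species", "life_stage"}
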