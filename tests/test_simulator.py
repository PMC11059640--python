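"""CNA simulator: position density, event laws, profile construction, noise."""

import numpy as np
import pytest
from scipy import stats

from cnphylo import (CNAEvent, CopyNumberMatrix, PositionDensity,
                     add_estimation_noise, events_to_profiles,
                     overlap_fraction, random_ultrametric_tree,
                     sample_position, simulate_events)
from cnphylo.simulator import GENOME_LENGTH
from conftest import make_tree


class TestPositionDensity:
    def test_uniform_when_a_is_zero(self):
        rng = np.random.default_rng(0)
        density = PositionDensity.build(0.0, rng)
        draws = density.sample(rng, 100_000)
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_histogram_matches_constructed_density(self):
        rng = np.random.default_rng(1)
        density = PositionDensity.build(0.6, rng)
        n = 200_000
        draws = density.sample(rng, n)
        edges = np.linspace(0, 1, 41)
        counts, _ = np.histogram(draws, edges)
        grid_mass = np.array([
            density._pdf[int(lo * density.grid_size):
                         int(hi * density.grid_size)].sum()
            / density.grid_size
            for lo, hi in zip(edges[:-1], edges[1:])])
        expected = grid_mass * n
        sd = np.sqrt(expected * (1 - grid_mass))
        assert np.all(np.abs(counts - expected) < 5 * sd + 5)

    def test_draws_stay_in_unit_interval(self):
        rng = np.random.default_rng(2)
        density = PositionDensity.build(1.2, rng)
        draws = density.sample(rng, 10_000)
        assert draws.min() >= 0.0 and draws.max() < 1.0
        x = sample_position(density, rng)
        assert 0.0 <= x < 1.0

    def test_negative_a_rejected(self):
        with pytest.raises(ValueError):
            PositionDensity.build(-0.1, np.random.default_rng(0))


class TestSimulateEvents:
    def test_zero_length_branch_has_no_events(self):
        tree = make_tree("(a:0.4,b:0.4);", d=0.0)
        rng = np.random.default_rng(3)
        density = PositionDensity.build(0.0, rng)
        events = simulate_events(tree, 50.0, density, rng)
        root_id = tree.root.id
        assert not any(e.branch_id == root_id for e in events)

    def test_poisson_mean_event_count(self):
        # two branches of duration 1 each, no stem: expected c*2 events
        tree = make_tree("(a:1.0,b:1.0);", d=0.0)
        rng = np.random.default_rng(4)
        density = PositionDensity.build(0.0, rng)
        c = 125.0
        counts = [len(simulate_events(tree, c, density, rng))
                  for _ in range(300)]
        mean = np.mean(counts)
        se = np.sqrt(2 * c / 300)
        assert abs(mean - 2 * c) < 4 * se

    def test_poisson_totals_goodness_of_fit(self):
        tree = make_tree("(a:0.5,b:0.5);", d=0.5)
        rng = np.random.default_rng(5)
        density = PositionDensity.build(0.0, rng)
        lam = 4.0 * 1.5  # c times total branch length (incl. stem)
        counts = np.array([len(simulate_events(tree, 4.0, density, rng))
                           for _ in range(400)])
        edges = [-0.5, 2.5, 4.5, 6.5, 8.5, np.inf]
        obs = np.histogram(counts, edges)[0]
        cdf = stats.poisson(lam).cdf
        probs = np.diff([0] + [cdf(e) for e in edges[1:-1]] + [1])
        chi2 = ((obs - 400 * probs) ** 2 / (400 * probs)).sum()
        assert chi2 < stats.chi2(len(obs) - 1).ppf(0.999)

    def test_mean_event_size_is_shifted_exponential(self):
        tree = make_tree("(a:1.0,b:1.0);", d=1.0)
        rng = np.random.default_rng(6)
        density = PositionDensity.build(0.0, rng)
        sizes = []
        while len(sizes) < 10_000:
            sizes += [e.length_bp
                      for e in simulate_events(tree, 2000.0, density, rng)]
        mean_mbp = np.mean(sizes) / 1e6
        assert abs(mean_mbp - 12.0) < 0.5
        assert min(sizes) >= 2e6

    def test_allele_and_sign_balance(self):
        tree = make_tree("(a:1.0,b:1.0);", d=1.0)
        rng = np.random.default_rng(7)
        density = PositionDensity.build(0.0, rng)
        events = simulate_events(tree, 3000.0, density, rng)
        assert abs(np.mean([e.allele for e in events]) - 0.5) < 0.03
        assert abs(np.mean([e.sign > 0 for e in events]) - 0.5) < 0.03

    def test_determinism_under_fixed_seed(self):
        tree = make_tree("(a:0.7,b:0.7);", d=0.3)
        density = PositionDensity.build(0.6, np.random.default_rng(8))
        e1 = simulate_events(tree, 40.0, density, np.random.default_rng(9))
        e2 = simulate_events(tree, 40.0, density, np.random.default_rng(9))
        assert [(e.branch_id, e.start, e.length_bp, e.sign, e.allele)
                for e in e1] == \
               [(e.branch_id, e.start, e.length_bp, e.sign, e.allele)
                for e in e2]


class TestOverlapFraction:
    def _event(self, start, length_bp):
        return CNAEvent(0, 0, start, length_bp, 1, 0.5)

    def test_single_event_zero(self):
        assert overlap_fraction([self._event(0.1, 5e6)]) == 0.0

    def test_identical_pair_is_one(self):
        evs = [self._event(0.1, 5e6), self._event(0.1, 5e6)]
        assert overlap_fraction(evs) == 1.0

    def test_disjoint_intervals_zero(self):
        evs = [self._event(0.0, 0.1 * GENOME_LENGTH),
               self._event(0.5, 0.1 * GENOME_LENGTH)]
        assert overlap_fraction(evs) == 0.0

    def test_mixed_configuration(self):
        # [0,.3) overlaps [.2,.4); [.8,.9) is isolated
        evs = [self._event(0.0, 0.3 * GENOME_LENGTH),
               self._event(0.2, 0.2 * GENOME_LENGTH),
               self._event(0.8, 0.1 * GENOME_LENGTH)]
        assert overlap_fraction(evs) == pytest.approx(2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction([])


class TestEventsToProfiles:
    def test_no_events_gives_diploid_everywhere(self):
        tree = make_tree("(a:0.4,b:0.4);", d=0.1)
        sim = events_to_profiles(tree, [], n_bins=50)
        assert np.all(sim.true_profiles.values == 2.0)
        assert all(np.all(p == 2) for p in sim.node_profiles.values())

    def test_single_gain_localized_to_one_leaf(self):
        tree = make_tree("(a:0.4,b:0.4);", d=0.1)
        leaf_a = next(l for l in tree.leaves() if l.label == "a")
        # gain covering bins 10..19 of 100
        ev = CNAEvent(leaf_a.id, 0, 0.10, 0.10 * GENOME_LENGTH, 1, 0.5)
        sim = events_to_profiles(tree, [ev], n_bins=100)
        prof = {c: sim.true_profiles.values[i]
                for i, c in enumerate(sim.true_profiles.cell_ids)}
        assert np.all(prof["a"][10:20] == 3)
        assert np.all(prof["a"][:10] == 2) and np.all(prof["a"][20:] == 2)
        assert np.all(prof["b"] == 2)

    def test_loss_floors_at_zero(self):
        tree = make_tree("(a:0.4,b:0.4);", d=0.1)
        leaf_a = next(l for l in tree.leaves() if l.label == "a")
        iv = (0.2, 0.1 * GENOME_LENGTH)
        evs = [CNAEvent(leaf_a.id, 0, *iv, -1, 0.1),
               CNAEvent(leaf_a.id, 0, *iv, -1, 0.5),  # allele already at 0
               CNAEvent(leaf_a.id, 0, *iv, -1, 0.9)]
        sim = events_to_profiles(tree, evs, n_bins=100)
        prof = sim.true_profiles.values[sim.true_profiles.cell_ids.index("a")]
        assert np.all(prof[20:30] == 1)  # only the maternal copy lost

    def test_per_base_oracle_on_handcrafted_events(self):
        """Overlap-weighted binning matches a direct per-base simulation."""
        tree = make_tree("((a:0.2,b:0.2):0.2,c:0.4);", d=0.2)
        nodes = {n.label: n for n in tree.postorder() if n.label}
        cherry = next(n for n in tree.internal_nodes() if not n.is_root)
        G = 1000.0  # tiny genome for the oracle
        evs = [
            CNAEvent(cherry.id, 0, 0.105, 300.0, 1, 0.3),
            CNAEvent(nodes["a"].id, 0, 0.250, 200.0, -1, 0.5),
            CNAEvent(nodes["a"].id, 1, 0.333, 150.0, -1, 0.2),
            CNAEvent(nodes["c"].id, 1, 0.021, 500.0, 1, 0.7),
            CNAEvent(tree.root.id, 0, 0.600, 333.0, 1, 0.1),
        ]
        sim = events_to_profiles(tree, evs, n_bins=10, genome_length=G)

        base = {lbl: np.ones((2, 1000), dtype=int)
                for lbl in ("root_stem", "cherry", "a", "b", "c")}

        def apply(arr, ev):
            s = int(round(ev.start * G))
            e = min(int(round(ev.start * G + ev.length_bp)), 1000)
            if ev.sign > 0:
                arr[ev.allele, s:e] += 1
            else:
                arr[ev.allele, s:e] = np.maximum(arr[ev.allele, s:e] - 1, 0)

        per_base = np.ones((2, 1000), dtype=int)
        apply(per_base, evs[4])                 # stem event (root branch)
        root_cn = per_base.copy()
        cherry_cn = root_cn.copy()
        apply(cherry_cn, evs[0])
        a_cn = cherry_cn.copy()
        apply(a_cn, evs[2])                     # time 0.2 before time 0.5
        apply(a_cn, evs[1])
        c_cn = root_cn.copy()
        apply(c_cn, evs[3])

        def binned(cn):
            tot = cn.sum(axis=0).reshape(10, 100).mean(axis=1)
            return np.floor(tot + 0.5).astype(int)

        prof = {cid: sim.true_profiles.values[i].astype(int)
                for i, cid in enumerate(sim.true_profiles.cell_ids)}
        assert np.array_equal(prof["a"], binned(a_cn))
        assert np.array_equal(prof["b"], binned(cherry_cn))
        assert np.array_equal(prof["c"], binned(c_cn))

    def test_ancestral_truth_consistent_with_path_events(self):
        rng = np.random.default_rng(12)
        tree = random_ultrametric_tree(6, rng)
        density = PositionDensity.build(0.6, rng)
        events = simulate_events(tree, 60.0, density, rng)
        sim = events_to_profiles(tree, events, n_bins=200)
        # recompute an internal node's profile from the event subset on its path
        internal = [n for n in sim.tree.internal_nodes() if not n.is_root][0]
        path_ids = set()
        cur = internal
        while cur is not None:
            path_ids.add(cur.id)
            cur = cur.parent
        sub = [e for e in events if e.branch_id in path_ids]
        resim = events_to_profiles(sim.tree, sub, n_bins=200)
        assert np.array_equal(resim.node_profiles[internal.label],
                              sim.node_profiles[internal.label])

    def test_invalid_bin_count(self):
        tree = make_tree("(a:0.4,b:0.4);")
        with pytest.raises(ValueError):
            events_to_profiles(tree, [], n_bins=0)


class TestEstimationNoise:
    def test_zero_target_is_identity(self):
        D = CopyNumberMatrix(np.full((3, 10), 2.0), ["a", "b", "c"])
        out = add_estimation_noise(D, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.values, D.values)

    def test_median_per_cell_hamming_near_target(self):
        rng = np.random.default_rng(13)
        vals = rng.integers(1, 5, size=(20, 750)).astype(float)
        D = CopyNumberMatrix(vals, [f"c{i}" for i in range(20)])
        out = add_estimation_noise(D, 0.24, rng)
        per_cell = (out.values != D.values).mean(axis=1)
        assert abs(np.median(per_cell) - 0.24) <= 0.03

    def test_outputs_clipped_to_state_space(self):
        rng = np.random.default_rng(14)
        vals = np.concatenate([np.zeros((2, 300)), np.full((2, 300), 9.0)])
        D = CopyNumberMatrix(vals.reshape(4, 300),
                             [f"c{i}" for i in range(4)])
        out = add_estimation_noise(D, 0.4, rng, k=9)
        assert out.values.min() >= 0 and out.values.max() <= 9

    def test_determinism(self):
        vals = np.full((2, 100), 3.0)
        D = CopyNumberMatrix(vals, ["a", "b"])
        o1 = add_estimation_noise(D, 0.3, np.random.default_rng(5))
        o2 = add_estimation_noise(D, 0.3, np.random.default_rng(5))
        assert np.array_equal(o1.values, o2.values)

    def test_invalid_target(self):
        D = CopyNumberMatrix(np.full((1, 5), 2.0), ["a"])
        with pytest.raises(ValueError):
            add_estimation_noise(D, 1.0, np.random.default_rng(0))


def test_high_overlap_under_study_conditions():
    """Nonuniform positions at realistic intensities make >90% of CNAs overlap."""
    rng = np.random.default_rng(21)
    fractions = []
    for c in (90.0, 250.0):
        tree = random_ultrametric_tree(50, rng)
        density = PositionDensity.build(0.6, rng)
        events = simulate_events(tree, c, density, rng)
        fractions.append(overlap_fraction(events))
    assert np.mean(fractions) > 0.9
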