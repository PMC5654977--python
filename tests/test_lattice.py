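"""Hexagonal lattice geometry, clone tree bookkeeping and single-step mechanics."""

import numpy as np
import pytest

from epiclone import lattice as lat
from epiclone._kernels import EMPTY, STEM_A, STEM_B, TA_C


def small_state(width=6, height=6, boundary="torus"):
    n = width * height
    return lat.LatticeState(width, height, boundary,
                            kind=np.full(n, STEM_A, np.int8),
                            label=np.zeros(n, np.int64),
                            q=np.zeros(n, np.int16))


class TestNeighbors:
    def test_torus_interior_has_six_distinct(self):
        for site in [(0, 0), (3, 4), (7, 1)]:
            nb = lat.neighbors(site, (8, 8), "torus")
            assert len(nb) == 6
            assert site not in nb

    @pytest.mark.parametrize("boundary", ["torus", "fixed"])
    def test_symmetry(self, boundary, rng):
        dims = (9, 8)
        for _ in range(200):
            i = (int(rng.integers(9)), int(rng.integers(8)))
            for j in lat.neighbors(i, dims, boundary):
                assert i in lat.neighbors(j, dims, boundary)

    def test_fixed_corner_counts(self):
        # odd-row offset: even-row origin keeps E and SE only
        assert len(lat.neighbors((0, 0), (8, 8), "fixed")) == 2
        # odd-row far corner keeps W and NW; odd-row left corner keeps 3
        assert len(lat.neighbors((7, 7), (8, 8), "fixed")) == 2
        assert len(lat.neighbors((0, 7), (8, 8), "fixed")) == 3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lat.neighbors((8, 0), (8, 8))

    def test_table_matches_reference_function(self, rng):
        for boundary in ("torus", "fixed"):
            tab = lat.build_neighbor_table(5, 4, boundary)
            for _ in range(30):
                x, y = int(rng.integers(5)), int(rng.integers(4))
                got = {divmod(t, 5)[::-1] for t in tab[y * 5 + x] if t >= 0}
                assert got == lat.neighbors((x, y), (5, 4), boundary)


class TestSimParams:
    def test_rejects_negative_rates_and_odd_torus_height(self):
        with pytest.raises(ValueError):
            lat.SimParams(lam=-0.1)
        with pytest.raises(ValueError):
            lat.SimParams(width=10, height=9, cluster_radius=2)
        lat.SimParams(width=10, height=9, cluster_radius=2, boundary="fixed")
        with pytest.raises(ValueError):
            lat.SimParams(width=10, height=10, nu=0.1, cluster_radius=6)

    def test_weekly_rates_convert_to_daily_probabilities(self):
        p = lat.SimParams(lam=0.5, phi=0.25)
        assert p.p_loss_a == pytest.approx(0.5 / 7)
        assert p.p_loss_b == pytest.approx(0.25 / 7)


class TestLatticeEnergy:
    def _hetero_state(self):
        # 6x6 torus, all stem; make site (2,2) surroundings controllable
        return small_state()

    def test_isolated_stem_cell_zero_energy(self):
        s = self._hetero_state()
        s.kind[:] = EMPTY
        site = 2 * 6 + 2
        s.kind[site] = STEM_A
        diff = np.zeros(36, np.uint8)
        assert lat.lattice_energy(site, s, diff, 100.0) == 0.0

    def test_ta_cell_formula(self):
        # TA cell with 3 stem neighbours, 1 empty neighbour, diff=1 -> 3-1+0 = 2
        s = self._hetero_state()
        s.kind[:] = EMPTY
        site = 2 * 6 + 2
        s.kind[site] = TA_C
        nb = [t for t in s.nbr[site] if t >= 0]
        s.kind[nb[0]] = s.kind[nb[1]] = s.kind[nb[2]] = STEM_A
        s.kind[nb[3]] = EMPTY
        s.kind[nb[4]] = s.kind[nb[5]] = TA_C
        diff = np.ones(36, np.uint8)
        # 3 stem − 1 empty + (1−1)·p = 2
        assert lat.lattice_energy(site, s, diff, 100.0) == 2.0

    def test_stem_cell_penalty_outside_cluster(self):
        # stem with 2 TA neighbours on diff=1 ground, p=100 -> 102
        s = self._hetero_state()
        site = 2 * 6 + 2
        nb = [t for t in s.nbr[site] if t >= 0]
        s.kind[nb[0]] = s.kind[nb[1]] = TA_C
        diff = np.ones(36, np.uint8)
        assert lat.lattice_energy(site, s, diff, 100.0) == 102.0

    def test_empty_site_energy_undefined(self):
        s = self._hetero_state()
        s.kind[0] = EMPTY
        with pytest.raises(ValueError):
            lat.lattice_energy(0, s, np.zeros(36, np.uint8), 100.0)

    def test_mutant_stem_counts_as_stem(self):
        s = self._hetero_state()
        site = 2 * 6 + 2
        s.kind[site] = STEM_B
        diff = np.zeros(36, np.uint8)
        assert lat.lattice_energy(site, s, diff, 100.0) == 0.0


class TestCloneTree:
    def test_recursive_size_simple_sum(self):
        tree = lat.CloneTree()
        c1, c2 = tree.add_batch(np.array([0, 0]), 1.0, np.array([1, 1], np.int8))
        (g1,) = tree.add_batch(np.array([c1]), 2.0, np.array([1], np.int8))
        state = small_state(4, 4)
        state.label[:] = 0
        state.label[0] = c1            # parent own count 1
        state.label[1:3] = g1          # child of c1, size 2
        state.label[3:6] = c2          # size 3
        sizes = tree.recursive_sizes(state)
        assert sizes[tree.rows_of(np.array([c1]))[0]] == 3  # 1 + 2
        assert sizes[tree.rows_of(np.array([c2]))[0]] == 3
        assert sizes[0] == 16  # root spans every occupied site

    def test_recursive_sizes_match_brute_force_ancestry(self, rng):
        tree = lat.CloneTree()
        labels = [0]
        for _ in range(50):
            parent = int(rng.choice(labels))
            (new,) = tree.add_batch(np.array([parent]), 1.0, np.array([1], np.int8))
            labels.append(int(new))
        state = small_state(10, 10)
        state.label[:] = rng.choice(labels, size=100)
        parent_of = dict(zip(tree.ids.tolist(), tree.parent.tolist()))
        brute = {l: 0 for l in labels}
        for site_label in state.label:
            l = int(site_label)
            while l != -1:
                brute[l] += 1
                l = parent_of[l]
        sizes = tree.recursive_sizes(state)
        for l in labels:
            assert sizes[tree.rows_of(np.array([l]))[0]] == brute[l]

    def test_unknown_label_rejected(self):
        tree = lat.CloneTree()
        state = small_state(4, 4)
        with pytest.raises(KeyError):
            lat.clone_sizes(state, tree, label=99)

    def test_purge_is_observationally_silent(self):
        p = lat.SimParams(width=20, height=20, duration=200, seed=5)
        res = lat.run(p, purge_interval=10**9)  # no purging during the run
        before = lat.clone_sizes(res.state, res.tree)
        n_before = len(res.tree)
        removed = res.tree.purge(res.state)
        after = lat.clone_sizes(res.state, res.tree)
        assert removed > 0 and len(res.tree) == n_before - removed
        assert np.array_equal(np.sort(before.sizes), np.sort(after.sizes))

    def test_live_counts_sum_to_occupied_sites(self):
        p = lat.SimParams(width=15, height=16, duration=60, seed=2)
        res = lat.run(p)
        assert res.tree.live_counts(res.state).sum() == res.state.n_occupied


class TestStepMechanics:
    def test_zero_rates_freeze_the_lattice(self):
        p = lat.SimParams(width=8, height=8, lam=0, omega=0, theta=0, kappa=0,
                          duration=30, seed=1, cluster_radius=1)
        res = lat.run(p)
        assert np.all(res.state.kind == STEM_A)
        assert np.all(res.state.label == 0)
        assert len(res.tree) == 1

    def test_isolated_death_leaves_site_empty(self):
        # single occupied site, certain death (λ=7/week → daily prob 1),
        # no neighbours to act as donors
        p = lat.SimParams(width=6, height=6, lam=7.0, omega=0, cluster_radius=1)
        state = small_state()
        state.kind[:] = EMPTY
        state.label[:] = -1
        state.kind[14], state.label[14] = STEM_A, 0
        tree = lat.CloneTree()
        rng = np.random.default_rng(0)
        lat.step_homogeneous(state, tree, p, rng)
        assert state.n_occupied == 0
        lat.step_homogeneous(state, tree, p, rng)
        assert state.n_occupied == 0

    def test_site_conservation_and_consistency(self):
        p = lat.SimParams(width=12, height=12, theta=1e-3, phi=0.25,
                          duration=100, seed=9, cluster_radius=3)
        res = lat.run(p)
        assert res.state.kind.size == 144
        occupied = res.state.n_occupied
        assert res.tree.live_counts(res.state).sum() == occupied
        # every lattice label is a live tree record
        assert set(np.unique(res.state.label[res.state.kind != EMPTY])) <= set(
            res.tree.ids.tolist())

    def test_same_seed_reproduces_trajectory(self):
        p = lat.SimParams(width=16, height=16, theta=1e-4, phi=0.1,
                          kappa=0.2, duration=80, seed=77, cluster_radius=4)
        r1, r2 = lat.run(p), lat.run(p)
        assert np.array_equal(r1.state.label, r2.state.label)
        assert np.array_equal(r1.state.kind, r2.state.kind)
        assert np.array_equal(np.sort(r1.samples[80].sizes),
                              np.sort(r2.samples[80].sizes))

    def test_zero_duration_returns_initial_founder_state(self):
        p = lat.SimParams(width=8, height=8, duration=0, cluster_radius=2)
        res = lat.run(p)
        assert np.all(res.state.label == 0)
        assert len(res.samples[0]) == 0  # no mutant clones yet
        with pytest.raises(ValueError):
            lat.run(lat.SimParams(width=8, height=8, duration=-1, cluster_radius=2))

    def test_forced_swap_on_two_site_lattice(self):
        # 2x1 non-wrapping strip: one edge; κ·dt=1 forces the swap each step
        p = lat.SimParams(width=2, height=1, kappa=1.0, lam=0, omega=0,
                          boundary="fixed", cluster_radius=0.4)
        state = lat.LatticeState(2, 1, "fixed",
                                 kind=np.array([STEM_A, STEM_B], np.int8),
                                 label=np.array([0, 1], np.int64),
                                 q=np.zeros(2, np.int16))
        rng = np.random.default_rng(0)
        lat.migrate(state, p, rng)
        assert list(state.label) == [1, 0]
        lat.migrate(state, p, rng)
        assert list(state.label) == [0, 1]

    def test_zero_kappa_never_swaps(self):
        p = lat.SimParams(width=6, height=6, kappa=0.0, lam=0, omega=0,
                          cluster_radius=1)
        state = small_state()
        state.label[:] = np.arange(36)
        tree_labels = state.label.copy()
        lat.migrate(state, p, np.random.default_rng(1))
        assert np.array_equal(state.label, tree_labels)


class TestHeterogeneousMode:
    def test_reduces_to_homogeneous_without_ta_dynamics(self):
        p = lat.SimParams(width=10, height=10, nu=0.0, kappa=0.0, theta=1e-3,
                          phi=0.25, duration=50, seed=4, cluster_radius=2)
        diff = np.zeros(100, np.uint8)
        rng1, rng2 = np.random.default_rng(3), np.random.default_rng(3)
        s1, t1 = small_state(10, 10), lat.CloneTree()
        s2, t2 = small_state(10, 10), lat.CloneTree()
        for _ in range(50):
            lat.step_homogeneous(s1, t1, p, rng1)
            lat.step_heterogeneous(s2, t2, p, diff, rng2)
        assert np.array_equal(s1.label, s2.label)
        assert np.array_equal(s1.kind, s2.kind)

    def test_exhausted_ta_cell_never_divides(self):
        p = lat.SimParams(width=6, height=6, lam=0, omega=0, nu=0,
                          ta_div_rate=1.0, ta_loss_rate=0.0, q_max=3,
                          cluster_radius=1)
        state = small_state()
        state.kind[:] = EMPTY
        state.label[:] = -1
        state.kind[14], state.label[14], state.q[14] = TA_C, 0, 3  # at q_max
        tree = lat.CloneTree()
        rng = np.random.default_rng(0)
        diff = np.ones(36, np.uint8)
        for _ in range(20):
            lat.step_heterogeneous(state, tree, p, diff, rng)
        assert state.n_occupied == 1  # never divided, never lost

    def test_ta_daughters_both_carry_incremented_q(self):
        p = lat.SimParams(width=6, height=6, lam=0, omega=0, nu=0,
                          ta_div_rate=1.0, ta_loss_rate=0.0, q_max=5,
                          cluster_radius=1)
        state = small_state()
        state.kind[:] = EMPTY
        state.label[:] = -1
        state.kind[14], state.label[14], state.q[14] = TA_C, 0, 1
        tree = lat.CloneTree()
        lat.step_heterogeneous(state, tree, p, np.ones(36, np.uint8),
                               np.random.default_rng(0))
        occupied = np.flatnonzero(state.kind == TA_C)
        assert occupied.size >= 2
        assert np.all(state.q[occupied] >= 2)

    def test_differentiation_only_outside_clusters(self):
        p = lat.SimParams(width=8, height=8, lam=0, omega=0, nu=1.0,
                          kappa=0, ta_loss_rate=0.0, cluster_radius=2)
        state = small_state(8, 8)
        diff = np.zeros(64, np.uint8)
        diff[32:] = 1
        tree = lat.CloneTree()
        lat.step_heterogeneous(state, tree, p, diff, np.random.default_rng(0))
        assert np.all(state.kind[:32] == STEM_A)
        assert np.all(state.kind[32:] == TA_C)

    def test_energy_gate_rejects_uphill_swaps_globally(self):
        # random stem/TA mixture: accepted migration moves can only lower
        # the total lattice energy
        rng = np.random.default_rng(8)
        p = lat.SimParams(width=12, height=12, kappa=0.5, lam=0, omega=0,
                          cluster_radius=3)
        diff = lat.make_cluster_diff_map(12, 12, 3.0, 8.0)
        state = small_state(12, 12)
        state.kind[:] = rng.choice([STEM_A, TA_C, EMPTY], size=144,
                                   p=[0.45, 0.45, 0.1])
        state.label[state.kind == EMPTY] = -1
        energies = [lat.total_lattice_energy(state, diff, p.penalty_p)]
        for _ in range(25):
            lat.migrate(state, p, rng, diff_map=diff)
            energies.append(lat.total_lattice_energy(state, diff, p.penalty_p))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)
        assert energies[-1] < energies[0]  # sorting actually happened

    def test_cluster_diff_map_geometry(self):
        diff = lat.make_cluster_diff_map(60, 60, 10.0, 30.0)
        assert diff.min() == 0 and diff.max() == 1
        frac_cluster = 1 - diff.mean()
        # triangular packing of radius-10 disks at 30-cell pitch covers
        # πr²/(√3/2·s²) ≈ 40% of the plane
        assert 0.25 < frac_cluster < 0.55
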