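"""PaCS-MD selection logic, umbrella sampling, MBAR, barriers."""

import numpy as np
import pytest
from scipy.special import logsumexp

from cgbind.dynamics import HarmonicBias, LangevinIntegrator, initial_state
from cgbind.enhanced_sampling import (FreeEnergyProfile, FreeEnergyProfile2D,
                                      UmbrellaWindow, barrier_height,
                                      mbar_solve, pacs_cycle, pacs_run,
                                      pmf_2d, reweight_pmf, targeted_md,
                                      umbrella_centers)
from cgbind.synthetic_data import make_oracle_system
from cgbind.units import KB


class TestMbar:
    def _toy_windows(self, rng, n_win=5, n=1500):
        """Exactly sampled harmonic-bias windows on V(x) = (k0/2) x^2."""
        T = 300.0
        kT = KB * T
        k0, kw = 1.5 * kT, 12.0 * kT
        centers = np.linspace(-2, 2, n_win)
        wins = []
        for c in centers:
            var = kT / (k0 + kw)
            mu = kw * c / (k0 + kw)
            wins.append(UmbrellaWindow(center=float(c), k=kw,
                                       samples=rng.normal(mu, np.sqrt(var), n),
                                       discarded_fraction=0.0))
        return wins, k0, T

    def test_iterative_agrees_with_direct_solution(self, rng):
        """Self-consistent MBAR matches an independent direct fixed-point
        solution of the same equations on a 5-window toy."""
        wins, k0, T = self._toy_windows(rng)
        beta = 1.0 / (KB * T)
        pooled = np.concatenate([w.samples for w in wins])
        u_kn = np.stack([beta * 0.5 * w.k * (pooled - w.center) ** 2
                         for w in wins])
        N_k = np.array([len(w.samples) for w in wins], dtype=float)
        f = mbar_solve(u_kn, N_k, tol=1e-9)
        # independent route: plain-python damped fixed-point iteration with
        # explicit sums (no logsumexp shortcuts)
        g = np.zeros(len(wins))
        for _ in range(6000):
            denom = np.zeros(u_kn.shape[1])
            for l in range(len(wins)):
                denom += N_k[l] * np.exp(g[l] - u_kn[l])
            g_new = -np.log(np.sum(np.exp(-u_kn) / denom, axis=1))
            g_new -= g_new[0]
            if np.max(np.abs(g_new - g)) < 1e-10:
                g = g_new
                break
            g = g_new
        assert np.abs(f - g).max() < 1e-6

    def test_harmonic_pmf_recovery(self, rng):
        wins, k0, T = self._toy_windows(rng, n_win=9, n=2500)
        prof = reweight_pmf(wins, temperature=T, n_bins=32, n_boot=25,
                            seed=0)
        kT = KB * T
        ref = 0.5 * k0 * prof.grid ** 2 / kT
        ref -= ref.min()
        core = np.isfinite(prof.F) & (np.abs(prof.grid) < 1.5)
        err = np.abs(prof.F[core] - ref[core])
        band = 3 * np.maximum(prof.uncertainty[core], 0.05)
        assert np.all(err < band)

    def test_single_window_zero_bias_reduces_to_histogram(self, rng):
        samples = rng.normal(0, 1, 4000)
        win = UmbrellaWindow(center=0.0, k=0.0, samples=samples,
                             discarded_fraction=0.0)
        prof = reweight_pmf([win], temperature=300.0, n_bins=20, n_boot=0)
        h, edges = np.histogram(samples, bins=20)
        ref = -np.log(h / h.sum())
        ref -= ref[np.isfinite(ref)].min()
        ok = np.isfinite(prof.F) & np.isfinite(ref)
        assert np.abs(prof.F[ok] - ref[ok]).max() < 1e-6

    def test_subsampling_stability(self, rng):
        wins, k0, T = self._toy_windows(rng, n_win=7, n=3000)
        prof_full = reweight_pmf(wins, temperature=T, n_bins=24, n_boot=0)
        half = [UmbrellaWindow(w.center, w.k, w.samples[::2], 0.0)
                for w in wins]
        prof_half = reweight_pmf(half, temperature=T, n_bins=24, n_boot=0,
                                 grid=np.linspace(prof_full.grid[0] - 0.05,
                                                  prof_full.grid[-1] + 0.05,
                                                  25))
        core = (np.abs(prof_full.grid) < 1.5)
        a = prof_full.F[core]
        b = np.interp(prof_full.grid[core], prof_half.grid, prof_half.F)
        assert np.nanmax(np.abs(a - b)) < 0.3

    def test_poor_overlap_warns(self, rng):
        w1 = UmbrellaWindow(0.0, 50.0, rng.normal(0, 0.05, 500), 0.0)
        w2 = UmbrellaWindow(5.0, 50.0, rng.normal(5, 0.05, 500), 0.0)
        with pytest.warns(UserWarning, match="overlap"):
            reweight_pmf([w1, w2], temperature=300.0, n_bins=10, n_boot=0)

    def test_window_grid_endpoints(self):
        centers = umbrella_centers(41)
        assert len(centers) == 41
        assert centers[0] == -1.0
        assert centers[-1] == 1.0
        assert np.allclose(np.diff(centers), 0.05)


class TestUmbrellaResponse:
    def test_doubling_k_halves_variance(self):
        """Window variance in a quadratic potential follows kT/(k0+kw)."""
        T = 300.0
        osys = make_oracle_system("harmonic1d", {"k": 0.5, "temperature": T})

        def run(kw, seed):
            bias = HarmonicBias(lambda c: (c[0, 0], np.array([[1.0, 0, 0]])),
                                center=0.5, k=kw)
            st = initial_state(np.zeros((1, 3)), T, seed=seed)
            tr = LangevinIntegrator(osys.ff).run(
                st, 120000, restraints=[bias],
                observables={"x": lambda c: c[0, 0]}, stride=25,
                store_frames=False)
            return tr.observables["x"].to_numpy()[400:].var()

        v1 = run(2.0, 3)
        v2 = run(4.5 - 0.5, 4)  # k0 + kw doubles: 0.5+2 -> 0.5+4
        assert v1 / v2 == pytest.approx(2.0, rel=0.25)


class TestBarriers:
    def test_1d_double_well_closed_form(self):
        g = np.linspace(-2, 2, 201)
        F = 3.0 * (g ** 2 - 1) ** 2
        prof = FreeEnergyProfile(grid=g, F=F.copy())
        b = barrier_height(prof, (-1.4, -0.6), (0.6, 1.4))
        assert b == pytest.approx(3.0, abs=1e-6)

    def test_monotone_profile_is_downhill(self):
        g = np.linspace(-1, 1, 101)
        prof = FreeEnergyProfile(grid=g, F=np.linspace(5, 0, 101))
        assert barrier_height(prof, (-1.0, -0.8), (0.8, 1.0)) == 0.0

    def test_2d_saddle_matches_path_enumeration(self):
        # small grid with a known saddle; compare the bottleneck level
        # against exhaustive enumeration of all simple paths
        import itertools
        import networkx as nx

        rng = np.random.default_rng(5)
        F = rng.uniform(1.0, 8.0, size=(5, 5))
        F[1, 1] = 0.0
        F[3, 3] = 0.2
        prof = FreeEnergyProfile2D(grid_a=np.arange(5.0),
                                   grid_b=np.arange(5.0), F=F.copy())
        got = barrier_height(prof, ((1, 1), (1, 1)), ((3, 3), (3, 3)))
        G = nx.grid_2d_graph(5, 5)
        best = np.inf
        for path in nx.all_simple_paths(G, (1, 1), (3, 3)):
            level = max(prof.F[p] for p in path)
            best = min(best, level)
        ref = max(best - max(prof.F[1, 1], prof.F[3, 3]), 0.0)
        assert got == pytest.approx(ref, abs=1e-9)

    def test_disconnected_basin_raises(self):
        F = np.full((4, 4), np.nan)
        F[0, 0] = 0.0
        F[3, 3] = 0.0
        prof = FreeEnergyProfile2D(grid_a=np.arange(4.0),
                                   grid_b=np.arange(4.0), F=F)
        with pytest.raises(ValueError, match="connected"):
            barrier_height(prof, ((0, 0), (0, 0)), ((3, 3), (3, 3)))


class TestPmf2d:
    def test_uniform_samples_are_flat(self, rng):
        a = rng.uniform(0, 1, 60000)
        b = rng.uniform(0, 1, 60000)
        prof = pmf_2d(a, b, bins=6)
        assert np.nanmax(prof.F) < 0.25

    def test_independent_gaussians_quadratic(self, rng):
        a = rng.normal(0, 1, 120000)
        b = rng.normal(0, 1, 120000)
        prof = pmf_2d(a, b, bins=21, range_=[[-3, 3], [-3, 3]])
        ga, gb = np.meshgrid(prof.grid_a, prof.grid_b, indexing="ij")
        ref = 0.5 * (ga ** 2 + gb ** 2)
        ref -= ref.min()
        core = (np.abs(ga) < 2) & (np.abs(gb) < 2) & np.isfinite(prof.F)
        assert np.abs(prof.F[core] - ref[core]).max() < 0.35

    def test_bin_doubling_stability(self, rng):
        a = rng.normal(0, 1, 100000)
        b = rng.normal(0, 1, 100000)
        p1 = pmf_2d(a, b, bins=12, range_=[[-3, 3], [-3, 3]])
        p2 = pmf_2d(a, b, bins=24, range_=[[-3, 3], [-3, 3]])
        b1 = barrier_height(p1, ((-0.3, 0.3), (-0.3, 0.3)),
                            ((1.5, 2.5), (1.5, 2.5)))
        b2 = barrier_height(p2, ((-0.3, 0.3), (-0.3, 0.3)),
                            ((1.5, 2.5), (1.5, 2.5)))
        assert abs(b1 - b2) < 0.6


def _distance_metric(coords, target):
    """Progress metric for single-bead toys (best-fit RMSD needs >= 3)."""
    return float(np.linalg.norm(np.asarray(coords) - np.asarray(target)))


class TestPacs:
    def _dw(self):
        return make_oracle_system("doublewell1d", {"barrier": 2.0, "x0": 2.0})

    def test_single_replica_degenerates_to_best_frame_pick(self):
        osys = self._dw()
        start = np.array([[-2.0, 0, 0]])
        target = np.array([[2.0, 0, 0]])
        seeds, best = pacs_cycle([start], osys.ff, target,
                                 n_replicas=1, steps_per_replica=200, seed=1,
                                 stride=20, metric=_distance_metric)
        assert len(seeds) == 1
        assert best == pytest.approx(_distance_metric(seeds[0], target))
        assert best <= _distance_metric(start, target)

    def test_best_rmsd_non_increasing(self):
        osys = self._dw()
        target = np.array([[2.0, 0, 0]])
        _, log = pacs_run(np.array([[-2.0, 0, 0]]), osys.ff, target,
                          n_cycles=8, n_replicas=4, steps_per_replica=100,
                          seed=2, stride=20, metric=_distance_metric)
        series = np.array(log.best_rmsd)
        assert np.all(np.diff(series) <= 1e-12)

    def test_target_equals_start_converges_immediately(self):
        osys = self._dw()
        start = np.array([[-2.0, 0, 0]])
        seeds, log = pacs_run(start, osys.ff, start.copy(), n_cycles=10,
                              n_replicas=2, steps_per_replica=50, seed=3,
                              rmsd_stop=1e-9, metric=_distance_metric)
        assert len(log.best_rmsd) == 1
        assert log.best_rmsd[0] == pytest.approx(0.0, abs=1e-12)

    def test_reaches_target_basin_faster_than_unbiased(self):
        """Paired comparison on the double-well particle: the cascade
        selection crosses into the target basin more often than plain MD
        with the same total step budget."""
        osys = self._dw()
        target = np.array([[2.0, 0, 0]])
        n_rep, spr, n_cyc = 4, 100, 8
        total = n_rep * spr * n_cyc
        pacs_hits = 0
        md_hits = 0
        for rep in range(12):
            seeds, log = pacs_run(np.array([[-2.0, 0, 0]]), osys.ff, target,
                                  n_cycles=n_cyc, n_replicas=n_rep,
                                  steps_per_replica=spr, seed=100 + rep,
                                  stride=10, rmsd_stop=0.5,
                                  metric=_distance_metric)
            if log.best_rmsd[-1] <= 0.5:
                pacs_hits += 1
            st = initial_state(np.array([[-2.0, 0, 0]]), 300.0,
                               seed=500 + rep)
            tr = LangevinIntegrator(osys.ff).run(
                st, total, observables={"x": lambda c: c[0, 0]}, stride=10,
                store_frames=False)
            if np.any(tr.observables["x"].to_numpy() > 1.5):
                md_hits += 1
        assert pacs_hits > md_hits

    def test_snapshots_are_unbiased_states(self):
        """PaCS-MD never modifies the potential: every returned seed is an
        ordinary configuration whose energy is reproducible from its
        coordinates alone."""
        osys = self._dw()
        target = np.array([[2.0, 0, 0]])
        seeds, _ = pacs_cycle([np.array([[-2.0, 0, 0]])], osys.ff, target,
                              n_replicas=3, steps_per_replica=100, seed=7,
                              metric=_distance_metric)
        for s in seeds:
            e1 = osys.ff.energy(s)
            e2 = osys.ff.energy(s.copy())
            assert e1 == e2
            assert np.isfinite(e1)


class TestTargetedMd:
    def test_stiff_limit_pins_structure(self, toy_pair):
        from cgbind.energy_model import ForceField, ModelParameters
        closed, open_ = toy_pair
        ff = ForceField.from_structures(closed, open_, ModelParameters())
        tr = targeted_md(closed.coords, ff, closed.coords, k=2000.0,
                         n_steps=2000, seed=1, stride=100,
                         observables={})
        from cgbind.reaction_coords import kabsch_rmsd
        r = kabsch_rmsd(tr.final_state.coords, closed.coords)
        assert r < 0.35

    def test_zero_k_equals_unbiased(self):
        osys = make_oracle_system("harmonic1d", {"k": 1.0})
        t1 = targeted_md(np.zeros((1, 3)), osys.ff, np.ones((1, 3)), k=0.0,
                         n_steps=300, seed=5)
        st = initial_state(np.zeros((1, 3)), 300.0, seed=5)
        t2 = LangevinIntegrator(osys.ff).run(st, 300, stride=100)
        assert np.array_equal(t1.final_state.coords, t2.final_state.coords)

    def test_rmsd_variance_decreases_with_k(self, toy_pair):
        from cgbind.energy_model import ForceField, ModelParameters
        from cgbind.reaction_coords import kabsch_rmsd
        closed, open_ = toy_pair
        ff = ForceField.from_structures(closed, open_, ModelParameters())
        out = []
        for k in (5.0, 50.0, 500.0):
            tr = targeted_md(
                closed.coords, ff, closed.coords, k=k, n_steps=4000, seed=2,
                stride=50,
                observables={"r": lambda c: kabsch_rmsd(c, closed.coords)})
            out.append(tr.observables["r"].to_numpy()[20:].var())
        assert out[0] > out[1] > out[2]
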