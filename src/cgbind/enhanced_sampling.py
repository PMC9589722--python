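"""Enhanced sampling: PaCS-MD, targeted MD, umbrella sampling and
free-energy estimation.

PaCS-MD (parallel cascade selection MD) samples conformational transitions
without biasing forces: each cycle runs several short unbiased trajectories,
ranks every sampled snapshot by RMSD to a target structure, and reseeds the
next cycle from the best snapshots.  Because the potential is never
modified, any PaCS-MD snapshot is a valid unbiased-dynamics state.  On a
stall (no snapshot beats the incumbent best) the system is relaxed by a
plain MD segment before the cascade resumes.

Umbrella sampling applies harmonic biases (k/2)(xi - c)^2 along the
conformational coordinate xi on a grid of windows; the unbiased free-energy
profile is recovered with the multistate Bennett acceptance ratio (MBAR),
solved here by self-consistent iteration of

    f_k = -ln sum_n exp(-u_k(x_n)) / sum_l N_l exp(f_l - u_l(x_n))

to a relative tolerance of 1e-7, with block-bootstrap uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .dynamics import (HarmonicBias, LangevinIntegrator, RmsdRestraint,
                       SimulationState, Trajectory, initial_state)
from .reaction_coords import kabsch_rmsd, xi_gradient
from .units import KB


# ---------------------------------------------------------------------------
# PaCS-MD
# ---------------------------------------------------------------------------

@dataclass
class PacsLog:
    """Per-cycle record of a PaCS-MD run."""

    best_rmsd: list = field(default_factory=list)
    stalled: list = field(default_factory=list)
    n_relaxations: int = 0


def _default_metric(subset):
    def metric(coords, target):
        return kabsch_rmsd(coords, target, subset)
    return metric


def pacs_cycle(seeds, ff, target_coords, n_replicas: int,
               steps_per_replica: int, seed: int, subset=None,
               stride: int = 50, restraints=(), temperature=None,
               metric=None):
    """One PaCS-MD cycle: short runs from the seeds, snapshot re-selection.

    ``seeds`` is a list of coordinate arrays.  Each replica starts from a
    seed (cycled) with fresh Maxwell-Boltzmann velocities.  All sampled
    snapshots plus the seeds themselves (incumbent retention) are ranked by
    best-fit RMSD to ``target_coords`` over ``subset`` (or by a custom
    ``metric(coords, target)``); the ``n_replicas`` best become the next
    seeds.  Returns (new_seeds, best_rmsd).
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    metric = metric or _default_metric(subset)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_replicas)
    temp = temperature if temperature is not None else ff.params.temperature
    integ = LangevinIntegrator(ff, temperature=temp)
    pool = [np.asarray(s, dtype=float).copy() for s in seeds]
    for r in range(n_replicas):
        start = seeds[r % len(seeds)]
        st = initial_state(np.asarray(start, dtype=float),
                           temp, seed=child[r].entropy % (2 ** 31))
        traj = integ.run(st, steps_per_replica, restraints=restraints,
                         stride=stride, store_frames=True)
        pool.extend(list(traj.frames[1:]))
    rmsds = np.array([metric(c, target_coords) for c in pool])
    order = np.argsort(rmsds, kind="stable")
    new_seeds = [pool[i] for i in order[:n_replicas]]
    return new_seeds, float(rmsds[order[0]])


def pacs_run(start_coords, ff, target_coords, n_cycles: int,
             n_replicas: int = 10, steps_per_replica: int = 200,
             relax_steps: int = 200, seed: int = 0, subset=None,
             stride: int = 50, restraints=(), rmsd_stop: float | None = None,
             temperature=None, metric=None):
    """Iterate PaCS-MD cycles toward a target structure.

    Keeps the best-so-far snapshot among the seeds, so the reported
    best-RMSD series is non-increasing.  A stalled cycle (no improvement on
    the incumbent) triggers an unbiased relaxation segment from the current
    seeds before the cascade resumes.  Stops early when ``rmsd_stop`` is
    reached.  Returns (seeds, log) where ``log.best_rmsd`` has one entry per
    executed cycle.
    """
    ss = np.random.SeedSequence(seed)
    metric = metric or _default_metric(subset)
    seeds = [np.asarray(start_coords, dtype=float).copy()]
    log = PacsLog()
    best = metric(seeds[0], target_coords)
    temp = temperature if temperature is not None else ff.params.temperature
    if rmsd_stop is not None and best <= rmsd_stop:
        log.best_rmsd.append(best)
        log.stalled.append(False)
        return seeds, log
    for cyc in range(n_cycles):
        cseed = int(ss.spawn(1)[0].entropy % (2 ** 31))
        seeds, cycle_best = pacs_cycle(
            seeds, ff, target_coords, n_replicas, steps_per_replica,
            seed=cseed, subset=subset, stride=stride, restraints=restraints,
            temperature=temp, metric=metric)
        stalled = cycle_best >= best - 1e-12
        best = min(best, cycle_best)
        log.best_rmsd.append(best)
        log.stalled.append(bool(stalled))
        if rmsd_stop is not None and best <= rmsd_stop:
            break
        if stalled and relax_steps > 0:
            log.n_relaxations += 1
            integ = LangevinIntegrator(ff, temperature=temp)
            relaxed = []
            for i, s in enumerate(seeds):
                st = initial_state(s, temp,
                                   seed=int(ss.spawn(1)[0].entropy % (2 ** 31)))
                tr = integ.run(st, relax_steps, restraints=restraints,
                               stride=max(relax_steps, 1), store_frames=False)
                relaxed.append(tr.final_state.coords.copy())
            seeds = relaxed
    return seeds, log


def targeted_md(start_coords, ff, reference_coords, k: float,
                n_steps: int, subset=None, seed: int = 0, stride: int = 100,
                observables=None, extra_restraints=(), temperature=None,
                store_frames: bool = True) -> Trajectory:
    """Dynamics under a harmonic RMSD restraint toward a reference.

    With stiff ``k`` (kcal/mol/A^2 on the RMSD) the structure is maintained
    near the reference; k = 0 reduces exactly to an unbiased run with the
    same seed.
    """
    temp = temperature if temperature is not None else ff.params.temperature
    restraints = list(extra_restraints)
    if k > 0:
        restraints.append(RmsdRestraint(reference_coords, subset=subset, k=k))
    st = initial_state(np.asarray(start_coords, dtype=float), temp, seed=seed)
    integ = LangevinIntegrator(ff, temperature=temp)
    return integ.run(st, n_steps, restraints=restraints,
                     observables=observables or {}, stride=stride,
                     store_frames=store_frames)


# ---------------------------------------------------------------------------
# Umbrella sampling
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    """One biased window: harmonic centre, force constant and xi samples."""

    center: float
    k: float
    samples: np.ndarray
    discarded_fraction: float = 0.25

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite window samples")

    @property
    def production(self) -> np.ndarray:
        n0 = int(len(self.samples) * self.discarded_fraction)
        return self.samples[n0:]


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile in units of k_B T, minimum shifted to zero."""

    grid: np.ndarray
    F: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self):
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - np.nanmin(self.F[finite])


def umbrella_centers(n_windows: int = 41, lo: float = -1.0, hi: float = 1.0):
    """Evenly spaced window centres (default 41 windows, spacing 0.05)."""
    return np.linspace(lo, hi, n_windows)


def seed_windows_from_frames(frames, xi_values, centers):
    """Pick, per window centre, the frame whose xi is nearest the centre."""
    xi_values = np.asarray(xi_values, dtype=float)
    out = []
    for c in centers:
        out.append(np.asarray(frames[int(np.argmin(np.abs(xi_values - c)))],
                              dtype=float).copy())
    return out


def run_umbrella(ff, closed_ref, open_ref, centers, initials,
                 k: float = 836.0, steps_per_window: int = 4000,
                 discard_fraction: float = 0.25, seed: int = 0,
                 subset=None, stride: int = 20, restraints=(),
                 temperature=None):
    """Biased sampling in harmonic xi windows.

    ``initials`` supplies one starting structure per centre (typically PaCS
    frames nearest each centre).  Returns a list of UmbrellaWindow whose
    ``samples`` include the full series; the first ``discard_fraction`` is
    dropped by downstream reweighting (mirroring equilibration discard).
    """
    centers = np.asarray(centers, dtype=float)
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centres must be strictly increasing")
    if len(initials) != len(centers):
        raise ValueError("need one initial structure per window")
    temp = temperature if temperature is not None else ff.params.temperature
    ss = np.random.SeedSequence(seed)
    windows = []
    for c0, init in zip(centers, initials):
        def cv(coords):
            return xi_gradient(coords, closed_ref, open_ref, subset)

        bias = HarmonicBias(cv, center=float(c0), k=k)
        st = initial_state(np.asarray(init, dtype=float), temp,
                           seed=int(ss.spawn(1)[0].entropy % (2 ** 31)))
        integ = LangevinIntegrator(ff, temperature=temp)
        traj = integ.run(st, steps_per_window,
                         restraints=[bias, *restraints],
                         observables={"xi": lambda coords: xi_gradient(
                             coords, closed_ref, open_ref, subset)[0]},
                         stride=stride, store_frames=False)
        windows.append(UmbrellaWindow(
            center=float(c0), k=k,
            samples=traj.observables["xi"].to_numpy()[1:],
            discarded_fraction=discard_fraction))
    return windows


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def mbar_solve(u_kn, N_k, tol: float = 1e-7, max_iter: int = 20000):
    """Self-consistent solution of the MBAR equations.

    ``u_kn`` (K, N) holds reduced bias energies of every pooled sample in
    every state; ``N_k`` the per-state sample counts.  Returns the reduced
    free energies f_k (f_0 = 0) solved to ``tol`` in max |delta f|.
    """
    u_kn = np.asarray(u_kn, dtype=float)
    N_k = np.asarray(N_k, dtype=float)
    K, N = u_kn.shape
    if N_k.sum() != N:
        raise ValueError("sample counts do not match the pooled sample size")
    f = np.zeros(K)
    logN = np.log(np.where(N_k > 0, N_k, 1.0))
    active = N_k > 0
    for it in range(max_iter):
        # log denominator per sample: ln sum_l N_l exp(f_l - u_ln)
        denom = logsumexp((f[active, None] - u_kn[active]) + logN[active, None],
                          axis=0)
        f_new = -logsumexp(-u_kn - denom[None, :], axis=1)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"MBAR did not converge within {max_iter} iterations")
    return f


def _window_bias_matrix(windows, temperature):
    beta = 1.0 / (KB * temperature)
    samples = [w.production for w in windows]
    pooled = np.concatenate(samples)
    N_k = np.array([len(s) for s in samples], dtype=float)
    u_kn = np.stack([
        beta * 0.5 * w.k * (pooled - w.center) ** 2 for w in windows
    ])
    return pooled, u_kn, N_k


def reweight_pmf(windows, temperature: float | None = None, grid=None,
                 n_bins: int = 60, tol: float = 1e-7, n_boot: int = 20,
                 block: int = 50, seed: int = 0,
                 min_overlap: int = 1) -> FreeEnergyProfile:
    """Unbiased 1D profile from umbrella windows via MBAR reweighting.

    Warns (with an overlap diagnostic) when adjacent windows share no
    configuration-space overlap.  Uncertainties are block-bootstrap
    estimates over each window's time series.
    """
    import warnings

    if len(windows) < 1:
        raise ValueError("need at least one window")
    temperature = temperature or 300.0
    pooled, u_kn, N_k = _window_bias_matrix(windows, temperature)
    if len(windows) >= 2:
        overlap = _overlap_counts(windows)
        if overlap.min() < min_overlap:
            worst = int(np.argmin(overlap))
            warnings.warn(
                "poor window overlap between centres "
                f"{windows[worst].center:.3f} and {windows[worst + 1].center:.3f} "
                f"(counts {overlap.tolist()})")
    if grid is None:
        grid = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    centers = 0.5 * (grid[:-1] + grid[1:])

    def pmf_of(samples_per_window):
        pooled_, u_kn_, N_k_ = _window_bias_matrix_from(
            samples_per_window, windows, temperature)
        f = mbar_solve(u_kn_, N_k_, tol=tol)
        logN = np.log(N_k_)
        denom = logsumexp((f[:, None] - u_kn_) + logN[:, None], axis=0)
        logw = -denom
        Fb = np.full(len(centers), np.nan)
        idx = np.digitize(pooled_, grid) - 1
        for b in range(len(centers)):
            sel = idx == b
            if sel.any():
                Fb[b] = -logsumexp(logw[sel])
        return Fb

    prod = [w.production for w in windows]
    F = pmf_of(prod)
    unc = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            res = []
            for s in prod:
                nb = max(1, len(s) // block)
                starts = rng.integers(0, max(1, len(s) - block + 1), size=nb)
                res.append(np.concatenate([s[a:a + block] for a in starts]))
            boots.append(pmf_of(res))
        B = np.stack(boots)
        B -= np.nanmin(B, axis=1, keepdims=True)
        unc = np.nanstd(B, axis=0)
    prof = FreeEnergyProfile(grid=centers, F=F, uncertainty=unc)
    return prof


def _window_bias_matrix_from(samples, windows, temperature):
    beta = 1.0 / (KB * temperature)
    pooled = np.concatenate(samples)
    N_k = np.array([len(s) for s in samples], dtype=float)
    u_kn = np.stack([
        beta * 0.5 * w.k * (pooled - w.center) ** 2 for w in windows
    ])
    return pooled, u_kn, N_k


def _overlap_counts(windows):
    """Samples of window i falling within the span of window i+1, plus the
    converse; a zero signals a sampling gap."""
    out = []
    for a, b in zip(windows[:-1], windows[1:]):
        sa, sb = a.production, b.production
        lo_b, hi_b = sb.min(), sb.max()
        lo_a, hi_a = sa.min(), sa.max()
        n = np.sum((sa >= lo_b) & (sa <= hi_b)) + np.sum((sb >= lo_a) & (sb <= hi_a))
        out.append(n)
    return np.array(out)


# ---------------------------------------------------------------------------
# Histogram free-energy surfaces and barriers
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile2D:
    """2D free-energy surface in k_B T; empty bins are NaN-masked."""

    grid_a: np.ndarray
    grid_b: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - np.nanmin(self.F[finite])


def pmf_2d(samples_a, samples_b, bins=40, temperature: float = 300.0,
           range_=None) -> FreeEnergyProfile2D:
    """F = -kT ln(2D histogram) from unbiased equilibrium samples (in kT)."""
    H, ea, eb = np.histogram2d(np.asarray(samples_a, dtype=float),
                               np.asarray(samples_b, dtype=float),
                               bins=bins, range=range_)
    with np.errstate(divide="ignore"):
        F = -np.log(H / H.sum())
    F[~np.isfinite(F)] = np.nan
    return FreeEnergyProfile2D(
        grid_a=0.5 * (ea[:-1] + ea[1:]),
        grid_b=0.5 * (eb[:-1] + eb[1:]),
        F=F)


def barrier_height(profile, basin_a, basin_b) -> float:
    """Free-energy barrier (kT) between two basins of a profile.

    1D: basins are (lo, hi) coordinate intervals; the barrier is the maximum
    of F between the two basin minima, minus the higher basin minimum
    (downhill profiles give 0).  2D: basins are ((lo_a, hi_a), (lo_b, hi_b))
    rectangles; the barrier is the bottleneck (minimax) level at which the
    basins first connect on the bin adjacency graph, minus the higher basin
    minimum.
    """
    if isinstance(profile, FreeEnergyProfile):
        g, F = profile.grid, profile.F
        ia = _basin_argmin_1d(g, F, basin_a)
        ib = _basin_argmin_1d(g, F, basin_b)
        lo, hi = min(ia, ib), max(ia, ib)
        seg = F[lo:hi + 1]
        seg = seg[np.isfinite(seg)]
        ref = max(F[ia], F[ib])
        return float(max(seg.max() - ref, 0.0))
    if isinstance(profile, FreeEnergyProfile2D):
        return _barrier_2d(profile, basin_a, basin_b)
    raise TypeError("unsupported profile type")


def _basin_argmin_1d(grid, F, basin):
    lo, hi = basin
    sel = (grid >= lo) & (grid <= hi) & np.isfinite(F)
    if not sel.any():
        raise ValueError(f"basin {basin} outside sampled support")
    idx = np.nonzero(sel)[0]
    return int(idx[np.argmin(F[idx])])


def _barrier_2d(profile: FreeEnergyProfile2D, basin_a, basin_b) -> float:
    from scipy.ndimage import label

    F = profile.F
    A = _basin_mask_2d(profile, basin_a)
    B = _basin_mask_2d(profile, basin_b)
    min_a = np.nanmin(F[A])
    min_b = np.nanmin(F[B])
    ref = max(min_a, min_b)
    levels = np.unique(F[np.isfinite(F)])
    # bottleneck level: smallest threshold at which A and B are connected
    for lev in levels:
        if lev < ref:
            continue
        mask = np.isfinite(F) & (F <= lev)
        lab, _ = label(mask)
        la = set(np.unique(lab[A & mask])) - {0}
        lb = set(np.unique(lab[B & mask])) - {0}
        if la & lb:
            return float(max(lev - ref, 0.0))
    raise ValueError("basins are not connected on the sampled surface")


def _basin_mask_2d(profile: FreeEnergyProfile2D, basin):
    (lo_a, hi_a), (lo_b, hi_b) = basin
    ma = (profile.grid_a >= lo_a) & (profile.grid_a <= hi_a)
    mb = (profile.grid_b >= lo_b) & (profile.grid_b <= hi_b)
    mask = np.outer(ma, mb) & np.isfinite(profile.F)
    if not mask.any():
        raise ValueError(f"basin {basin} outside sampled support")
    return mask
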