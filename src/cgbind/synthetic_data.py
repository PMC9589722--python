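"""Synthetic two-state toy systems for exercising the full pipeline.

The toy protein is a "clamshell": a rigid CORE scaffold (floor, end wall and
flanking rows), an NMP-like side wall, and a LID-like plate that roofs a
three-sided binding cleft.  The open conformer is generated from the closed
one by a crankshaft rotation of the LID segment about the axis through its
two anchoring beads, so chain connectivity is preserved exactly and domain
opening genuinely uncovers the cleft.  A rod-shaped rigid ligand (5 beads,
AMP-like, or 7 beads, ATP-like) buries in the cleft, contacting the floor,
the LID plate and the NMP wall, so that closing traps it and opening frees
it - the mechanistic ingredient the binding-rescue experiments require.

All generators are deterministic given their seed.  Fixtures can be written
as PDB files so the synthetic and real-structure paths share one loader.

Spacing between scaffold beads is 3.8 A (C-alpha-like); the generator
supports n_beads >= 50 (smaller chains cannot carry the cleft scaffold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy_model import ModelParameters
from .model_builder import (CGStructure, Ligand, assign_domains,
                            build_native_contacts)

A = 3.8  # scaffold lattice spacing, Angstrom


# ---------------------------------------------------------------------------
# Clamshell scaffold
# ---------------------------------------------------------------------------

def _clamshell_coords(n_beads: int) -> tuple[np.ndarray, dict]:
    """Ideal (jitter-free) closed-conformer bead positions, in chain order.

    Chain layout (1-based residues, n >= 60): floor 1-20 (CORE), NMP side
    wall 21-28, LID plate 29-38 roofing the ligand groove, hinge anchor +
    strut 39-40, end wall 41-50, and two static cage rails 51-60 (CORE)
    that seal the cleft sides at ligand height end to end, so the closed
    enzyme genuinely buries the ligand while every pocket bead keeps
    >= 5.5 A clearance from the native ligand (leaving room for non-native
    poses).  The mobile LID is deliberately small (10 beads) so the open
    state's conformational entropy stays comparable to the closed state's.
    Beads beyond 60 extend flanking floor rows.
    """
    if n_beads < 60:
        raise ValueError("clamshell scaffold requires n_beads >= 60")
    pos = []
    # floor: 4 rows x 5 columns at z = 0 (CORE)
    for iy in range(4):
        xs = range(5) if iy % 2 == 0 else range(4, -1, -1)
        for ix in xs:
            pos.append((ix * A, iy * A, 0.0))
    # NMP wall at x = -A: two z-layers sweeping y; the last bead sits on the
    # hinge axis (x = -A, z = 2A)
    ys = [3 * A, 2 * A, A, 0.0]
    for y in ys:
        pos.append((-A, y, A))
    for y in ys[::-1]:
        pos.append((-A, y, 2 * A))
    # LID plate at z = 3A roofing the groove
    for ix in range(5):
        pos.append((ix * A, 2 * A, 3 * A))
    for ix in range(4, -1, -1):
        pos.append((ix * A, A, 3 * A))
    # hinge anchor on the rotation axis through the NMP top end, plus strut
    pos.append((-A, 4 * A, 2 * A))
    pos.append((-A, 4 * A, A))
    # end wall at x = 5A: two full z-layers plus a two-bead top row that
    # meets the closed LID edge
    wall_y = [0.0, A, 2 * A, 3 * A]
    for iz, zs in enumerate((A, 2 * A)):
        ys_w = wall_y if iz % 2 == 0 else wall_y[::-1]
        for y in ys_w:
            pos.append((5 * A, y, zs))
    for y in (A, 2 * A):
        pos.append((5 * A, y, 3 * A))
    # static cage rails at ligand height sealing the cleft sides end to end
    rail_x = [1.0, 4.5, 8.0, 11.5, 15.0]
    for x in rail_x:
        pos.append((x, 0.0, 1.5 * A))
    for x in rail_x[::-1]:
        pos.append((x, 3 * A, 1.5 * A))
    # flanking rows absorb any remaining beads
    flank = []
    row = 0
    while len(flank) < n_beads:  # generous upper bound
        if row % 2 == 0:
            y = -A * (2 + row // 2)
            xs = [ix * A for ix in range(5)]
        else:
            y = A * (4 + row // 2)
            xs = [ix * A for ix in range(4, -1, -1)]
        flank.extend((x, y, 0.0) for x in xs)
        row += 1
    need = n_beads - len(pos)
    if need > 0:
        pos.extend(flank[:need])
    coords = np.array(pos[:n_beads], dtype=float)
    info = {
        "architecture": "clamshell",
        "lid_residues": (29, 38),       # 1-based inclusive
        "nmp_residues": (21, 28),
        "hinge_anchors": (28, 39),      # residues defining the rotation axis
        "spacing": A,
    }
    return coords, info


def clamshell_domain_ranges(n_beads: int) -> dict:
    """Default CORE/NMP/LID residue intervals of the clamshell scaffold."""
    return {
        "CORE": [(1, 20), (39, n_beads)],
        "NMP": [(21, 28)],
        "LID": [(29, 38)],
    }


def _rotate_about_axis(points, p0, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    d = points - p0
    return (p0 + c * d + s * np.cross(axis, d)
            + (1 - c) * np.outer(d @ axis, axis))


def make_two_state_protein(n_beads: int = 60, hinge_residues=None,
                           hinge_angle: float = 50.0, seed: int = 0,
                           jitter: float = 0.15, max_retries: int = 20
                           ) -> tuple[CGStructure, CGStructure]:
    """Generate a closed/open reference pair related by a hinge rotation.

    The open conformer equals the closed one with the mobile segment
    (default: the LID plate) rigidly rotated by ``hinge_angle`` degrees about
    the axis through the beads flanking the segment (a crankshaft move, so
    both junction bonds keep their lengths).  A small seeded Gaussian jitter
    breaks the lattice symmetry; a steric clash after rotation triggers a
    bounded regeneration with fresh jitter.
    """
    coords0, info = _clamshell_coords(n_beads)
    if hinge_residues is None:
        hinge_residues = info["lid_residues"]
    lo, hi = hinge_residues
    if lo <= 1 or hi >= n_beads:
        raise ValueError("hinge segment must be interior to the chain")
    seg = np.arange(lo - 1, hi)            # 0-based mobile beads
    ia, ib = lo - 2, hi                    # axis anchor beads

    rng = np.random.default_rng(seed)
    angle = np.deg2rad(hinge_angle)
    for attempt in range(max_retries):
        closed = coords0 + rng.normal(0.0, jitter, size=coords0.shape)
        axis = closed[ib] - closed[ia]
        open_ = closed.copy()
        # two rotation senses; take the one that moves the segment away from
        # the rest of the molecule (domain opening)
        rest = np.setdiff1d(np.arange(n_beads), seg)

        def _sep(c):
            d = c[seg].mean(axis=0) - c[rest].mean(axis=0)
            return np.linalg.norm(d)

        cand_p = open_.copy()
        cand_p[seg] = _rotate_about_axis(closed[seg], closed[ia], axis, angle)
        cand_m = open_.copy()
        cand_m[seg] = _rotate_about_axis(closed[seg], closed[ia], axis, -angle)
        open_ = cand_p if _sep(cand_p) >= _sep(cand_m) else cand_m

        dmin = _min_nonneighbor_distance(open_)
        if dmin >= 2.5:
            break
    else:
        raise RuntimeError(
            f"could not generate clash-free open conformer after "
            f"{max_retries} retries (min distance {dmin:.2f} A)")

    ranges = clamshell_domain_ranges(n_beads)
    res = np.arange(1, n_beads + 1)
    meta = dict(info, hinge_residues=tuple(hinge_residues),
                hinge_angle=hinge_angle, seed=seed)
    mk = lambda c, tag: assign_domains(
        CGStructure(coords=c, role=["protein"] * n_beads, residue_index=res,
                    domain=[""] * n_beads, conformer=tag, meta=meta),
        ranges)
    return mk(closed, "closed"), mk(open_, "open")


def _min_nonneighbor_distance(coords, skip: int = 1) -> float:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    n = len(coords)
    iu = np.triu_indices(n, k=skip + 1)
    return float(d[iu].min())


# ---------------------------------------------------------------------------
# Toy ligands
# ---------------------------------------------------------------------------

@dataclass
class LigandPose:
    """A rigid ligand pose: bead coordinates plus bead-role metadata."""

    coords: np.ndarray
    kind: str
    base_beads: np.ndarray
    ribose_bead: int
    terminal_bead: int

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.base_beads = np.asarray(self.base_beads, dtype=np.int64)

    def copy(self) -> "LigandPose":
        return LigandPose(self.coords.copy(), self.kind,
                          self.base_beads.copy(), self.ribose_bead,
                          self.terminal_bead)


def make_toy_ligand(closed: CGStructure, n_beads: int = 5, pocket=None,
                    seed: int = 0) -> LigandPose:
    """Place a rod-shaped rigid ligand in the clamshell cleft (native pose).

    The ligand is a linear rod along the cleft axis at mid-height, with the
    ribose bead dipping toward the floor; by construction every native
    contact is formed (Q = 1) and at least 8 contacts exist at the 6.5 A
    criterion (validated, hard error otherwise).
    """
    # the rod spans 14 A so that flipping it end over end is sterically
    # impossible inside the closed cleft (it needs the lid open) - the
    # orientational frustration that makes repeated opening matter
    if n_beads == 5:
        kind = "AMP"
        xs = np.linspace(0.0, 14.0, 5)
        ribose = 2
    elif n_beads == 7:
        kind = "ATP"
        xs = np.linspace(-0.5, 14.5, 7)
        ribose = 2
    else:
        raise ValueError("toy ligands have 5 (AMP-like) or 7 (ATP-like) beads")
    y0, z0 = 1.5 * A, 1.5 * A
    if pocket is not None:
        y0 = pocket.get("y", y0)
        z0 = pocket.get("z", z0)
    coords = np.column_stack([xs, np.full(n_beads, y0), np.full(n_beads, z0)])
    coords[ribose, 2] -= 1.5
    pose = LigandPose(coords=coords, kind=kind, base_beads=np.array([0, 1]),
                      ribose_bead=ribose, terminal_bead=n_beads - 1)
    holo = attach_ligand(closed, [pose])
    contacts = build_native_contacts(holo, threshold=6.5)
    n_pl = sum(1 for c in contacts.native_cls if c == "protein-ligand")
    if n_pl < 8:
        raise RuntimeError(
            f"toy ligand forms only {n_pl} native contacts (< 8); "
            "pocket specification incompatible with the scaffold")
    return pose


def attach_ligand(protein: CGStructure, poses) -> CGStructure:
    """Append ligand beads to a protein structure, with ligand metadata."""
    coords = [protein.coords]
    role = list(protein.role)
    res = list(protein.residue_index)
    dom = list(protein.domain)
    ligands = []
    n = protein.n_beads
    atoms = None
    if protein.atoms is not None:
        atoms = list(protein.atoms)
    for pose in poses:
        m = len(pose.coords)
        idx = np.arange(n, n + m)
        coords.append(pose.coords)
        role.extend([f"ligand:{pose.kind}"] * m)
        res.extend([-1] * m)
        dom.extend([""] * m)
        if atoms is not None:
            atoms.extend([pose.coords[k][None, :] for k in range(m)])
        ligands.append(Ligand(kind=pose.kind, indices=idx,
                              base_beads=pose.base_beads,
                              terminal_bead=pose.terminal_bead))
        n += m
    return CGStructure(
        coords=np.concatenate(coords, axis=0),
        role=role,
        residue_index=np.array(res),
        domain=dom,
        conformer=protein.conformer,
        atoms=atoms,
        ligands=ligands,
        meta=dict(protein.meta),
    )


def perturb_pose(pose: LigandPose, mode: str = "flip180",
                 magnitude: float = 1.0, seed: int = 0,
                 clash_ref: CGStructure | None = None,
                 clash_dist: float = 3.2, max_retries: int = 200
                 ) -> LigandPose:
    """Generate a non-native pose from the native one.

    ``flip180`` applies a 180-degree rigid rotation about the axis through
    the ligand centroid perpendicular to both the base-to-terminal-phosphate
    vector and the ribose offset: the rod flips head-to-tail (theta = pi)
    and the ribose bead points to the opposite side.  It is an exact
    involution.  ``random`` applies a random rotation (angle scaled by
    ``magnitude`` in [0, 1]) plus a bounded random translation, resampled
    until clash-free against ``clash_ref`` (typically the open conformer).
    """
    new = pose.copy()
    cen = pose.coords.mean(axis=0)
    if mode == "flip180":
        v = pose.coords[pose.terminal_bead] - pose.coords[pose.base_beads].mean(axis=0)
        w = pose.coords[pose.ribose_bead] - cen
        axis = np.cross(v, w)
        if np.linalg.norm(axis) < 1e-9:
            # collinear ligand: any perpendicular axis
            trial = np.array([0.0, 0.0, 1.0])
            axis = np.cross(v, trial)
            if np.linalg.norm(axis) < 1e-9:
                axis = np.cross(v, np.array([0.0, 1.0, 0.0]))
        new.coords = _rotate_about_axis(pose.coords, cen,
                                        axis, np.pi)
        return new
    if mode != "random":
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = np.random.default_rng(seed)
    if magnitude == 0:
        return new
    for _ in range(max_retries):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        ang = magnitude * np.pi * rng.uniform(0.2, 1.0)
        shift = magnitude * rng.uniform(-3.0, 3.0, size=3)
        cand = _rotate_about_axis(pose.coords, cen, u, ang) + shift
        if clash_ref is None:
            new.coords = cand
            return new
        prot = clash_ref.coords[clash_ref.protein_mask]
        dmin = np.min(np.linalg.norm(
            prot[:, None, :] - cand[None, :, :], axis=-1))
        if dmin >= clash_dist:
            new.coords = cand
            return new
    raise RuntimeError(
        f"no clash-free perturbed pose found in {max_retries} attempts")


# ---------------------------------------------------------------------------
# Closed-form oracle systems
# ---------------------------------------------------------------------------

class AnalyticForceField:
    """ForceField-compatible wrapper around an analytic potential.

    ``fn(coords) -> (E, F)`` with coords of shape (n, 3).
    """

    def __init__(self, fn, n_beads: int, params: ModelParameters | None = None):
        self.fn = fn
        self.n_beads = n_beads
        self.params = params or ModelParameters()

    def energy_forces(self, coords):
        coords = np.asarray(coords, dtype=float)
        e, F = self.fn(coords)
        return e, F, {"analytic": e}

    def energy(self, coords):
        return self.energy_forces(coords)[0]


@dataclass
class OracleSystem:
    ff: AnalyticForceField
    analytic: dict


@dataclass
class TelegraphSeries:
    times: np.ndarray
    states: np.ndarray
    switch_times: np.ndarray
    rate: float


def make_oracle_system(kind: str, params: dict | None = None, seed: int = 0):
    """Closed-form-solvable fixtures for thermostat/estimator validation.

    ``harmonic1d``: isotropic harmonic well, Boltzmann variance k_B T / k per
    coordinate.  ``doublewell1d``: quartic double well b ((x/x0)^2 - 1)^2
    along x (barrier exactly b) plus harmonic confinement in y, z.
    ``telegraph``: two-state jump series with exponential dwells of known
    mean 1/rate.
    """
    params = dict(params or {})
    if kind == "harmonic1d":
        k = float(params.get("k", 1.0))
        temperature = float(params.get("temperature", 300.0))

        def fn(c):
            return 0.5 * k * float((c ** 2).sum()), -k * c

        mp = ModelParameters(temperature=temperature)
        from .units import KB
        return OracleSystem(
            ff=AnalyticForceField(fn, 1, mp),
            analytic={"k": k, "variance": KB * temperature / k},
        )
    if kind == "doublewell1d":
        b = float(params.get("barrier", 3.0))
        x0 = float(params.get("x0", 2.0))
        kp = float(params.get("k_perp", 5.0))
        temperature = float(params.get("temperature", 300.0))

        def fn(c):
            x, y, z = c[0]
            u = (x / x0) ** 2 - 1.0
            e = b * u * u + 0.5 * kp * (y * y + z * z)
            F = np.zeros_like(c)
            F[0, 0] = -4.0 * b * u * x / (x0 * x0)
            F[0, 1] = -kp * y
            F[0, 2] = -kp * z
            return e, F

        mp = ModelParameters(temperature=temperature)
        return OracleSystem(
            ff=AnalyticForceField(fn, 1, mp),
            analytic={"barrier": b, "minima": (-x0, x0),
                      "potential": lambda x: b * ((x / x0) ** 2 - 1.0) ** 2},
        )
    if kind == "telegraph":
        rate = float(params.get("rate", 1.0))
        n_switches = int(params.get("n_switches", 100))
        dt = float(params.get("dt", 0.01))
        rng = np.random.default_rng(seed)
        dwells = rng.exponential(1.0 / rate, size=n_switches)
        switch_times = np.cumsum(dwells)
        total = switch_times[-1]
        times = np.arange(0.0, total, dt)
        states = (np.searchsorted(switch_times, times, side="right") % 2)
        return TelegraphSeries(times=times, states=states,
                               switch_times=switch_times, rate=rate)
    raise ValueError(f"unknown oracle system kind {kind!r}")


# ---------------------------------------------------------------------------
# PDB fixture output
# ---------------------------------------------------------------------------

def write_pdb(struct: CGStructure, path):
    """Write a CG structure as a PDB file (beads as CA atoms / HETATM).

    Protein beads become ALA CA atoms so :func:`cgbind.model_builder.
    load_structure` reads the file back with identical bead positions.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = struct.n_beads
    arr = struc.AtomArray(n)
    arr.coord = struct.coords.astype(np.float32)
    res_counter = max([int(r) for r in struct.residue_index if r > 0],
                      default=0)
    lig_res = {}
    for i in range(n):
        if struct.role[i] == "protein":
            arr.chain_id[i] = "A"
            arr.res_id[i] = int(struct.residue_index[i])
            arr.res_name[i] = "ALA"
            arr.atom_name[i] = "CA"
            arr.element[i] = "C"
            arr.hetero[i] = False
        else:
            kind = struct.role[i].split(":", 1)[1]
            if kind not in lig_res:
                res_counter += 1
                lig_res[kind] = res_counter
            arr.chain_id[i] = "B"
            arr.res_id[i] = lig_res[kind]
            arr.res_name[i] = kind[:3]
            arr.atom_name[i] = f"L{i}"
            arr.element[i] = "C"
            arr.hetero[i] = True
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
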