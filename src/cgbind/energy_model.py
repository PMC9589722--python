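"""Coarse-grained double-basin energy model.

The apo protein is described by structure-based (Go-type) potentials built
from the closed and the open reference conformations.  Bonded terms and
intra-domain contacts are shared single-basin terms referenced to the closed
structure; each of the three interface components (LID-CORE, NMP-CORE,
LID-NMP) carries a closed-basin and an open-basin contact set that are mixed
into a smooth double-basin surface via the lower eigenvalue of the two-state
secular problem,

    V_MB = ((V1 + V2) - sqrt((V1 - V2)^2 + 4 Delta^2)) / 2,

with V1 the closed-basin component, V2 the open-basin component shifted by
the energy-gap parameter dV, and Delta the coupling that controls the barrier
between the basins.  Ligands interact through 12-10 native contacts of depth
eps_nat, Gaussian non-native wells of depth eps_nnat (the ruggedness dial of
the binding landscape) and width sigma_nnat, and r^-12 excluded volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .model_builder import (CGStructure, ContactMap, Topology,
                            build_native_contacts, build_nonnative_pairs,
                            build_topology)

__all__ = [
    "ModelParameters", "ForceField", "multi_basin_mix",
    "ligand_native_term", "ligand_nonnative_term", "excluded_volume_term",
    "single_basin_forcefield", "single_basin_energy", "apo_energy",
    "total_energy",
]


@dataclass
class ModelParameters:
    """All force-field constants, in kcal/mol, Angstrom, Kelvin, tau.

    ``deltaV`` and ``coupling_delta`` are per-interface arrays ordered
    (LID-CORE, NMP-CORE, LID-NMP); both are calibrated, not taken from any
    printed table.  ``eps_nnat`` is the non-native ruggedness scan variable.
    """

    eps_nat: float = 0.15              # protein-ligand native contact depth
    eps_nnat: float = 0.0              # non-native well depth (scan variable)
    sigma_nnat: float = 6.0            # non-native Gaussian width, A
    eps_exv: float = 1.0               # excluded-volume prefactor
    sigma_exv_protein: float = 4.0     # protein-protein excluded volume, A
    sigma_exv_protein_ligand: float = 5.0
    sigma_exv_ligand_ligand: float = 3.5
    eps_protein: float = 0.3           # interface native contact depth
    eps_intra: float = 1.0             # intra-domain contact depth (rigid domains)
    contact_threshold: float = 6.5     # heavy-atom native-contact cutoff, A
    deltaV: tuple = (0.0, 0.0, 0.0)    # per-interface open-basin offset
    coupling_delta: tuple = (0.5, 0.5, 0.5)  # per-interface coupling Delta
    k_bond: float = 100.0              # kcal/mol/A^2 (E = k/2 (r-r0)^2)
    k_angle: float = 20.0              # kcal/mol/rad^2
    k_dihedral: float = 1.0            # kcal/mol, E = k (1 - cos(phi-phi0))
    k_angle_hinge: float = 2.0         # per-basin hinge angle constant
    k_dihedral_hinge: float = 0.5      # per-basin hinge dihedral constant
    k_tether: float = 0.01             # per-basin interface spring, kcal/mol/A^2
    k_ligand_bond: float = 100.0       # rigid-ligand restraints
    k_ligand_angle: float = 50.0
    k_ligand_dihedral: float = 50.0
    temperature: float = 300.0         # K
    gamma: float = 0.25                # Langevin friction, tau^-1
    dt: float = 0.1                    # time step, tau

    def __post_init__(self):
        for name in ("eps_nat", "eps_nnat", "eps_exv", "eps_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("sigma_nnat", "sigma_exv_protein",
                     "sigma_exv_protein_ligand", "sigma_exv_ligand_ligand"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.deltaV = tuple(float(x) for x in self.deltaV)
        self.coupling_delta = tuple(float(x) for x in self.coupling_delta)
        if len(self.deltaV) != 3 or len(self.coupling_delta) != 3:
            raise ValueError("deltaV and coupling_delta must have 3 components")
        if any(c < 0 for c in self.coupling_delta):
            raise ValueError("coupling_delta must be non-negative")

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Pure pair terms (reference forms; the kernels implement the same math)
# ---------------------------------------------------------------------------

def multi_basin_mix(v_closed, v_open, deltaV, coupling):
    """Smooth double-basin mix of two single-basin energies (kcal/mol).

    Lower eigenvalue of [[V1, -Delta], [-Delta, V2]] with V1 = v_closed and
    V2 = v_open + deltaV; always <= min(V1, V2), with equality iff the
    coupling vanishes.
    """
    if coupling < 0:
        raise ValueError("coupling must be non-negative")
    v1 = np.asarray(v_closed, dtype=float)
    v2 = np.asarray(v_open, dtype=float) + deltaV
    s = np.sqrt((v1 - v2) ** 2 + 4.0 * coupling ** 2)
    out = 0.5 * (v1 + v2 - s)
    return out.item() if out.ndim == 0 else out


def ligand_native_term(r, r0, eps_nat):
    """12-10 native-contact attraction: eps*[5 (r0/r)^12 - 6 (r0/r)^10].

    Minimum of depth -eps_nat at r = r0; repulsive core; vanishes at large r.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    q = r0 / r
    out = eps_nat * (5.0 * q ** 12 - 6.0 * q ** 10)
    return out.item() if out.ndim == 0 else out


def ligand_nonnative_term(r, eps_nnat, sigma_nnat):
    """Gaussian non-native well: -eps * exp(-r^2 / (2 sigma^2))."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    out = -eps_nnat * np.exp(-(r ** 2) / (2.0 * sigma_nnat ** 2))
    return out.item() if out.ndim == 0 else out


def excluded_volume_term(r, sigma, eps_exv):
    """Soft-core repulsion eps * (sigma/r)^12."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    out = eps_exv * (sigma / r) ** 12
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Force field
# ---------------------------------------------------------------------------

COMPONENT_NAMES = ("bonded", "intra_domain", "mb_lid_core", "mb_nmp_core",
                   "mb_lid_nmp", "ligand_native", "ligand_nonnative",
                   "excluded_volume")


class ForceField:
    """Evaluates total energy and forces for a packed :class:`Topology`."""

    def __init__(self, topology: Topology, params: ModelParameters):
        unknown = set(np.unique(topology.con_grp).tolist()) - {0, 1, 2, 3, 4, 5, 6, 7}
        if unknown:
            raise ValueError(f"unclassified contact groups: {sorted(unknown)}")
        self.topology = topology
        self.params = params
        self._dV = np.asarray(params.deltaV, dtype=np.float64)
        self._coupling = np.asarray(params.coupling_delta, dtype=np.float64)
        self._F = np.zeros((topology.n_beads, 3))
        self._Fg = np.zeros((6, topology.n_beads, 3))
        self._comps = np.zeros(8)

    @classmethod
    def from_structures(cls, closed: CGStructure, open_: CGStructure,
                        params: ModelParameters,
                        contacts_closed: ContactMap | None = None,
                        contacts_open: ContactMap | None = None) -> "ForceField":
        topo = build_topology(closed, open_, params,
                              contacts_closed=contacts_closed,
                              contacts_open=contacts_open)
        return cls(topo, params)

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    def energy_forces(self, coords):
        """Return (energy kcal/mol, forces kcal/mol/A, component dict)."""
        coords = np.ascontiguousarray(coords, dtype=np.float64)
        if coords.shape != (self.topology.n_beads, 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match topology "
                f"({self.topology.n_beads} beads)")
        t = self.topology
        e = _kernels.ff_energy_forces(
            coords,
            t.bond_i, t.bond_j, t.bond_r0, t.bond_k,
            t.ang_i, t.ang_j, t.ang_k, t.ang_t0, t.ang_kk, t.ang_grp,
            t.dih_i, t.dih_j, t.dih_k, t.dih_l, t.dih_p0, t.dih_kk, t.dih_grp,
            t.con_i, t.con_j, t.con_r0, t.con_eps, t.con_grp,
            t.teth_i, t.teth_j, t.teth_r0, t.teth_k, t.teth_grp,
            t.nn_i, t.nn_j,
            t.exv_i, t.exv_j, t.exv_sig,
            self.params.eps_nnat, self.params.sigma_nnat, self.params.eps_exv,
            self._dV, self._coupling,
            self._F, self._Fg, self._comps)
        return e, self._F.copy(), dict(zip(COMPONENT_NAMES, self._comps))

    def energy(self, coords) -> float:
        return self.energy_forces(coords)[0]

    def with_params(self, **kw) -> "ForceField":
        return ForceField(self.topology, self.params.replace(**kw))


def single_basin_forcefield(reference: CGStructure, params: ModelParameters,
                            contacts: ContactMap | None = None) -> ForceField:
    """Single-basin structure-based force field built against one reference.

    Bonded terms and every native contact (including interface contacts) are
    referenced to ``reference``; no basin mixing is applied.
    """
    if contacts is None:
        contacts = build_native_contacts(reference,
                                         threshold=params.contact_threshold)
        if reference.ligands:
            contacts = build_nonnative_pairs(contacts, reference)
    topo = build_topology(reference, reference, params,
                          contacts_closed=contacts,
                          contacts_open=ContactMap(
                              native_i=np.zeros(0, np.int64),
                              native_j=np.zeros(0, np.int64),
                              native_r0=np.zeros(0),
                              native_cls=[]))
    # collapse interface groups onto the shared single-basin group; drop the
    # basin tethers (they exist to shape interconversion, not a single basin)
    for name in ("con_grp", "ang_grp", "dih_grp"):
        grp = getattr(topo, name).copy()
        grp[(grp >= 1) & (grp <= 6)] = 0
        setattr(topo, name, grp)
    zi = np.zeros(0, np.int64)
    topo.teth_i = zi.copy()
    topo.teth_j = zi.copy()
    topo.teth_r0 = np.zeros(0)
    topo.teth_k = np.zeros(0)
    topo.teth_grp = zi.copy()
    p = params.replace(coupling_delta=(0.0, 0.0, 0.0), deltaV=(0.0, 0.0, 0.0))
    return ForceField(topo, p)


def single_basin_energy(coords, reference: CGStructure, params: ModelParameters,
                        contacts: ContactMap | None = None):
    """Energy/forces of the single-basin potential centred on ``reference``."""
    ff = single_basin_forcefield(reference, params, contacts=contacts)
    return ff.energy_forces(coords)


def apo_energy(coords, ff: ForceField):
    """Double-basin apo energy: shared terms plus the three mixed interfaces."""
    return ff.energy_forces(coords)


def total_energy(coords, ff: ForceField):
    """Full energy: apo terms plus ligand native/non-native/excluded volume."""
    return ff.energy_forces(coords)


def finite_difference_forces(ff: ForceField, coords, h: float = 1e-5):
    """Central-difference gradient check helper (returns -dE/dx array)."""
    coords = np.asarray(coords, dtype=float)
    F = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            cp = coords.copy()
            cp[i, d] += h
            ep = ff.energy(cp)
            cp[i, d] -= 2 * h
            em = ff.energy(cp)
            F[i, d] = -(ep - em) / (2 * h)
    return F
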