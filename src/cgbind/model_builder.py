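"""Build coarse-grained topologies from pairs of reference structures.

A protein is reduced to one bead per residue at the C-alpha position; ligands
(ATP-like, AMP-like) are reduced to a small number of beads placed at
centroids of chemical moieties.  From a closed (ligand-bound) and an open
reference conformation the builder derives:

* native contact lists per basin (heavy-atom distance criterion, default
  6.5 A), classified by domain interface (intra-domain, LID-CORE, NMP-CORE,
  LID-NMP) or as protein-ligand;
* non-native protein-ligand pairs obeying two eligibility rules: the protein
  residue must lie within 6 A of a residue that forms a native contact with
  the ligand, and the pair distance in the closed reference must not exceed
  10 A;
* generic bonded terms (bonds, angles, dihedrals) referenced to the closed
  structure, plus stiff internal restraints that keep each ligand rigid;
* excluded-volume pair lists for everything else.

The result is a :class:`Topology` of flat arrays consumed by the energy
kernels, serializable to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

# contact group codes used throughout the package
GROUP_SHARED = 0          # single-basin terms (intra-domain protein contacts)
GROUP_CLOSED_IFACE = {"LID-CORE": 1, "NMP-CORE": 2, "LID-NMP": 3}
GROUP_OPEN_IFACE = {"LID-CORE": 4, "NMP-CORE": 5, "LID-NMP": 6}
GROUP_LIGAND = 7          # protein-ligand native contacts

DOMAIN_NAMES = ("CORE", "LID", "NMP")

#: default AdK domain ranges (1-based, inclusive); literature conventions vary
ADK_DOMAIN_RANGES = {
    "CORE": [(1, 29), (68, 117), (161, 214)],
    "NMP": [(30, 67)],
    "LID": [(118, 160)],
}


@dataclass
class Ligand:
    """Bead-level metadata for one rigid ligand."""

    kind: str                      # "ATP" | "AMP" | free-form toy name
    indices: np.ndarray            # bead indices within the parent CGStructure
    base_beads: np.ndarray         # local indices forming the base (ring) moiety
    terminal_bead: int             # local index of the terminal-phosphate bead

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.base_beads = np.asarray(self.base_beads, dtype=np.int64)


@dataclass
class CGStructure:
    """Coarse-grained structure: bead coordinates plus per-bead annotation.

    ``atoms`` optionally stores the heavy atoms that were condensed into each
    bead (used for native-contact detection); when absent each bead is its
    own single "atom".
    """

    coords: np.ndarray                      # (N, 3) Angstrom
    role: list[str]                         # "protein" | "ligand:<KIND>"
    residue_index: np.ndarray               # per-bead; -1 for ligand beads
    domain: list[str]                       # "CORE"/"LID"/"NMP" or "" for ligand
    conformer: str                          # "closed" | "open" | "instantaneous"
    atoms: list[np.ndarray] | None = None   # heavy atoms per bead, (m_i, 3)
    ligands: list[Ligand] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        n = len(self.coords)
        if n == 0:
            raise ValueError("CGStructure requires at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite bead coordinates")
        if not (len(self.role) == len(self.residue_index) == len(self.domain) == n):
            raise ValueError("per-bead annotation lengths do not match coords")
        for lig in self.ligands:
            nb = len(lig.indices)
            if lig.kind == "ATP" and nb != 7:
                raise ValueError(f"ATP ligand must have 7 beads, got {nb}")
            if lig.kind == "AMP" and nb != 5:
                raise ValueError(f"AMP ligand must have 5 beads, got {nb}")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def protein_mask(self) -> np.ndarray:
        return np.array([r == "protein" for r in self.role], dtype=bool)

    @property
    def protein_indices(self) -> np.ndarray:
        return np.nonzero(self.protein_mask)[0]

    def domain_indices(self, name: str) -> np.ndarray:
        return np.array(
            [i for i, d in enumerate(self.domain) if d == name], dtype=np.int64
        )

    def bead_atoms(self, i: int) -> np.ndarray:
        """Heavy atoms condensed into bead i (the bead itself if unknown)."""
        if self.atoms is None or self.atoms[i] is None:
            return self.coords[i][None, :]
        return self.atoms[i]


@dataclass
class ContactMap:
    """Native contact pairs with reference distances, plus non-native pairs.

    ``native`` columns: i, j (bead indices), r0 (A, bead-bead reference
    distance), cls (interface class string).  ``nonnative`` columns: i, j.
    ``nonnative_meta`` records, per pair, the distance to the nearest
    contact-forming residue and the reference pair distance (eligibility
    provenance).
    """

    native_i: np.ndarray
    native_j: np.ndarray
    native_r0: np.ndarray
    native_cls: list[str]
    nonnative_i: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    nonnative_j: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    nonnative_meta: dict = field(default_factory=dict)
    exclusions: set = field(default_factory=set)

    def __post_init__(self):
        self.native_i = np.asarray(self.native_i, dtype=np.int64)
        self.native_j = np.asarray(self.native_j, dtype=np.int64)
        self.native_r0 = np.asarray(self.native_r0, dtype=np.float64)
        if np.any(self.native_r0 <= 0):
            raise ValueError("native contact with non-positive reference distance")
        nat = set(zip(self.native_i.tolist(), self.native_j.tolist()))
        if len(nat) != len(self.native_i):
            raise ValueError("duplicate native contact pair")
        nn = set(zip(self.nonnative_i.tolist(), self.nonnative_j.tolist()))
        if len(nn) != len(self.nonnative_i):
            raise ValueError("duplicate non-native pair")
        if nat & nn:
            raise ValueError("native and non-native pair lists overlap")

    @property
    def n_native(self) -> int:
        return len(self.native_i)

    def native_pairs_of_class(self, cls: str) -> np.ndarray:
        sel = [k for k, c in enumerate(self.native_cls) if c == cls]
        return np.array(sel, dtype=np.int64)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _read_pdb_atoms(path):
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, altloc="first")
    return arr


def load_structure(path, conformer: str = "instantaneous") -> CGStructure:
    """Read a PDB file into a protein-only CGStructure (one bead per residue).

    Beads are placed at C-alpha positions; all heavy atoms of each residue are
    retained for contact detection.  A residue lacking a C-alpha atom is a
    hard error naming that residue.
    """
    import biotite.structure as struc

    arr = _read_pdb_atoms(path)
    prot = arr[struc.filter_amino_acids(arr)]
    prot = prot[prot.element != "H"]
    if prot.array_length() == 0:
        raise ValueError(f"{path}: no amino-acid atoms found")

    coords, res_ids, atoms = [], [], []
    # preserve file order of residues
    seen = []
    for rid, cid in zip(prot.res_id, prot.chain_id):
        key = (cid, int(rid))
        if key not in seen:
            seen.append(key)
    for cid, rid in seen:
        sel = (prot.res_id == rid) & (prot.chain_id == cid)
        res = prot[sel]
        ca = res[res.atom_name == "CA"]
        if ca.array_length() == 0:
            raise ValueError(f"{path}: residue {rid} (chain {cid}) lacks a CA atom")
        coords.append(np.asarray(ca.coord[0], dtype=np.float64))
        res_ids.append(rid)
        atoms.append(np.asarray(res.coord, dtype=np.float64))

    n = len(coords)
    return CGStructure(
        coords=np.array(coords),
        role=["protein"] * n,
        residue_index=np.array(res_ids),
        domain=[""] * n,
        conformer=conformer,
        atoms=atoms,
    )


def load_reference_pair(closed_file, open_file) -> tuple[CGStructure, CGStructure]:
    """Load the closed/open reference pair, enforcing matched residue lists."""
    closed = load_structure(closed_file, conformer="closed")
    open_ = load_structure(open_file, conformer="open")
    if closed.n_beads != open_.n_beads:
        raise ValueError(
            f"residue-count mismatch: {closed.n_beads} (closed) vs "
            f"{open_.n_beads} (open)"
        )
    if not np.array_equal(closed.residue_index, open_.residue_index):
        raise ValueError("residue numbering differs between closed and open files")
    return closed, open_


# ---------------------------------------------------------------------------
# Ligand coarse-graining
# ---------------------------------------------------------------------------

_RING5 = ("N9", "C8", "N7", "C5", "C4")
_RING6 = ("N1", "C2", "N3", "C6", "N6")
_RIBOSE = ("C1'", "C2'", "C3'", "C4'", "C5'", "O2'", "O3'", "O4'", "O5'")

#: moiety -> atom names, in bead order.  The base is two beads (purine 5-ring
#: and 6-ring), the ribose one, phosphates one bead per phosphorus plus one
#: terminal-oxygen bead.  Only the counts are constrained by the model (AMP 5,
#: ATP 7); the grouping itself is a package convention and configurable.
LIGAND_BEAD_SCHEMES = {
    "AMP": [
        ("ring5", _RING5),
        ("ring6", _RING6),
        ("ribose", _RIBOSE),
        ("phosphate-P", ("P", "PA")),
        ("phosphate-O", ("O1P", "O2P", "O3P", "OP1", "OP2", "OP3")),
    ],
    "ATP": [
        ("ring5", _RING5),
        ("ring6", _RING6),
        ("ribose", _RIBOSE),
        ("alpha-phosphate", ("PA", "O1A", "O2A", "O3A")),
        ("beta-phosphate", ("PB", "O1B", "O2B", "O3B")),
        ("gamma-phosphate-P", ("PG",)),
        ("gamma-phosphate-O", ("O1G", "O2G", "O3G")),
    ],
}


def map_ligand_beads(atom_names, atom_coords, ligand_kind: str,
                     scheme: dict | None = None) -> np.ndarray:
    """Map ligand heavy atoms onto coarse-grained beads.

    Each bead sits at the centre of geometry of its moiety's atoms.  The
    mapping is deterministic (fixed bead order per scheme).  Raises if a
    moiety has no atoms, naming the missing group.
    """
    schemes = scheme or LIGAND_BEAD_SCHEMES
    if ligand_kind not in schemes:
        raise KeyError(f"unknown ligand kind {ligand_kind!r}")
    atom_coords = np.asarray(atom_coords, dtype=np.float64)
    names = list(atom_names)
    beads = []
    for group_name, group_atoms in schemes[ligand_kind]:
        sel = [k for k, nm in enumerate(names) if nm in group_atoms]
        if not sel:
            raise ValueError(
                f"{ligand_kind}: no heavy atoms found for moiety {group_name!r}"
            )
        beads.append(atom_coords[sel].mean(axis=0))
    return np.array(beads)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _heavy_atom_contact(struct: CGStructure, i: int, j: int, threshold: float) -> bool:
    ai, aj = struct.bead_atoms(i), struct.bead_atoms(j)
    d2 = ((ai[:, None, :] - aj[None, :, :]) ** 2).sum(axis=-1)
    return bool(d2.min() < threshold * threshold)


def _interface_class(struct: CGStructure, i: int, j: int) -> str:
    ri, rj = struct.role[i], struct.role[j]
    if ri != "protein" or rj != "protein":
        return "protein-ligand"
    di, dj = struct.domain[i], struct.domain[j]
    if di == dj:
        return "intra-domain"
    pair = frozenset((di, dj))
    for name in ("LID-CORE", "NMP-CORE", "LID-NMP"):
        a, b = name.split("-")
        if pair == frozenset((a, b)):
            return name
    raise ValueError(f"unclassifiable bead pair ({i}, {j}): domains {di!r}, {dj!r}")


def build_native_contacts(struct: CGStructure, threshold: float = 6.5,
                          min_seq_sep: int = 3) -> ContactMap:
    """Detect native contacts in a reference structure.

    A pair is a native contact iff any heavy-atom pair between the two beads'
    atom groups is closer than ``threshold`` (A).  Protein-protein pairs
    additionally require a sequence separation ``|i-j| >= min_seq_sep``.
    The stored r0 is the bead-bead distance in the reference structure.
    Candidate pairs are pruned with a KD-tree over heavy atoms; tests compare
    the result against a brute-force all-pairs scan.
    """
    n = struct.n_beads
    # flat heavy-atom list with owning bead index
    owner, pts = [], []
    for i in range(n):
        a = struct.bead_atoms(i)
        pts.append(a)
        owner.extend([i] * len(a))
    pts = np.concatenate(pts, axis=0)
    owner = np.array(owner)
    tree = cKDTree(pts)
    cand = set()
    for a, b in tree.query_pairs(threshold):
        i, j = owner[a], owner[b]
        if i == j:
            continue
        cand.add((min(i, j), max(i, j)))

    prot = struct.protein_mask
    ni, nj, r0, cls = [], [], [], []
    for i, j in sorted(cand):
        if prot[i] and prot[j]:
            if abs(int(struct.residue_index[i]) - int(struct.residue_index[j])) < min_seq_sep:
                continue
        elif not (prot[i] or prot[j]):
            continue  # ligand-ligand pairs interact through excluded volume only
        if not _heavy_atom_contact(struct, i, j, threshold):
            continue
        d = float(np.linalg.norm(struct.coords[i] - struct.coords[j]))
        if d <= 0:
            raise ValueError(f"coincident beads in native contact ({i}, {j})")
        ni.append(i)
        nj.append(j)
        r0.append(d)
        cls.append(_interface_class(struct, i, j))
    return ContactMap(
        native_i=np.array(ni, dtype=np.int64),
        native_j=np.array(nj, dtype=np.int64),
        native_r0=np.array(r0),
        native_cls=cls,
    )


def build_nonnative_pairs(contacts: ContactMap, closed: CGStructure,
                          shell: float = 6.0, max_ref_dist: float = 10.0) -> ContactMap:
    """Attach the non-native protein-ligand pair list to a contact map.

    (i, j) with protein residue i and ligand bead j is non-native iff it is
    not a native contact, residue i lies within ``shell`` (A, bead distance)
    of some residue that forms a native protein-ligand contact, and the (i, j)
    distance in the closed reference is at most ``max_ref_dist`` (A).
    """
    prot = closed.protein_indices
    lig = np.array([k for k, r in enumerate(closed.role) if r != "protein"],
                   dtype=np.int64)
    native = set(zip(contacts.native_i.tolist(), contacts.native_j.tolist()))
    contact_res = sorted({
        (i if closed.role[i] == "protein" else j)
        for i, j, c in zip(contacts.native_i, contacts.native_j, contacts.native_cls)
        if c == "protein-ligand"
    })
    nn_i, nn_j, meta_shell, meta_ref = [], [], [], []
    if contact_res:
        cres = np.array(contact_res, dtype=np.int64)
        for i in prot:
            dshell = float(np.min(np.linalg.norm(
                closed.coords[cres] - closed.coords[i], axis=1)))
            if dshell > shell:
                continue
            for j in lig:
                key = (min(i, j), max(i, j))
                if key in native:
                    continue
                dref = float(np.linalg.norm(closed.coords[i] - closed.coords[j]))
                if dref > max_ref_dist:
                    continue
                nn_i.append(key[0])
                nn_j.append(key[1])
                meta_shell.append(dshell)
                meta_ref.append(dref)
    return ContactMap(
        native_i=contacts.native_i,
        native_j=contacts.native_j,
        native_r0=contacts.native_r0,
        native_cls=contacts.native_cls,
        nonnative_i=np.array(nn_i, dtype=np.int64),
        nonnative_j=np.array(nn_j, dtype=np.int64),
        nonnative_meta={
            "shell": shell,
            "max_ref_dist": max_ref_dist,
            "dist_to_contact_residue": meta_shell,
            "ref_distance": meta_ref,
        },
        exclusions=contacts.exclusions,
    )


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------

def assign_domains(struct: CGStructure, ranges: dict[str, list[tuple[int, int]]]
                   ) -> CGStructure:
    """Label protein beads with domain names from residue-index intervals.

    ``ranges`` maps a domain name to a list of inclusive 1-based residue
    intervals.  The intervals must partition the protein chain exactly:
    overlap or an unlabeled residue is a hard error.
    """
    label = {}
    for name, ivals in ranges.items():
        for lo, hi in ivals:
            for r in range(lo, hi + 1):
                if r in label:
                    raise ValueError(
                        f"residue {r} assigned to both {label[r]} and {name}")
                label[r] = name
    domain = list(struct.domain)
    for k in struct.protein_indices:
        r = int(struct.residue_index[k])
        if r not in label:
            raise ValueError(f"residue {r} not covered by any domain interval")
        domain[k] = label[r]
    return CGStructure(
        coords=struct.coords.copy(),
        role=list(struct.role),
        residue_index=struct.residue_index.copy(),
        domain=domain,
        conformer=struct.conformer,
        atoms=struct.atoms,
        ligands=struct.ligands,
        meta=dict(struct.meta),
    )


# ---------------------------------------------------------------------------
# Topology assembly
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Flat interaction lists for the energy kernels (all arrays contiguous)."""

    n_beads: int
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_t0: np.ndarray
    ang_kk: np.ndarray
    ang_grp: np.ndarray
    dih_i: np.ndarray
    dih_j: np.ndarray
    dih_k: np.ndarray
    dih_l: np.ndarray
    dih_p0: np.ndarray
    dih_kk: np.ndarray
    dih_grp: np.ndarray
    con_i: np.ndarray
    con_j: np.ndarray
    con_r0: np.ndarray
    con_eps: np.ndarray
    con_grp: np.ndarray
    teth_i: np.ndarray
    teth_j: np.ndarray
    teth_r0: np.ndarray
    teth_k: np.ndarray
    teth_grp: np.ndarray
    nn_i: np.ndarray
    nn_j: np.ndarray
    exv_i: np.ndarray
    exv_j: np.ndarray
    exv_sig: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("bond_i", "bond_j", "ang_i", "ang_j", "ang_k", "ang_grp",
                     "dih_i", "dih_j", "dih_k", "dih_l", "dih_grp",
                     "con_i", "con_j", "con_grp", "teth_i", "teth_j",
                     "teth_grp", "nn_i", "nn_j", "exv_i", "exv_j"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), np.int64))
        for name in ("bond_r0", "bond_k", "ang_t0", "ang_kk", "dih_p0", "dih_kk",
                     "con_r0", "con_eps", "teth_r0", "teth_k", "exv_sig"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), np.float64))

    def to_json(self, path):
        data = {
            "n_beads": self.n_beads,
            "meta": self.meta,
        }
        for f_ in self.__dataclass_fields__:
            if f_ in ("n_beads", "meta"):
                continue
            data[f_] = getattr(self, f_).tolist()
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            data = json.load(fh)
        kwargs = {k: np.asarray(v) for k, v in data.items()
                  if k not in ("n_beads", "meta")}
        return cls(n_beads=data["n_beads"], meta=data.get("meta", {}), **kwargs)


def _angles_of_chain(idx):
    return [(idx[k], idx[k + 1], idx[k + 2]) for k in range(len(idx) - 2)]


def _dihedrals_of_chain(idx):
    return [(idx[k], idx[k + 1], idx[k + 2], idx[k + 3]) for k in range(len(idx) - 3)]


def _angle_value(a, b, c):
    u, v = a - b, c - b
    ct = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(ct, -1.0, 1.0)))


def _dihedral_value(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def build_topology(closed: CGStructure, open_: CGStructure, params,
                   contacts_closed: ContactMap | None = None,
                   contacts_open: ContactMap | None = None) -> Topology:
    """Assemble the full interaction topology for the double-basin model.

    ``closed`` must contain the ligand(s) in the native pose and carry domain
    labels; ``open_`` covers the same protein beads in the open conformation.
    Intra-domain protein contacts and all bonded terms are single-basin
    (closed reference); each of the three interface components contributes a
    closed-basin and an open-basin contact set that the energy model mixes.
    """
    n = closed.n_beads
    prot = closed.protein_indices
    if contacts_closed is None:
        contacts_closed = build_nonnative_pairs(
            build_native_contacts(closed, threshold=params.contact_threshold),
            closed,
        )
    if contacts_open is None:
        contacts_open = build_native_contacts(open_, threshold=params.contact_threshold)

    bonds, angles, dihedrals = [], [], []
    # protein backbone (assumes one chain in bead order)
    pidx = list(prot)
    for k in range(len(pidx) - 1):
        i, j = pidx[k], pidx[k + 1]
        bonds.append((i, j, float(np.linalg.norm(closed.coords[i] - closed.coords[j])),
                      params.k_bond))
    # Angles and dihedrals whose reference values differ between the two
    # conformers span the hinge.  Each basin keeps its own copy of these
    # terms (referenced to its conformer, softened) and they are routed into
    # the interface component of the domains they span, so the double-basin
    # mixing - not a shared harmonic well - governs the hinge geometry.
    def _iface_groups(beads):
        doms = {closed.domain[b] for b in beads} - {""}
        if len(doms) == 2:
            for name in ("LID-CORE", "NMP-CORE", "LID-NMP"):
                if doms == set(name.split("-")):
                    return GROUP_CLOSED_IFACE[name], GROUP_OPEN_IFACE[name]
        return None

    for (i, j, k) in _angles_of_chain(pidx):
        tc = _angle_value(*closed.coords[[i, j, k]])
        to = _angle_value(*open_.coords[[i, j, k]])
        if abs(tc - to) < 0.15:
            angles.append((i, j, k, tc, params.k_angle, GROUP_SHARED))
        else:
            grps = _iface_groups((i, j, k))
            if grps is None:
                angles.append((i, j, k, tc, params.k_angle_hinge, GROUP_SHARED))
            else:
                gc, go = grps
                angles.append((i, j, k, tc, params.k_angle_hinge, gc))
                angles.append((i, j, k, to, params.k_angle_hinge, go))
    for (i, j, k, l) in _dihedrals_of_chain(pidx):
        pc = _dihedral_value(*closed.coords[[i, j, k, l]])
        po = _dihedral_value(*open_.coords[[i, j, k, l]])
        dphi = abs(np.angle(np.exp(1j * (pc - po))))
        if dphi < 0.3:
            dihedrals.append((i, j, k, l, pc, params.k_dihedral, GROUP_SHARED))
        else:
            grps = _iface_groups((i, j, k, l))
            if grps is None:
                dihedrals.append((i, j, k, l, pc, params.k_dihedral_hinge,
                                  GROUP_SHARED))
            else:
                gc, go = grps
                dihedrals.append((i, j, k, l, pc, params.k_dihedral_hinge, gc))
                dihedrals.append((i, j, k, l, po, params.k_dihedral_hinge, go))
    # rigid-ligand internal restraints
    for lig in closed.ligands:
        lidx = list(lig.indices)
        for k in range(len(lidx) - 1):
            i, j = lidx[k], lidx[k + 1]
            bonds.append((i, j,
                          float(np.linalg.norm(closed.coords[i] - closed.coords[j])),
                          params.k_ligand_bond))
        for (i, j, k) in _angles_of_chain(lidx):
            angles.append((i, j, k, _angle_value(*closed.coords[[i, j, k]]),
                           params.k_ligand_angle, GROUP_SHARED))
        for (i, j, k, l) in _dihedrals_of_chain(lidx):
            dihedrals.append((i, j, k, l,
                              _dihedral_value(*closed.coords[[i, j, k, l]]),
                              params.k_ligand_dihedral, GROUP_SHARED))

    # contacts with group codes
    con = []
    nat_any = set()
    for i, j, r0, cls in zip(contacts_closed.native_i, contacts_closed.native_j,
                             contacts_closed.native_r0, contacts_closed.native_cls):
        nat_any.add((min(i, j), max(i, j)))
        if cls == "intra-domain":
            con.append((i, j, r0, params.eps_intra, GROUP_SHARED))
        elif cls == "protein-ligand":
            con.append((i, j, r0, params.eps_nat, GROUP_LIGAND))
        else:
            con.append((i, j, r0, params.eps_protein, GROUP_CLOSED_IFACE[cls]))
    for i, j, r0, cls in zip(contacts_open.native_i, contacts_open.native_j,
                             contacts_open.native_r0, contacts_open.native_cls):
        nat_any.add((min(i, j), max(i, j)))
        if cls in GROUP_OPEN_IFACE:
            con.append((i, j, r0, params.eps_protein, GROUP_OPEN_IFACE[cls]))
        # intra-domain contacts of the open basin coincide with the closed
        # ones for rigid domains and are carried by the shared set

    # Basin-defining harmonic tethers: every interface contact pair of either
    # basin gets a soft spring toward its distance in each reference, routed
    # into that basin's mixed component.  These long-range terms give each
    # basin a funnel over the whole interdomain range (the 12-10 contacts
    # alone are too short-ranged to steer re-closing) - an elastic-network
    # complement standard in multiple-basin constructions.
    teth = []
    if params.k_tether > 0:
        for name in ("LID-CORE", "NMP-CORE", "LID-NMP"):
            pairs = set()
            for cm in (contacts_closed, contacts_open):
                for i, j, cls in zip(cm.native_i, cm.native_j, cm.native_cls):
                    if cls == name:
                        pairs.add((min(i, j), max(i, j)))
            for i, j in sorted(pairs):
                rc = float(np.linalg.norm(closed.coords[i] - closed.coords[j]))
                ro = float(np.linalg.norm(open_.coords[i] - open_.coords[j]))
                if abs(rc - ro) < 1e-9 and closed.conformer == open_.conformer:
                    continue  # degenerate single-basin build
                teth.append((i, j, rc, params.k_tether, GROUP_CLOSED_IFACE[name]))
                teth.append((i, j, ro, params.k_tether, GROUP_OPEN_IFACE[name]))

    # excluded volume
    exv = []
    res = closed.residue_index
    for a in range(len(prot)):
        for b in range(a + 1, len(prot)):
            i, j = prot[a], prot[b]
            if abs(int(res[i]) - int(res[j])) < 3:
                continue
            if (min(i, j), max(i, j)) in nat_any:
                continue
            exv.append((i, j, params.sigma_exv_protein))
    lig_beads = {}
    for lig in closed.ligands:
        for k in lig.indices:
            lig_beads[int(k)] = lig.kind
    for i in prot:
        for j in lig_beads:
            if (min(i, j), max(i, j)) in nat_any:
                continue
            exv.append((min(i, j), max(i, j), params.sigma_exv_protein_ligand))
    ligs = list(closed.ligands)
    for a in range(len(ligs)):
        for b in range(a + 1, len(ligs)):
            for i in ligs[a].indices:
                for j in ligs[b].indices:
                    exv.append((min(i, j), max(i, j),
                                params.sigma_exv_ligand_ligand))

    def cols(rows, k):
        return np.array([r[k] for r in rows]) if rows else np.zeros(0)

    topo = Topology(
        n_beads=n,
        bond_i=cols(bonds, 0), bond_j=cols(bonds, 1),
        bond_r0=cols(bonds, 2), bond_k=cols(bonds, 3),
        ang_i=cols(angles, 0), ang_j=cols(angles, 1), ang_k=cols(angles, 2),
        ang_t0=cols(angles, 3), ang_kk=cols(angles, 4), ang_grp=cols(angles, 5),
        dih_i=cols(dihedrals, 0), dih_j=cols(dihedrals, 1),
        dih_k=cols(dihedrals, 2), dih_l=cols(dihedrals, 3),
        dih_p0=cols(dihedrals, 4), dih_kk=cols(dihedrals, 5),
        dih_grp=cols(dihedrals, 6),
        con_i=cols(con, 0), con_j=cols(con, 1), con_r0=cols(con, 2),
        con_eps=cols(con, 3), con_grp=cols(con, 4),
        teth_i=cols(teth, 0), teth_j=cols(teth, 1), teth_r0=cols(teth, 2),
        teth_k=cols(teth, 3), teth_grp=cols(teth, 4),
        nn_i=contacts_closed.nonnative_i, nn_j=contacts_closed.nonnative_j,
        exv_i=cols(exv, 0), exv_j=cols(exv, 1), exv_sig=cols(exv, 2),
        meta={
            "contact_threshold": params.contact_threshold,
            "nonnative_shell": 6.0,
            "nonnative_max_ref_dist": 10.0,
            "ligands": [
                {
                    "kind": lig.kind,
                    "indices": lig.indices.tolist(),
                    "base_beads": lig.base_beads.tolist(),
                    "terminal_bead": int(lig.terminal_bead),
                }
                for lig in closed.ligands
            ],
        },
    )
    return topo
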