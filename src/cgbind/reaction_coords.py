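"""Reaction coordinates for conformational motion and ligand binding.

* best-fit (Kabsch) RMSD over an arbitrary bead subset;
* the conformational progress coordinate
  xi = (RMSD_closed - RMSD_open) / RMSD_closed-open, which is -1 at the
  closed reference and +1 at the open reference;
* Q, the fraction of formed native contacts;
* pose coordinates (R, theta) of a ligand after CORE-domain superposition:
  R is the displacement of the terminal-phosphate bead from its native
  position and theta the angle between the instantaneous and native
  base-to-terminal-phosphate vectors;
* interdomain centre-of-mass distances (unit bead masses).

All coordinates are invariant under global rigid motion of the system.
"""

from __future__ import annotations

import numpy as np

from .model_builder import CGStructure, ContactMap, Ligand


def kabsch(X, Y):
    """Optimal rotation/translation mapping Y onto X (least-squares).

    Returns (R, t) such that ``Y @ R.T + t`` best fits X.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (Y - yc).T @ (X - xc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = xc - yc @ R.T
    return R, t


def kabsch_rmsd(X, Y, subset=None) -> float:
    """Minimum RMSD between coordinate sets over rigid rotations+translations.

    ``subset`` selects the beads used both for superposition and for the
    deviation; requires at least 3 non-collinear points.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if subset is not None:
        X = X[subset]
        Y = Y[subset]
    if len(X) < 3:
        raise ValueError("RMSD subset needs at least 3 beads")
    # collinearity check via the rank of the centred coordinates
    if np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) RMSD subset")
    R, t = kabsch(X, Y)
    diff = X - (Y @ R.T + t)
    return float(np.sqrt((diff ** 2).sum() / len(X)))


def rmsd_gradient(coords, reference, subset=None):
    """Gradient of the best-fit RMSD with respect to ``coords``.

    Superposes the reference onto the instantaneous coordinates; by the
    envelope theorem the variation of the optimal rotation does not
    contribute, so the gradient of RMSD^2 is 2/N times the residual after
    superposition.  Returns (rmsd, grad) with grad of shape coords.shape
    (zero rows outside the subset).
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if subset is None:
        subset = np.arange(len(coords))
    X = coords[subset]
    Y = reference[subset]
    R, t = kabsch(X, Y)
    resid = X - (Y @ R.T + t)
    n = len(X)
    msd = (resid ** 2).sum() / n
    rmsd = np.sqrt(msd)
    grad = np.zeros_like(coords)
    if rmsd > 1e-12:
        # centred residual: translation optimality removes the mean
        grad[subset] = (resid - resid.mean(axis=0)) / (n * rmsd)
    return float(rmsd), grad


def xi(coords, closed_ref, open_ref, subset=None) -> float:
    """Conformational progress coordinate, -1 at closed and +1 at open."""
    rmsd_co = kabsch_rmsd(closed_ref, open_ref, subset)
    if rmsd_co <= 1e-12:
        raise ValueError("closed and open references coincide (RMSD_CO = 0)")
    rc = kabsch_rmsd(coords, closed_ref, subset)
    ro = kabsch_rmsd(coords, open_ref, subset)
    return (rc - ro) / rmsd_co


def xi_gradient(coords, closed_ref, open_ref, subset=None):
    """(xi, d xi/d coords) for use in umbrella biasing forces."""
    rmsd_co = kabsch_rmsd(closed_ref, open_ref, subset)
    if rmsd_co <= 1e-12:
        raise ValueError("closed and open references coincide (RMSD_CO = 0)")
    rc, gc = rmsd_gradient(coords, closed_ref, subset)
    ro, go = rmsd_gradient(coords, open_ref, subset)
    return (rc - ro) / rmsd_co, (gc - go) / rmsd_co


def fraction_native_contacts(coords, contacts: ContactMap, lam: float = 1.2,
                             cls: str | None = "protein-ligand",
                             smooth: bool = False, beta: float = 5.0) -> float:
    """Fraction Q of formed native contacts.

    A contact is formed iff r_ij < lam * r0_ij (sharp default).  ``cls``
    restricts the contact list to one interface class (None = all).  The
    smooth variant replaces the indicator with the switching function
    1 / (1 + exp(beta * (r - lam * r0))) behind the same interface.
    """
    coords = np.asarray(coords, dtype=float)
    if cls is None:
        sel = np.arange(contacts.n_native)
    else:
        sel = contacts.native_pairs_of_class(cls)
    if len(sel) == 0:
        raise ValueError("empty native contact list; Q is undefined")
    i = contacts.native_i[sel]
    j = contacts.native_j[sel]
    r0 = contacts.native_r0[sel]
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    if smooth:
        return float(np.mean(1.0 / (1.0 + np.exp(beta * (r - lam * r0)))))
    return float(np.mean(r < lam * r0))


def fraction_native_contacts_ligand(coords, contacts: ContactMap,
                                    ligand: Ligand, lam: float = 1.2) -> float:
    """Q restricted to native contacts involving one specific ligand."""
    lig_set = set(ligand.indices.tolist())
    sel = [k for k in range(contacts.n_native)
           if contacts.native_cls[k] == "protein-ligand"
           and (int(contacts.native_i[k]) in lig_set
                or int(contacts.native_j[k]) in lig_set)]
    if not sel:
        raise ValueError(f"ligand {ligand.kind}: no native contacts")
    sel = np.asarray(sel)
    i = contacts.native_i[sel]
    j = contacts.native_j[sel]
    r0 = contacts.native_r0[sel]
    r = np.linalg.norm(np.asarray(coords, dtype=float)[i] - coords[j], axis=1)
    return float(np.mean(r < lam * r0))


def pose_coordinates(coords, closed_ref: CGStructure, ligand: Ligand
                     ) -> tuple[float, float]:
    """(R, theta) of a ligand pose after CORE superposition.

    The CORE beads of the instantaneous structure are superposed onto the
    closed reference; R (A) is the displacement of the terminal-phosphate
    bead from its reference position and theta (rad, in [0, pi]) the angle
    between the base-COM -> terminal-phosphate vectors of the instantaneous
    and reference poses.  Both are 0 for the native pose.
    """
    coords = np.asarray(coords, dtype=float)
    core = closed_ref.domain_indices("CORE")
    if len(core) < 3:
        raise ValueError("CORE domain needs at least 3 beads for superposition")
    R, t = kabsch(closed_ref.coords[core], coords[core])
    moved = coords @ R.T + t  # instantaneous structure in the reference frame

    gi = ligand.indices
    term = gi[ligand.terminal_bead]
    base = gi[ligand.base_beads]
    p_inst = moved[term]
    p_ref = closed_ref.coords[term]
    r_val = float(np.linalg.norm(p_inst - p_ref))

    v_inst = p_inst - moved[base].mean(axis=0)
    v_ref = p_ref - closed_ref.coords[base].mean(axis=0)
    ni, nr = np.linalg.norm(v_inst), np.linalg.norm(v_ref)
    if ni < 1e-10 or nr < 1e-10:
        raise ValueError("degenerate base-to-phosphate vector")
    ct = float(np.dot(v_inst, v_ref) / (ni * nr))
    theta = float(np.arccos(np.clip(ct, -1.0, 1.0)))
    return r_val, theta


def interdomain_distance(coords, idx_a, idx_b) -> float:
    """Distance between unweighted bead centroids of two domains (A)."""
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty domain")
    coords = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(coords[idx_a].mean(axis=0)
                                - coords[idx_b].mean(axis=0)))
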