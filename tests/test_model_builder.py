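"""Topology construction: PDB loading, ligand mapping, contacts, domains."""

import numpy as np
import pytest

from cgbind.energy_model import ModelParameters
from cgbind.model_builder import (ADK_DOMAIN_RANGES, CGStructure, ContactMap,
                                  Topology, assign_domains,
                                  build_native_contacts, build_nonnative_pairs,
                                  build_topology, load_reference_pair,
                                  load_structure, map_ligand_beads)
from cgbind.synthetic_data import write_pdb


def _write_min_pdb(path, n_res=10, drop_ca_at=None):
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = []
    for r in range(1, n_res + 1):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C")):
            if name == "CA" and r == drop_ca_at:
                continue
            atoms.append((r, name, el,
                          (3.8 * r + (0.5 if name != "CA" else 0.0),
                           float(r % 3), 0.0)))
    arr = struc.AtomArray(len(atoms))
    for k, (r, name, el, xyz) in enumerate(atoms):
        arr.chain_id[k] = "A"
        arr.res_id[k] = r
        arr.res_name[k] = "ALA"
        arr.atom_name[k] = name
        arr.element[k] = el
        arr.hetero[k] = False
        arr.coord[k] = xyz
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


class TestLoadReferencePair:
    def test_bead_per_residue(self, tmp_path):
        p = tmp_path / "mini.pdb"
        _write_min_pdb(p, n_res=10)
        s = load_structure(p)
        assert s.n_beads == 10
        assert all(r == "protein" for r in s.role)

    def test_missing_ca_names_residue(self, tmp_path):
        p = tmp_path / "bad.pdb"
        _write_min_pdb(p, n_res=10, drop_ca_at=5)
        with pytest.raises(ValueError, match="residue 5"):
            load_structure(p)

    def test_residue_count_mismatch(self, tmp_path):
        a, b = tmp_path / "a.pdb", tmp_path / "b.pdb"
        _write_min_pdb(a, n_res=10)
        _write_min_pdb(b, n_res=9)
        with pytest.raises(ValueError, match="mismatch"):
            load_reference_pair(a, b)

    def test_round_trip_of_synthetic_fixture(self, tmp_path, toy_pair):
        closed, open_ = toy_pair
        pa, pb = tmp_path / "c.pdb", tmp_path / "o.pdb"
        write_pdb(closed, pa)
        write_pdb(open_, pb)
        c2, o2 = load_reference_pair(pa, pb)
        assert c2.n_beads == closed.n_beads
        # PDB coordinates carry 3 decimals
        np.testing.assert_allclose(c2.coords, closed.coords, atol=1e-3)
        np.testing.assert_allclose(o2.coords, open_.coords, atol=1e-3)


class TestMapLigandBeads:
    AMP_ATOMS = ["N9", "C8", "N7", "C5", "C4", "N1", "C2", "N3", "C6", "N6",
                 "C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O5'",
                 "P", "O1P", "O2P", "O3P"]
    ATP_EXTRA = ["PA", "O1A", "O2A", "PB", "O1B", "O2B", "PG",
                 "O1G", "O2G", "O3G"]

    def _coords(self, names, rng):
        return rng.normal(0, 4, size=(len(names), 3))

    def test_amp_has_five_beads(self, rng):
        xyz = self._coords(self.AMP_ATOMS, rng)
        beads = map_ligand_beads(self.AMP_ATOMS, xyz, "AMP")
        assert beads.shape == (5, 3)

    def test_atp_has_seven_beads(self, rng):
        names = [n for n in self.AMP_ATOMS if n not in ("P", "O1P", "O2P",
                                                        "O3P")]
        names += self.ATP_EXTRA
        beads = map_ligand_beads(names, self._coords(names, rng), "ATP")
        assert beads.shape == (7, 3)

    def test_translation_equivariance(self, rng):
        xyz = self._coords(self.AMP_ATOMS, rng)
        v = np.array([1.5, -2.0, 7.0])
        b0 = map_ligand_beads(self.AMP_ATOMS, xyz, "AMP")
        b1 = map_ligand_beads(self.AMP_ATOMS, xyz + v, "AMP")
        np.testing.assert_allclose(b1, b0 + v, atol=1e-12)

    def test_missing_moiety_is_named(self, rng):
        names = [n for n in self.AMP_ATOMS if not n.endswith("'")]
        with pytest.raises(ValueError, match="ribose"):
            map_ligand_beads(names, self._coords(names, rng), "AMP")

    def test_deterministic(self, rng):
        xyz = self._coords(self.AMP_ATOMS, rng)
        b0 = map_ligand_beads(self.AMP_ATOMS, xyz, "AMP")
        b1 = map_ligand_beads(self.AMP_ATOMS, xyz, "AMP")
        np.testing.assert_array_equal(b0, b1)


def _two_bead_structure(dist):
    """Two 'residues' whose single heavy atoms sit ``dist`` apart."""
    coords = np.array([[0.0, 0, 0], [dist, 0, 0]])
    return CGStructure(coords=coords, role=["protein", "protein"],
                       residue_index=np.array([1, 5]),
                       domain=["CORE", "CORE"], conformer="closed")


class TestNativeContacts:
    @pytest.mark.parametrize("dist,expected", [(6.4, 1), (6.6, 0)])
    def test_threshold(self, dist, expected):
        s = _two_bead_structure(dist)
        cm = build_native_contacts(s, threshold=6.5)
        assert cm.n_native == expected

    def test_matches_brute_force_oracle(self, holo_system):
        holo = holo_system["holo"]
        cm = build_native_contacts(holo, threshold=6.5)
        got = set(zip(cm.native_i.tolist(), cm.native_j.tolist()))
        # independent O(N^2) scan over all bead pairs and heavy atoms
        expected = set()
        prot = holo.protein_mask
        for i in range(holo.n_beads):
            for j in range(i + 1, holo.n_beads):
                if prot[i] and prot[j]:
                    if abs(int(holo.residue_index[i])
                           - int(holo.residue_index[j])) < 3:
                        continue
                elif not (prot[i] or prot[j]):
                    continue
                ai, aj = holo.bead_atoms(i), holo.bead_atoms(j)
                d = np.sqrt(((ai[:, None] - aj[None]) ** 2).sum(-1)).min()
                if d < 6.5:
                    expected.add((i, j))
        assert got == expected

    def test_permutation_stability(self, rng):
        # shuffling atoms within a bead's heavy-atom group keeps the map
        atoms1 = [rng.normal(0, 2, (4, 3)), rng.normal(5, 2, (5, 3))]
        coords = np.array([a.mean(axis=0) for a in atoms1])
        def build(atoms):
            s = CGStructure(coords=coords.copy(),
                            role=["protein", "protein"],
                            residue_index=np.array([1, 10]),
                            domain=["CORE", "CORE"], conformer="closed",
                            atoms=atoms)
            return build_native_contacts(s, threshold=6.5)
        cm1 = build(atoms1)
        atoms2 = [a[::-1].copy() for a in atoms1]
        cm2 = build(atoms2)
        assert np.array_equal(cm1.native_i, cm2.native_i)
        assert np.array_equal(cm1.native_j, cm2.native_j)
        np.testing.assert_allclose(cm1.native_r0, cm2.native_r0)

    def test_disjoint_native_nonnative(self, holo_system):
        cm = holo_system["contacts"]
        nat = set(zip(cm.native_i.tolist(), cm.native_j.tolist()))
        non = set(zip(cm.nonnative_i.tolist(), cm.nonnative_j.tolist()))
        assert nat and non
        assert not (nat & non)


class TestNonnativePairs:
    def _mini_complex(self, res2_pos):
        """Residue 1 at the origin forms a native contact with the ligand
        bead at (0, 5, 0); residue 2 at ``res2_pos`` is the candidate for a
        non-native pair with that ligand bead."""
        coords = np.array([
            [0.0, 0.0, 0.0],
            list(res2_pos),
            [0.0, 5.0, 0.0],
        ])
        s = CGStructure(coords=coords,
                        role=["protein", "protein", "ligand:AMP"],
                        residue_index=np.array([1, 10, -1]),
                        domain=["CORE", "CORE", ""], conformer="closed")
        cm = build_native_contacts(s, threshold=6.5)
        return build_nonnative_pairs(cm, s)

    def test_shell_rule_excludes_far_residue(self):
        # residue 2 sits 7 A from the contact-forming residue: ineligible
        cm = self._mini_complex((0.0, -7.0, 0.0))
        assert (1, 2) not in set(zip(cm.nonnative_i, cm.nonnative_j))

    def test_reference_distance_rule(self):
        # eligible (5.9 A shell) but 10.9 A from the ligand: excluded
        cm = self._mini_complex((0.0, -5.9, 0.0))
        assert (1, 2) not in set(zip(cm.nonnative_i, cm.nonnative_j))
        # eligible and 9 A from the ligand: included
        cm = self._mini_complex((0.0, -4.0, 0.0))
        assert (1, 2) in set(zip(cm.nonnative_i, cm.nonnative_j))

    def test_matches_brute_force_oracle(self, holo_system):
        holo = holo_system["holo"]
        cm = holo_system["contacts"]
        got = set(zip(cm.nonnative_i.tolist(), cm.nonnative_j.tolist()))
        nat = set(zip(cm.native_i.tolist(), cm.native_j.tolist()))
        contact_res = {int(i) for k, (i, j) in
                       enumerate(zip(cm.native_i, cm.native_j))
                       if cm.native_cls[k] == "protein-ligand"
                       for i in ((i, j)[0],) if holo.role[int(i)] == "protein"}
        contact_res |= {int(j) for k, (i, j) in
                        enumerate(zip(cm.native_i, cm.native_j))
                        if cm.native_cls[k] == "protein-ligand"
                        and holo.role[int(j)] == "protein"}
        expected = set()
        lig = [k for k, r in enumerate(holo.role) if r != "protein"]
        for i in np.nonzero(holo.protein_mask)[0]:
            dshell = min(np.linalg.norm(holo.coords[c] - holo.coords[i])
                         for c in contact_res)
            if dshell > 6.0:
                continue
            for j in lig:
                pair = (min(i, j), max(i, j))
                if pair in nat:
                    continue
                if np.linalg.norm(holo.coords[i] - holo.coords[j]) <= 10.0:
                    expected.add(pair)
        assert got == expected


class TestAssignDomains:
    def _chain(self, n):
        return CGStructure(coords=np.arange(n * 3, dtype=float).reshape(n, 3),
                           role=["protein"] * n,
                           residue_index=np.arange(1, n + 1),
                           domain=[""] * n, conformer="closed")

    def test_explicit_ranges(self):
        s = assign_domains(self._chain(60), {
            "CORE": [(1, 20), (41, 60)], "NMP": [(21, 30)],
            "LID": [(31, 40)]})
        assert s.domain[0] == "CORE"
        assert s.domain[20] == "NMP"
        assert s.domain[30] == "LID"
        assert s.domain[59] == "CORE"

    def test_overlap_is_error(self):
        with pytest.raises(ValueError, match="both"):
            assign_domains(self._chain(10), {"CORE": [(1, 5)],
                                             "LID": [(5, 10)]})

    def test_gap_is_error(self):
        with pytest.raises(ValueError, match="not covered"):
            assign_domains(self._chain(10), {"CORE": [(1, 5)],
                                             "LID": [(7, 10)]})

    def test_adk_default_ranges_cover_three_domains(self):
        s = assign_domains(self._chain(214), ADK_DOMAIN_RANGES)
        counts = {d: s.domain.count(d) for d in ("CORE", "LID", "NMP")}
        assert all(v > 0 for v in counts.values())
        assert sum(counts.values()) == 214


class TestTopology:
    def test_json_round_trip(self, holo_system, tmp_path):
        topo = holo_system["ff"].topology
        path = tmp_path / "topo.json"
        topo.to_json(path)
        back = Topology.from_json(path)
        assert back.n_beads == topo.n_beads
        np.testing.assert_array_equal(back.con_i, topo.con_i)
        np.testing.assert_allclose(back.con_r0, topo.con_r0)
        np.testing.assert_array_equal(back.teth_grp, topo.teth_grp)

    def test_duplicate_native_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ContactMap(native_i=np.array([0, 0]), native_j=np.array([1, 1]),
                       native_r0=np.array([5.0, 5.0]),
                       native_cls=["intra-domain"] * 2)
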