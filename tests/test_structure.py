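"""Structure parsing, symmetry, superposition and ion-site geometry."""

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import navperm as nv
from navperm.structure import pore_axis_frame, transform_points


@pytest.fixture
def toy_model():
    spec = nv.ToyPoreSpec(ring_charges=((-0.76, 8.0), (-0.51, 3.0)),
                          ion_positions=(10.0, 7.2, 1.6),
                          water_positions=(4.5,))
    model, _ = nv.generate_toy_pore(spec)
    return model


def kabsch_oracle(A, B):
    """Independent SVD-based optimal rotation mapping B onto A."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    return R, t, float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

class TestReadWrite:
    def test_fixture_round_trip_to_pdb_precision(self, toy_model, tmp_path):
        path = tmp_path / "toy.pdb"
        nv.write_pdb(toy_model, path)
        back = nv.read_structure(path)
        assert len(back.atoms) == len(toy_model.atoms)
        a = np.sort(toy_model.coords(), axis=0)
        b = np.sort(back.coords(), axis=0)
        assert np.allclose(a, b, atol=5e-4)  # PDB stores 3 decimals

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  CA ASER A   1       1.000   0.000   0.000  0.30 10.00           C",
            "ATOM      2  CA BSER A   1       2.000   0.000   0.000  0.70 10.00           C",
            "ATOM      3  CB  SER A   1       3.000   0.000   0.000  1.00 10.00           C",
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = nv.read_structure(path)
        ca = [a for a in model.atoms if a.name == "CA"]
        assert len(ca) == 1
        assert ca[0].xyz[0] == pytest.approx(2.0)  # the 0.70 conformer

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            nv.read_structure(path)


# --------------------------------------------------------------------------
# Symmetry
# --------------------------------------------------------------------------

class TestSymmetry:
    def test_identity_operator_duplicates_in_place(self, toy_model):
        out = nv.apply_symmetry(toy_model, (np.eye(3), np.zeros(3)))
        assert len(out.atoms) == 2 * len(toy_model.atoms)
        n = len(toy_model.atoms)
        for orig, copy_ in zip(out.atoms[:n], out.atoms[n:]):
            assert np.allclose(orig.xyz, copy_.xyz)
            assert copy_.chain != orig.chain

    def test_twofold_about_z(self):
        spec = nv.ToyPoreSpec(ring_charges=((-0.5, 0.0),), n_fold=4,
                              ion_positions=(), water_positions=())
        model, _ = nv.generate_toy_pore(spec)
        R = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        out = nv.apply_symmetry(model, (R, np.zeros(3)))
        first = model.atoms[0].xyz  # on the ring at (r, 0, 0)
        image = out.atoms[len(model.atoms)].xyz
        assert np.allclose(image, [-first[0], -first[1], first[2]], atol=1e-12)

    def test_intra_chain_distances_preserved(self, toy_model):
        R = Rotation.from_euler("xyz", [11.0, -37.0, 101.0],
                                degrees=True).as_matrix()
        out = nv.apply_symmetry(toy_model, (R, np.array([3.0, -2.0, 7.0])))
        n = len(toy_model.atoms)
        orig = np.vstack([a.xyz for a in out.atoms[:n]])
        new = np.vstack([a.xyz for a in out.atoms[n:]])
        d_orig = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
        d_new = np.linalg.norm(new[:, None] - new[None, :], axis=-1)
        assert np.allclose(d_orig, d_new, atol=1e-9)

    def test_half_tetramer_completed_to_fourfold_ring(self):
        # keep two adjacent chains of a 4-fold ring, complete by a 2-fold
        spec = nv.ToyPoreSpec(ring_charges=((-0.5, 0.0),), n_fold=4,
                              ion_positions=(), water_positions=())
        model, _ = nv.generate_toy_pore(spec)
        half = nv.StructureModel(
            atoms=[a for a in model.atoms if a.chain in {"A", "B"}],
            name="half")
        R = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        full = nv.apply_symmetry(half, (R, np.zeros(3)))
        got = np.sort(np.vstack([a.xyz for a in full.atoms]), axis=0)
        want = np.sort(np.vstack([a.xyz for a in model.atoms]), axis=0)
        assert np.allclose(got, want, atol=1e-12)

    def test_improper_operator_rejected(self, toy_model):
        mirror = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="det"):
            nv.apply_symmetry(toy_model, (mirror, np.zeros(3)))

    def test_missing_operator_index(self, toy_model):
        with pytest.raises(IndexError):
            nv.apply_symmetry(toy_model, 5)


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------

class TestSuperpose:
    def test_self_superposition_is_exact(self, toy_model):
        res = nv.superpose(toy_model, toy_model, selection="all")
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_rigid_copy_recovered(self, toy_model):
        moved = copy.deepcopy(toy_model)
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        for a in moved.atoms:
            a.xyz = R @ a.xyz + t
        res = nv.superpose(toy_model, moved, selection="all")
        assert res.rmsd < 1e-9

    def test_matches_svd_oracle_and_beats_random_rotations(self, toy_model):
        rng = np.random.default_rng(11)
        perturbed = copy.deepcopy(toy_model)
        for a in perturbed.atoms:
            a.xyz = a.xyz + rng.normal(0.0, 0.4, size=3)
        res = nv.superpose(toy_model, perturbed, selection="all")
        A = toy_model.coords()
        B = np.vstack([a.xyz for a in perturbed.atoms])
        _, _, rmsd_oracle = kabsch_oracle(A, B)
        assert res.rmsd == pytest.approx(rmsd_oracle, rel=1e-9)
        # Kabsch optimality: no random rigid transform scores better
        for _ in range(50):
            Rr = Rotation.random(rng=rng).as_matrix()
            moved = B @ Rr.T
            moved += A.mean(axis=0) - moved.mean(axis=0)
            rmsd_r = np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1)))
            assert res.rmsd <= rmsd_r + 1e-12

    def test_invariant_to_pre_rotation(self, toy_model):
        rng = np.random.default_rng(3)
        perturbed = copy.deepcopy(toy_model)
        for a in perturbed.atoms:
            a.xyz = a.xyz + rng.normal(0.0, 0.3, size=3)
        base = nv.superpose(toy_model, perturbed, selection="all").rmsd
        pre = copy.deepcopy(perturbed)
        R = Rotation.from_euler("y", 73, degrees=True).as_matrix()
        for a in pre.atoms:
            a.xyz = R @ a.xyz
        assert nv.superpose(toy_model, pre, selection="all").rmsd == \
            pytest.approx(base, rel=1e-9)
        # and symmetric in its arguments
        assert nv.superpose(perturbed, toy_model, selection="all").rmsd == \
            pytest.approx(base, rel=1e-9)

    def test_fit_on_one_selection_score_on_another(self, toy_model):
        perturbed = copy.deepcopy(toy_model)
        rng = np.random.default_rng(5)
        for a in perturbed.atoms:
            a.xyz = a.xyz + rng.normal(0.0, 0.2, size=3)
        res = nv.superpose(toy_model, perturbed, selection="resi 178",
                           score_selection="resi 179")
        fit_only = nv.superpose(toy_model, perturbed, selection="resi 178")
        assert res.n_atoms == 4  # the 179 ring
        assert res.rmsd != pytest.approx(fit_only.rmsd)

    def test_empty_pairing_rejected(self, toy_model):
        with pytest.raises(ValueError, match="pairing"):
            nv.superpose(toy_model, toy_model, selection="resi 999")

    def test_mutation_site_atoms_drop_out_of_pairing(self, toy_model):
        # renaming one ring's atoms emulates a shorter mutant side chain:
        # pairing by atom name silently excludes them
        mutant = copy.deepcopy(toy_model)
        for a in mutant.atoms:
            if a.residue_number == 178:
                a.name = "OD1"
        with pytest.warns(UserWarning, match="unmatched"):
            res = nv.superpose(toy_model, mutant, selection="protein")
        assert res.n_atoms == 4  # only the 179 ring pairs
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)


# --------------------------------------------------------------------------
# Ion-site geometry
# --------------------------------------------------------------------------

class TestIonSites:
    def test_constructed_distances(self, toy_model):
        sites, report = nv.ion_site_geometry(toy_model)
        assert [s.label for s in sites.sites] == ["Na_I", "Na_II", "Na_III"]
        inter = {p["pair"]: p["distance"] for p in report["inter_site"]}
        assert inter[("Na_I", "Na_II")] == pytest.approx(2.80, abs=1e-9)
        assert inter[("Na_II", "Na_III")] == pytest.approx(5.60, abs=1e-9)

    def test_sites_ordered_extracellular_to_intracellular(self, toy_model):
        sites, _ = nv.ion_site_geometry(toy_model)
        z = [s.z_axial for s in sites.sites]
        assert z == sorted(z, reverse=True)

    def test_ordering_invariant_to_rigid_motion(self, toy_model):
        moved = copy.deepcopy(toy_model)
        R = Rotation.from_euler("x", 25, degrees=True).as_matrix()
        for a in moved.atoms:
            a.xyz = R @ a.xyz + np.array([5.0, 1.0, -2.0])
        sites, report = nv.ion_site_geometry(moved)
        inter = {p["pair"]: p["distance"] for p in report["inter_site"]}
        assert inter[("Na_I", "Na_II")] == pytest.approx(2.80, abs=1e-9)

    def test_coordination_census_at_cutoffs(self):
        # one oxygen 3.4 A from the ion: inside a 3.5 A shell, outside 3.3
        atoms = [
            nv.AtomRecord(serial=1, name="O", element="O", residue_name="GLY",
                          residue_number=1, chain="A",
                          xyz=np.array([3.4, 0.0, 0.0])),
            nv.AtomRecord(serial=2, name="NA", element="NA", residue_name="NA",
                          residue_number=2, chain="S",
                          xyz=np.zeros(3), is_hetero=True),
        ]
        model = nv.StructureModel(atoms=atoms)
        _, r35 = nv.ion_site_geometry(model, coordination_cutoff=3.5)
        _, r33 = nv.ion_site_geometry(model, coordination_cutoff=3.3)
        assert r35["sites"][0]["coordination_count"] == 1
        assert r33["sites"][0]["coordination_count"] == 0
        assert r35["sites"][0]["nearest_protein_atom"]["distance"] == \
            pytest.approx(3.4)

    def test_counts_monotone_in_cutoff(self, toy_model):
        counts = []
        for cutoff in (2.0, 3.5, 5.0, 8.0, 12.0):
            _, rep = nv.ion_site_geometry(toy_model,
                                          coordination_cutoff=cutoff)
            counts.append([s["coordination_count"] for s in rep["sites"]])
        arr = np.array(counts)
        assert np.all(np.diff(arr, axis=0) >= 0)

    def test_no_ions_warns_and_returns_empty(self):
        atoms = [nv.AtomRecord(serial=1, name="CA", element="C",
                               residue_name="ALA", residue_number=1,
                               chain="A", xyz=np.zeros(3))]
        model = nv.StructureModel(atoms=atoms)
        with pytest.warns(UserWarning, match="no sodium"):
            sites, report = nv.ion_site_geometry(model)
        assert sites.sites == [] and report["inter_site"] == []


class TestCompareSites:
    def _sites(self, shift=0.0):
        spec = nv.ToyPoreSpec(ion_positions=(10.0, 7.2, 1.6))
        model, _ = nv.generate_toy_pore(spec)
        if shift:
            for a in model.atoms:
                a.xyz = a.xyz + np.array([0.0, 0.0, shift])
        sites, _ = nv.ion_site_geometry(model)
        return sites

    def test_identical_sets_zero_displacement(self):
        s = self._sites()
        table = nv.compare_sites(s, s)
        assert np.allclose(table["displacement"], 0.0)

    def test_uniform_shift_reported(self):
        table = nv.compare_sites(self._sites(), self._sites(shift=0.3))
        assert np.allclose(table["displacement"], 0.3, atol=1e-9)

    def test_missing_site_flagged(self):
        a = self._sites()
        b = self._sites()
        b.sites = b.sites[1:]  # site nearest the extracellular side lost
        b.sites = [
            nv.IonSite(label=f"Na_{r}", xyz=s.xyz, z_axial=s.z_axial,
                       b_factor=s.b_factor, tetramer_id=s.tetramer_id)
            for r, s in zip(["I", "II"], b.sites)
        ]
        table = nv.compare_sites(a, b).set_index("label")
        assert not table.loc["Na_III", "in_b"]
        assert np.isnan(table.loc["Na_III", "displacement"])


def test_pore_axis_detected_after_rotation(toy_model):
    R = Rotation.from_euler("y", 90, degrees=True).as_matrix()
    coords = toy_model.coords(lambda a: a.is_protein) @ R.T
    frame = pore_axis_frame(coords)
    # rotated pore axis (now along x) is mapped back to z
    axis_world = frame[2]
    assert abs(axis_world @ np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0,
                                                                        abs=1e-9)
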