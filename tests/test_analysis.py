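"""H-bond detection, pose taxonomy, Kabsch RMSD, interface area."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aptadock import analysis, synthgen
from aptadock.analysis import (KeyResidueSet, classify_pose, detect_hbonds,
                               hbond_census, interface_area, kabsch_rmsd,
                               quadruplex_rmsd_distribution, rmsd_timecourse)
from aptadock.selection import ComplexModel
from aptadock.structio import HBondRole


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def test_planted_bonds_recovered_exactly(small_params):
    cm = synthgen.make_hbond_fixture(5, small_params)
    bonds = detect_hbonds(cm)
    assert len(bonds) == 5
    assert all(b.d_da <= 3.5 and b.angle_hda <= 30.0 for b in bonds)
    serials = [(b.donor_serial, b.acceptor_serial) for b in bonds]
    assert serials == sorted(serials)


def test_threshold_decoys_excluded(small_params):
    cm = synthgen.make_hbond_fixture(2, small_params)
    assert len(detect_hbonds(cm)) == 2
    # the fixture plants max(n,1)=2 decoys per violated criterion
    assert len(detect_hbonds(cm, d_max=3.7)) == 4   # distance decoys enter
    assert len(detect_hbonds(cm, a_max=50.0)) == 4  # angle decoys enter


def test_detection_matches_bruteforce_scan(small_params):
    cm = synthgen.make_pose_fixture("side", small_params)
    got = {(b.donor_serial, b.hydrogen_serial, b.acceptor_serial)
           for b in detect_hbonds(cm)}
    expected = set()
    for don_s, acc_s in ((cm.receptor, cm.ligand), (cm.ligand, cm.receptor)):
        serials = don_s.atom_by_serial()
        for _, d in don_s.iter_atoms():
            if d.hbond_role not in (HBondRole.DONOR, HBondRole.BOTH):
                continue
            for _, a in acc_s.iter_atoms():
                if a.hbond_role not in (HBondRole.ACCEPTOR, HBondRole.BOTH):
                    continue
                v = a.coords - d.coords
                dist = np.linalg.norm(v)
                if dist == 0 or dist > 0.35:
                    continue
                for hser in d.attached_hydrogens:
                    h = serials[hser][1]
                    vh = h.coords - d.coords
                    cosang = vh @ v / (np.linalg.norm(vh) * dist)
                    if math.degrees(math.acos(np.clip(cosang, -1, 1))) <= 30:
                        expected.add((d.serial, h.serial, a.serial))
    assert got == expected


def test_donor_without_hydrogen_warns(small_params):
    cm = synthgen.make_hbond_fixture(1, small_params)
    for r, a in cm.receptor.iter_atoms():
        a.attached_hydrogens = []
    with pytest.warns(UserWarning, match="without attached hydrogens"):
        assert detect_hbonds(cm) == []


def test_census_identical_snapshots(small_params):
    cm = synthgen.make_hbond_fixture(4, small_params)
    keys = KeyResidueSet(rbd_keys=["S1"], hbd_keys=[])
    single = hbond_census([cm], keys)
    triple = hbond_census([cm] * 3, keys)
    assert single == triple
    assert sum(single.values()) == 4


def test_census_half_planted_average(small_params):
    with_bond = synthgen.make_hbond_fixture(1, small_params)
    without = synthgen.make_hbond_fixture(0, small_params)
    keys = KeyResidueSet(rbd_keys=["S1"], hbd_keys=[])
    out = hbond_census([with_bond, without], keys)
    assert out["S1"] == pytest.approx(0.5)


def test_census_empty_interface_is_zero(small_params):
    cm = synthgen.make_hbond_fixture(0, small_params)
    out = hbond_census([cm], KeyResidueSet(rbd_keys=["S1"], hbd_keys=[]))
    assert all(v == 0.0 for v in out.values())


def test_census_unresolvable_key_rejected(small_params):
    cm = synthgen.make_hbond_fixture(1, small_params)
    with pytest.raises(ValueError, match="absent"):
        hbond_census([cm], KeyResidueSet(rbd_keys=["R999"], hbd_keys=[]))


# ---------------------------------------------------------------------------
# pose taxonomy
# ---------------------------------------------------------------------------

def test_fixture_labels_recovered(small_params):
    for label in ("sandwich", "side", "hug"):
        cm = synthgen.make_pose_fixture(label, small_params)
        out = classify_pose(cm)
        assert out.value == label
        assert out.evidence  # per-unit, per-domain booleans present


def test_monomer_touching_both_hbds_is_sandwich(small_params):
    # reuse the sandwich geometry but strip the ligand to its HBD-binder unit
    cm = synthgen.make_pose_fixture("sandwich", small_params)
    from aptadock.structio import DomainMap, DomainRole, Structure, annotate
    keep = cm.ligand_map.group("APT_B")
    residues = [r for r in cm.ligand.residues if r.key in keep]
    mono = annotate(Structure(residues, provenance=cm.ligand.provenance))
    lmap = DomainMap({"APT_B": keep}, {"APT_B": DomainRole.APT_HBD_BINDER})
    out = classify_pose(ComplexModel(cm.receptor, cm.receptor_map, mono, lmap))
    assert out.value == "sandwich"


def test_classification_is_total_and_exclusive(small_params):
    for label in ("sandwich", "side", "hug"):
        cm = synthgen.make_pose_fixture(label, small_params)
        assert classify_pose(cm).value in ("sandwich", "side", "hug",
                                           "unclassified")


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def test_kabsch_identity_is_zero():
    pts = np.random.default_rng(0).normal(size=(7, 3))
    assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)


def test_kabsch_rigid_transform_invariance():
    pts = np.random.default_rng(1).normal(size=(9, 3))
    rot = Rotation.from_euler("zyx", [0.4, -0.9, 2.2])
    moved = rot.apply(pts) + np.array([3.0, -1.0, 0.5])
    assert kabsch_rmsd(moved, pts) == pytest.approx(0.0, abs=1e-9)


def test_kabsch_matches_independent_solver():
    rng = np.random.default_rng(2)
    ref = rng.normal(size=(5, 3))
    mob = ref + rng.normal(scale=0.1, size=(5, 3))
    got = kabsch_rmsd(mob, ref)
    # independent optimal-rotation oracle
    rot, _ = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
    resid = rot.apply(mob - mob.mean(0)) - (ref - ref.mean(0))
    expected = 10.0 * math.sqrt(float(np.mean(np.sum(resid ** 2, axis=1))))
    assert got == pytest.approx(expected, abs=1e-4)


def test_kabsch_never_exceeds_raw_rmsd():
    rng = np.random.default_rng(3)
    for _ in range(5):
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3))
        raw = 10.0 * math.sqrt(float(np.mean(np.sum((a - b) ** 2, axis=1))))
        assert kabsch_rmsd(a, b) <= raw + 1e-9


def test_kabsch_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# quadruplex RMSD distribution
# ---------------------------------------------------------------------------

def test_unperturbed_core_rmsd_is_zero(small_params):
    s, lm = synthgen.make_toy_aptamer("monomer_quad", small_params)
    rmsds, counts, edges = quadruplex_rmsd_distribution(
        [s, s, s], lm.group("QUAD_CORE"), s)
    np.testing.assert_allclose(rmsds, 0.0, atol=1e-9)
    assert counts.sum() == 3


def test_core_rmsd_monotone_in_jitter(small_params):
    from aptadock import conformers
    s, lm = synthgen.make_toy_aptamer("monomer_quad", small_params)
    core = lm.group("QUAD_CORE")
    small = conformers.free_ensemble(s, 6, seed=5, perturb_amp=0.05)
    large = conformers.free_ensemble(s, 6, seed=5, perturb_amp=0.10)
    r_small, _, _ = quadruplex_rmsd_distribution(small.structures(), core, s)
    r_large, _, _ = quadruplex_rmsd_distribution(large.structures(), core, s)
    assert r_large[1:].mean() > r_small[1:].mean()


def test_core_size_enforced(small_params):
    s, lm = synthgen.make_toy_aptamer("monomer_quad", small_params)
    wrong = set(list(lm.group("QUAD_CORE"))[:10])
    with pytest.raises(ValueError, match="expected 12"):
        quadruplex_rmsd_distribution([s], wrong, s)


def test_timecourse_composition(small_params):
    from aptadock import conformers
    s, _ = synthgen.make_toy_aptamer("monomer_quad", small_params)
    snaps = conformers.free_ensemble(s, 4, seed=8).structures()
    series = rmsd_timecourse(snaps, 0)
    assert series[0] == pytest.approx(0.0, abs=1e-9)
    for i, snap in enumerate(snaps):
        assert series[i] == pytest.approx(
            kabsch_rmsd(snap.heavy_coords(), snaps[0].heavy_coords()))
    with pytest.raises(IndexError):
        rmsd_timecourse(snaps, 10)


# ---------------------------------------------------------------------------
# interface ("clash") area
# ---------------------------------------------------------------------------

def _mini(seed, center):
    import tests.test_rescoring as tr
    return tr._neutral_globule("A" if seed % 2 else "B", 1 + 100 * seed,
                               center, seed)


def test_distant_partners_bury_nothing():
    a = _mini(1, [0.0, 0.0, 0.0])
    b = _mini(2, [10.0, 0.0, 0.0])
    assert interface_area(a, b) == pytest.approx(0.0, abs=1e-9)


def test_interface_area_is_symmetric():
    a = _mini(1, [0.0, 0.0, 0.0])
    b = _mini(2, [1.0, 0.0, 0.0])
    assert interface_area(a, b) == pytest.approx(interface_area(b, a), abs=1e-9)


def test_interface_area_monotone_on_approach():
    a = _mini(1, [0.0, 0.0, 0.0])
    areas = [interface_area(a, _mini(2, [d, 0.0, 0.0]), n_points=256)
             for d in (2.0, 1.4, 1.0, 0.7)]
    assert areas[0] == pytest.approx(0.0, abs=1e-9)
    assert areas[1] < areas[2] < areas[3]


def test_two_sphere_interface_matches_cap_formula():
    from aptadock.structio import (Atom, Provenance, Residue, ResidueKind,
                                   Structure, annotate)

    def one_atom(chain, serial, pos):
        res = Residue(chain, 1, "ALA", ResidueKind.PROTEIN,
                      [Atom(serial, "CA", "C", np.asarray(pos, dtype=float))])
        return annotate(Structure([res], provenance=Provenance.SYNTHETIC))

    d = 0.5
    r = 0.170 + 0.14  # C radius + probe
    a = one_atom("A", 1, [0.0, 0.0, 0.0])
    b = one_atom("B", 2, [d, 0.0, 0.0])
    got = interface_area(a, b, n_points=4096)
    h = r - d / 2  # equal spheres: each buries a cap of height h
    expected = 2 * (2 * math.pi * r * h) / 2
    assert got == pytest.approx(expected, rel=0.02)


def test_clash_area_via_alignment(small_params):
    # superposing a rotated copy of the complex must reproduce the
    # direct aptamer/partner interface area
    cm = synthgen.make_pose_fixture("side", small_params)
    partner = _mini(3, [0.0, 1.5, 0.0])
    direct = interface_area(cm.ligand, partner, n_points=128)
    rot = Rotation.from_euler("xyz", [0.7, 0.2, -0.4])
    moved = ComplexModel(
        cm.receptor.with_coords(rot.apply(cm.receptor.coords()) + 2.0),
        cm.receptor_map,
        cm.ligand.with_coords(rot.apply(cm.ligand.coords()) + 2.0),
        cm.ligand_map)
    align = cm.receptor_map.group("RBD1")
    got = analysis.clash_area(moved, cm.receptor, partner, align, n_points=128)
    assert got == pytest.approx(direct, abs=0.05)
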