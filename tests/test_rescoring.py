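"""MM/GBSA components against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from aptadock import rescoring, synthgen
from aptadock.rescoring import (AtomParams, EnergyBreakdown, ForceFieldLite,
                                K_COULOMB, binding_free_energy, gb_energy,
                                mm_energy, sasa, snapshot_energy)
from aptadock.selection import ComplexModel
from aptadock.structio import (Atom, DomainMap, DomainRole, Provenance,
                               Residue, ResidueKind, Structure, annotate)


def _charged_structure(positions, resname="LYS", atom="NZ", chain="A"):
    """Each position becomes one +1-charged residue (LYS NZ)."""
    res = [Residue(chain, i + 1, resname, ResidueKind.PROTEIN,
                   [Atom(i + 1 + (1000 if chain != "A" else 0), atom, "N", p)])
           for i, p in enumerate(np.atleast_2d(positions))]
    return annotate(Structure(res, provenance=Provenance.SYNTHETIC))


def _dmap(s, role=DomainRole.RBD):
    return DomainMap({"G": {r.key for r in s.residues}}, {"G": role})


def test_coulomb_closed_form():
    # two +1e charges at 3.32 A: k_e / 3.32 = +100.02 kcal/mol
    a = _charged_structure(np.zeros(3))
    b = _charged_structure(np.array([0.332, 0.0, 0.0]), chain="B")
    cm = ComplexModel(a, _dmap(a), b, _dmap(b, DomainRole.APT_RBD_BINDER))
    e_coul, _ = mm_energy(cm, ForceFieldLite())
    assert e_coul == pytest.approx(K_COULOMB / 3.32, abs=1e-9)
    assert e_coul == pytest.approx(100.02, abs=0.01)


def test_lj_zero_at_sigma():
    ff = ForceFieldLite()
    sigma_n = 0.325  # N-N pair
    a = _charged_structure(np.zeros(3))
    b = _charged_structure(np.array([sigma_n, 0.0, 0.0]), chain="B")
    cm = ComplexModel(a, _dmap(a), b, _dmap(b, DomainRole.APT_RBD_BINDER))
    _, e_lj = mm_energy(cm, ff)
    assert e_lj == pytest.approx(0.0, abs=1e-9)


def test_mm_energy_matches_bruteforce_pair_loop(small_params):
    rec, rmap = synthgen.make_toy_receptor(
        synthgen.GenParams(seed=3, n_res_rbd=4, n_res_hbd=3))
    lig, lmap = synthgen.make_toy_aptamer(
        "monomer_plain", synthgen.GenParams(seed=4, apt_plain_len=5))
    cm = ComplexModel(rec, rmap, lig, lmap)
    ff = ForceFieldLite()
    e_coul, e_lj = mm_energy(cm, ff)
    pa, pb = ff.params(rec), ff.params(lig)
    ref_c = ref_lj = 0.0
    for i in range(len(pa.charge)):
        for j in range(len(pb.charge)):
            r = np.linalg.norm(pa.coords[i] - pb.coords[j])
            ref_c += K_COULOMB * pa.charge[i] * pb.charge[j] / (r * 10)
            sig = 0.5 * (pa.sigma[i] + pb.sigma[j])
            eps = math.sqrt(pa.epsilon[i] * pb.epsilon[j])
            ref_lj += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
    assert e_coul == pytest.approx(ref_c, rel=1e-10)
    assert e_lj == pytest.approx(ref_lj, rel=1e-10)


def test_unparameterized_atom_named_in_error():
    s = _charged_structure(np.zeros(3))
    s.residues[0].atoms[0].element = "Xx"
    with pytest.raises(ValueError, match="NZ"):
        ForceFieldLite().params(s)


def test_born_ion_closed_form():
    # single ion q=1e, Born radius 2 A, eps 1 -> 78.5
    p = AtomParams(np.array([1.0]), np.array([0.3]), np.array([0.1]),
                   np.array([0.2]), np.zeros((1, 3)))
    expected = -0.5 * (1 - 1 / 78.5) * K_COULOMB / 2.0
    assert gb_energy(p) == pytest.approx(expected, abs=1e-9)
    assert gb_energy(p) == pytest.approx(-81.96, abs=0.01)


def test_gb_zero_for_neutral_molecule(small_params):
    s, _ = synthgen.make_toy_aptamer("monomer_plain",
                                     synthgen.GenParams(seed=5, apt_plain_len=4))
    for res in s.residues:  # strip the phosphate charges
        for a in res.atoms:
            a.name = a.name if a.name != "P" else "C1X"
    s2 = _charged_structure(np.zeros(3), resname="ALA", atom="CB")
    assert gb_energy(s2) == 0.0


def test_gb_interaction_reaches_screened_coulomb_limit():
    single = AtomParams(np.array([1.0]), np.array([0.3]), np.array([0.1]),
                        np.array([0.2]), np.zeros((1, 3)))
    for r_nm in (20.0, 50.0):
        pair = AtomParams(np.array([1.0, 1.0]), np.full(2, 0.3), np.full(2, 0.1),
                          np.full(2, 0.2),
                          np.array([[0.0, 0.0, 0.0], [r_nm, 0.0, 0.0]]))
        inter = gb_energy(pair) - 2 * gb_energy(single)
        screened = -(1 - 1 / 78.5) * K_COULOMB / (r_nm * 10)
        assert inter == pytest.approx(screened, rel=1e-4)


def test_nonpositive_radius_rejected():
    p = AtomParams(np.array([1.0]), np.array([0.3]), np.array([0.1]),
                   np.array([-0.1]), np.zeros((1, 3)))
    with pytest.raises(ValueError, match="radius"):
        gb_energy(p)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _sphere_params(radii, coords):
    n = len(radii)
    return AtomParams(np.zeros(n), np.full(n, 0.3), np.full(n, 0.1),
                      np.asarray(radii, dtype=float),
                      np.asarray(coords, dtype=float).reshape(n, 3))


def test_sasa_isolated_atom_is_full_sphere():
    p = _sphere_params([0.19], [[0.0, 0.0, 0.0]])
    _, total = sasa(p, probe=0.14)
    assert total == pytest.approx(4 * math.pi * 0.33 ** 2, rel=1e-12)


def test_sasa_buried_atom_is_zero():
    # centre atom caged by 14 overlapping large spheres
    shell = [[0.25 * x, 0.25 * y, 0.25 * z]
             for x, y, z in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                             (0, 0, 1), (0, 0, -1), (1, 1, 1), (1, 1, -1),
                             (1, -1, 1), (1, -1, -1), (-1, 1, 1), (-1, 1, -1),
                             (-1, -1, 1), (-1, -1, -1)]]
    p = _sphere_params([0.1] + [0.3] * 14, [[0.0, 0.0, 0.0]] + shell)
    areas, _ = sasa(p, probe=0.14, n_points=256)
    assert areas[0] == 0.0


def test_sasa_two_spheres_match_cap_formula():
    r1 = r2 = 0.19 + 0.14
    d = 0.4
    p = _sphere_params([0.19, 0.19], [[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    _, total = sasa(p, probe=0.14, n_points=4096)
    # exposed area of equal spheres: each loses a cap of height h = r - d/2
    h = r1 - d / 2
    expected = 2 * (4 * math.pi * r1 ** 2 - 2 * math.pi * r1 * h)
    assert total == pytest.approx(expected, rel=0.01)


def test_sasa_quadrature_converges(small_params):
    s, _ = synthgen.make_toy_aptamer("monomer_plain",
                                     synthgen.GenParams(seed=6, apt_plain_len=6))
    _, a1 = sasa(s, n_points=512)
    _, a2 = sasa(s, n_points=1024)
    assert abs(a2 - a1) / a2 < 0.005


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------

def _neutral_globule(chain, serial0, center, seed):
    """Small neutral molecule: ALA/SER beads (no formal charges)."""
    rng = np.random.default_rng(seed)
    pts = synthgen._fcc_globule(8, 0.5, rng) + np.asarray(center)
    res = []
    for i, pt in enumerate(pts):
        name = "ALA" if i % 2 else "SER"
        atoms = [Atom(serial0 + 10 * i, "CA", "C", pt),
                 Atom(serial0 + 10 * i + 1, "CB", "C", pt + [0.14, 0, 0])]
        res.append(Residue(chain, i + 1, name, ResidueKind.PROTEIN, atoms))
    return annotate(Structure(res, provenance=Provenance.SYNTHETIC))


def _two_molecule_complex(offset):
    rec = _neutral_globule("A", 1, [0.0, 0.0, 0.0], seed=11)
    lig = _neutral_globule("D", 5000, offset, seed=12)
    rmap = DomainMap({"R": {r.key for r in rec.residues}}, {"R": DomainRole.RBD})
    lmap = DomainMap({"L": {r.key for r in lig.residues}},
                     {"L": DomainRole.APT_HBD_BINDER})
    return ComplexModel(rec, rmap, lig, lmap)


def test_breakdown_total_is_component_sum():
    e = EnergyBreakdown(1.25, -0.5, 3.0, -0.125)
    assert e.total == pytest.approx(1.25 - 0.5 + 3.0 - 0.125, abs=1e-12)


def test_noninteracting_limit_gives_zero():
    cm = _two_molecule_complex([100.0, 0.0, 0.0])
    e = snapshot_energy(cm)
    assert abs(e.total) < 0.1


def test_single_snapshot_sd_is_zero():
    cm = _two_molecule_complex([2.0, 0.0, 0.0])
    out = binding_free_energy([cm])
    assert out.sd == 0.0
    assert out.mean.total == pytest.approx(out.per_snapshot[0].total)


def test_tight_interface_beats_displaced():
    near = _two_molecule_complex([1.2, 0.0, 0.0])
    far = _two_molecule_complex([3.2, 0.0, 0.0])
    assert snapshot_energy(near).total < snapshot_energy(far).total


def test_empty_snapshot_list_rejected():
    with pytest.raises(ValueError):
        binding_free_energy([])
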