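"""Contact rule, attachment criteria, top-k selection, manifest arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptadock import synthgen
from aptadock.selection import (ComplexModel, EnsembleManifest, ScoredPose,
                                attachment_filter, contacts, manifest_counts,
                                select_top_k)
from aptadock.structio import (Atom, DomainMap, DomainRole, Provenance,
                               Residue, ResidueKind, Structure, annotate)


def _pair_complex(distance_nm):
    """One protein side-chain heavy atom vs one DNA heavy atom at a set gap."""
    rec = annotate(Structure([Residue("A", 1, "ALA", ResidueKind.PROTEIN, [
        Atom(1, "CA", "C", np.zeros(3)),
        Atom(2, "CB", "C", np.array([0.14, 0.0, 0.0]))])],
        provenance=Provenance.SYNTHETIC))
    lig = annotate(Structure([Residue("C", 1, "DT", ResidueKind.DNA, [
        Atom(10, "P", "P", np.array([0.14 + distance_nm, 0.0, 0.0]))])],
        provenance=Provenance.SYNTHETIC))
    rmap = DomainMap({"R": {("A", 1)}}, {"R": DomainRole.RBD})
    lmap = DomainMap({"L": {("C", 1)}}, {"L": DomainRole.APT_RBD_BINDER})
    return ComplexModel(rec, rmap, lig, lmap)


def test_contact_threshold_inclusive():
    hit, n = contacts(_pair_complex(0.44), "R", "L")
    assert hit and n == 1
    miss, n = contacts(_pair_complex(0.46), "R", "L")
    assert not miss and n == 0


def test_contact_ignores_backbone_ca():
    cm = _pair_complex(10.0)
    # move the DNA atom within range of CA but not CB
    cm.ligand.residues[0].atoms[0].coords = np.array([-0.4, 0.0, 0.0])
    hit, _ = contacts(cm, "R", "L")
    assert not hit


def test_contact_count_matches_bruteforce(small_params):
    cm = synthgen.make_pose_fixture("side", small_params)
    rmap, lmap = cm.receptor_map, cm.ligand_map
    ga = rmap.group("HBD1")
    gb = lmap.group("APT_B")
    _, count = contacts(cm, ga, gb)
    pa = [a.coords for r in cm.receptor.residues if r.key in ga
          for a in r.atoms if a.is_sidechain and not a.is_hydrogen]
    pb = [a.coords for r in cm.ligand.residues if r.key in gb
          for a in r.atoms if not a.is_hydrogen]
    ref = sum(1 for x in pa for y in pb if np.linalg.norm(x - y) <= 0.45)
    assert count == ref > 0


def test_contact_monotone_in_cutoff(small_params):
    cm = synthgen.make_pose_fixture("side", small_params)
    ga = cm.receptor_map.group("HBD1")
    gb = cm.ligand_map.group("APT_B")
    counts = [contacts(cm, ga, gb, cutoff=c)[1] for c in (0.3, 0.45, 0.6, 0.9)]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_empty_group_rejected(small_params):
    cm = synthgen.make_pose_fixture("side", small_params)
    with pytest.raises(ValueError):
        contacts(cm, set(), cm.ligand_map.group("APT_B"))


def test_attachment_passes_for_attached_heterodimer(small_params):
    cm = synthgen.make_pose_fixture("hug", small_params)
    assert attachment_filter(cm)


def test_attachment_fails_when_a_unit_detaches(small_params):
    cm = synthgen.make_pose_fixture("hug", small_params)
    unit_a = cm.ligand_map.union(cm.ligand_map.by_role(DomainRole.APT_RBD_BINDER))
    synthgen._translate_group(cm.ligand, unit_a, np.array([0.0, -20.0, 0.0]))
    assert not attachment_filter(cm)


def test_monomer_on_wrong_domain_fails():
    cm = _pair_complex(0.3)  # RBD-binder touching the RBD: passes
    assert attachment_filter(cm)
    cm.ligand_map.roles["L"] = DomainRole.APT_HBD_BINDER
    with pytest.raises(ValueError):
        # HBD-binder but the receptor map declares no HBD group
        attachment_filter(cm)


def test_monomer_hbd_binder_touching_only_rbd_fails(small_params):
    receptor, rmap = synthgen.make_toy_receptor(small_params)
    lig, lmap = synthgen.make_toy_aptamer("monomer_plain", small_params)
    # park the HBD-binder monomer on an RBD
    pts, _ = synthgen._group_heavy(receptor, rmap.group("RBD1"),
                                   sidechain_only=True)
    anchor = pts[np.argmin(pts[:, 1])]
    lp = lig.heavy_coords()
    top = lp[np.argmax(lp[:, 1])]
    synthgen._translate_group(lig, {r.key for r in lig.residues},
                              anchor - np.array([0.0, 0.3, 0.0]) - top)
    cm = ComplexModel(receptor, rmap, lig, lmap)
    assert not attachment_filter(cm)


# ---------------------------------------------------------------------------
# top-k selection
# ---------------------------------------------------------------------------

def _group(scores, passed=True):
    return [ScoredPose(f"p{i}", s, passed) for i, s in enumerate(scores)]


def test_topk_takes_best_passing():
    groups = {"g": _group([1.0, 5.0, 3.0, 2.0])}
    out = select_top_k(groups, 3)
    assert [p.score for p in out["g"]] == [5.0, 3.0, 2.0]


def test_topk_keeps_all_when_short():
    groups = {"g": _group([1.0, 2.0]) + _group([9.0], passed=False)}
    out = select_top_k(groups, 3)
    assert len(out["g"]) == 2
    assert all(p.passed for p in out["g"])


def test_topk_84_groups_yield_252():
    groups = {(r, l): _group([3.0, 2.0, 1.0, 0.5])
              for r in range(7) for l in range(12)}
    out = select_top_k(groups, 3)
    assert sum(len(v) for v in out.values()) == 252


def test_topk_7_groups_yield_21():
    groups = {(r, 0): _group([3.0, 2.0, 1.0, 0.5]) for r in range(7)}
    assert sum(len(v) for v in select_top_k(groups, 3).values()) == 21


def test_topk_tie_break_is_deterministic():
    groups = {"g": [ScoredPose("b", 1.0, True), ScoredPose("a", 1.0, True)]}
    out = select_top_k(groups, 1)
    assert out["g"][0].pose_id == "a"


@given(st.lists(st.tuples(st.integers(0, 6), st.booleans()), max_size=30),
       st.integers(1, 5))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_topk_size_equals_min_rule(poses, k):
    group = [ScoredPose(f"p{i}", float(s), ok) for i, (s, ok) in enumerate(poses)]
    out = select_top_k({"g": group}, k)
    assert len(out["g"]) == min(k, sum(p.passed for p in group))


# ---------------------------------------------------------------------------
# manifest arithmetic
# ---------------------------------------------------------------------------

def test_manifest_counts_heterodimer_campaign():
    c = manifest_counts(EnsembleManifest(7, 20, 12, 20, 3))
    assert c == {"docked_pairs": 33600, "variants": 84, "max_selected": 252}


def test_manifest_counts_monomer_campaign():
    c = manifest_counts(EnsembleManifest(7, 20, 1, 20, 3))
    assert c["docked_pairs"] == 2800
    assert c["max_selected"] == 21


def test_manifest_counts_degenerate():
    c = manifest_counts(EnsembleManifest(1, 1, 1, 1, 1))
    assert c == {"docked_pairs": 1, "variants": 1, "max_selected": 1}


def test_campaign_total_closed_form():
    het = manifest_counts(EnsembleManifest(7, 20, 12, 20, 3))["max_selected"]
    mono = manifest_counts(EnsembleManifest(7, 20, 1, 20, 3))["max_selected"]
    assert 2 * het + 3 * mono == 567


@given(st.integers(1, 9), st.integers(1, 9), st.integers(1, 9),
       st.integers(1, 9), st.integers(1, 4))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_manifest_counts_property(rv, rs, lv, ls, k):
    c = manifest_counts(EnsembleManifest(rv, rs, lv, ls, k))
    assert c["docked_pairs"] == rv * rs * lv * ls
    assert c["max_selected"] == rv * lv * k
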