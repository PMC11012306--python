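"""Geometric analysis of receptor/aptamer complexes.

Hydrogen-bond census with the geometric criteria (donor-acceptor distance
<= 3.5 A and H-donor-acceptor angle <= 30 deg), the three-way pose taxonomy
(sandwich / side / hug), Kabsch-superposed RMSDs (whole-complex time courses
and the 12-residue quadruplex core), and buried interface area as the
steric-clash proxy against the receptor's natural partner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .rescoring import ForceFieldLite, sasa
from .selection import ComplexModel, contacts
from .structio import DomainMap, DomainRole, HBondRole, Residue, Structure

HB_DMAX_ANGSTROM = 3.5
HB_AMAX_DEG = 30.0
POSE_CUTOFF = 0.45  # nm
HIST_BIN_ANGSTROM = 0.25

#: key receptor residues: the seven RBD residues implicated in receptor
#: binding and the ten basic HBD residues implicated in heparin binding
DEFAULT_RBD_KEYS = ["Y21", "Y25", "I43", "N62", "D63", "E64", "Q89"]
DEFAULT_HBD_KEYS = ["R123", "R124", "K125", "K140", "R145", "R149", "R156",
                    "K162", "R164", "R165"]


@dataclass(frozen=True)
class HBond:
    donor_serial: int
    hydrogen_serial: int
    acceptor_serial: int
    d_da: float      # Angstrom
    angle_hda: float  # degrees
    donor_residue: tuple[str, int] = ("", 0)
    acceptor_residue: tuple[str, int] = ("", 0)


@dataclass
class PoseLabel:
    value: str  # sandwich | side | hug | unclassified
    evidence: dict[str, dict[str, bool]]  # aptamer unit -> domain -> contact


@dataclass
class KeyResidueSet:
    """Key residues given as one-letter-code + resseq strings (e.g. 'R123')."""

    rbd_keys: list[str] = field(default_factory=lambda: list(DEFAULT_RBD_KEYS))
    hbd_keys: list[str] = field(default_factory=lambda: list(DEFAULT_HBD_KEYS))

    def resseqs(self) -> list[int]:
        return [int(k[1:]) for k in self.rbd_keys + self.hbd_keys]


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(cm: ComplexModel, d_max: float = HB_DMAX_ANGSTROM,
                  a_max: float = HB_AMAX_DEG) -> list[HBond]:
    """All inter-molecular donor-H...acceptor triplets meeting the criteria.

    Donors without attached hydrogens are skipped (with a warning naming the
    count). Both directions (receptor donor -> ligand acceptor and vice
    versa) are scanned. Output is sorted by (donor serial, acceptor serial).
    """
    d_max_nm = d_max * 0.1
    bonds: list[HBond] = []
    skipped = 0
    rec_ser = cm.receptor.atom_by_serial()
    lig_ser = cm.ligand.atom_by_serial()

    def side_atoms(s: Structure, want_donor: bool):
        out = []
        for r, a in s.iter_atoms():
            if a.is_hydrogen:
                continue
            if want_donor and a.hbond_role in (HBondRole.DONOR, HBondRole.BOTH):
                out.append((r, a))
            if not want_donor and a.hbond_role in (HBondRole.ACCEPTOR, HBondRole.BOTH):
                out.append((r, a))
        return out

    for don_struct, acc_struct, serials in (
            (cm.receptor, cm.ligand, rec_ser),
            (cm.ligand, cm.receptor, lig_ser)):
        donors = side_atoms(don_struct, True)
        acceptors = side_atoms(acc_struct, False)
        if not donors or not acceptors:
            continue
        dk = cKDTree(np.array([a.coords for _, a in donors]))
        ak = cKDTree(np.array([a.coords for _, a in acceptors]))
        for di, ais in enumerate(dk.query_ball_tree(ak, d_max_nm)):
            dres, datom = donors[di]
            if not datom.attached_hydrogens:
                if ais:
                    skipped += 1
                continue
            for ai in ais:
                ares, aatom = acceptors[ai]
                v_da = aatom.coords - datom.coords
                d_da = float(np.linalg.norm(v_da))
                if d_da > d_max_nm or d_da == 0.0:
                    continue
                for hser in datom.attached_hydrogens:
                    _, hatom = serials[hser]
                    v_dh = hatom.coords - datom.coords
                    cosang = float(v_dh @ v_da
                                   / (np.linalg.norm(v_dh) * d_da))
                    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if ang <= a_max:
                        bonds.append(HBond(datom.serial, hatom.serial,
                                           aatom.serial, d_da * 10.0, ang,
                                           dres.key, ares.key))
    if skipped:
        warnings.warn(f"{skipped} donor(s) without attached hydrogens skipped",
                      stacklevel=2)
    bonds.sort(key=lambda b: (b.donor_serial, b.acceptor_serial))
    return bonds


def hbond_census(snapshots: Sequence[ComplexModel], keys: KeyResidueSet | None = None
                 ) -> dict[str, float]:
    """Time-averaged H-bond count per key receptor residue (multiplicities).

    Key residues are matched per chain by residue number; counts for the same
    number on different chains are summed (the receptor is a homodimer).
    Non-key receptor residues are aggregated under 'other'.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    keys = keys or KeyResidueSet()
    key_list = keys.rbd_keys + keys.hbd_keys
    wanted = {int(k[1:]): k for k in key_list}
    rec = snapshots[0].receptor
    present = {r.resseq for r in rec.residues}
    missing = [k for n, k in wanted.items() if n not in present]
    if missing:
        raise ValueError(f"key residues absent from receptor: {missing}")
    totals = {k: 0.0 for k in key_list}
    totals["other"] = 0.0
    rec_keys = {r.key for r in rec.residues}
    for cm in snapshots:
        for b in detect_hbonds(cm):
            res_key = (b.donor_residue if b.donor_residue in rec_keys
                       else b.acceptor_residue)
            label = wanted.get(res_key[1], "other")
            totals[label] += 1.0
    n = len(snapshots)
    return {k: v / n for k, v in totals.items()}


# ---------------------------------------------------------------------------
# pose taxonomy
# ---------------------------------------------------------------------------

def classify_pose(cm: ComplexModel, cutoff: float = POSE_CUTOFF) -> PoseLabel:
    """Three-way pose taxonomy from per-unit/per-domain contact evidence.

    Precedence: (1) sandwich - some single aptamer unit contacts both HBDs;
    (2) hug - the RBD-binder unit contacts both RBDs (interior) while the
    HBD-binder contacts exactly one HBD; (3) side - the HBD-binder contacts
    exactly one HBD and the RBD-binder (if any) contacts at most one RBD.
    Anything else is unclassified. A missing unit (monomeric aptamer)
    satisfies 'at most one' vacuously but never 'exactly one' or 'both'.
    """
    rmap, lmap = cm.receptor_map, cm.ligand_map
    hbds = sorted(rmap.by_role(DomainRole.HBD))
    rbds = sorted(rmap.by_role(DomainRole.RBD))
    if not hbds or not rbds:
        raise ValueError("receptor domain map lacks HBD/RBD groups")
    units = {
        "rbd_binder": lmap.union(lmap.by_role(DomainRole.APT_RBD_BINDER)),
        "hbd_binder": lmap.union(lmap.by_role(DomainRole.APT_HBD_BINDER)),
    }
    units = {k: v for k, v in units.items() if v}
    if not units:
        raise ValueError("ligand domain map declares no binding-unit role")

    evidence: dict[str, dict[str, bool]] = {}
    for uname, ukeys in units.items():
        evidence[uname] = {}
        for dom in hbds + rbds:
            got, _ = contacts(cm, rmap.group(dom), ukeys, cutoff)
            evidence[uname][dom] = got

    def n_hbd(u): return sum(evidence[u][d] for d in hbds)
    def n_rbd(u): return sum(evidence[u][d] for d in rbds)

    label = "unclassified"
    if any(n_hbd(u) >= 2 for u in units):
        label = "sandwich"
    elif ("rbd_binder" in units and n_rbd("rbd_binder") >= 2
          and "hbd_binder" in units and n_hbd("hbd_binder") == 1):
        label = "hug"
    elif ("hbd_binder" in units and n_hbd("hbd_binder") == 1
          and ("rbd_binder" not in units or n_rbd("rbd_binder") <= 1)):
        label = "side"
    return PoseLabel(label, evidence)


# ---------------------------------------------------------------------------
# RMSD machinery
# ---------------------------------------------------------------------------

def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray,
                return_transform: bool = False):
    """Least-squares optimal-superposition RMSD (Angstrom; inputs in nm).

    Proper rotation enforced (det = +1) via SVD sign correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"coordinate count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - mc, reference - rc
    u, _, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = (rot @ x.T).T
    rmsd_nm = math.sqrt(float(np.mean(np.sum((moved - y) ** 2, axis=1))))
    if return_transform:
        return rmsd_nm * 10.0, rot, rc - rot @ mc
    return rmsd_nm * 10.0


def _group_heavy_coords(s: Structure, keys: set[tuple[str, int]]) -> np.ndarray:
    return np.array([a.coords for r in s.residues if r.key in keys
                     for a in r.atoms if not a.is_hydrogen])


def quadruplex_rmsd_distribution(snapshots: Sequence[Structure],
                                 core_group: set[tuple[str, int]],
                                 reference: Structure,
                                 expected_core_size: int | None = 12,
                                 bin_width: float = HIST_BIN_ANGSTROM
                                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-snapshot Kabsch RMSD of the quadruplex core vs its reference.

    Returns (rmsds [A], histogram counts, bin edges [A]). The core group
    defaults to the 12 residues of the quadruplex region; pass
    ``expected_core_size=None`` to lift the check.
    """
    if expected_core_size is not None and len(core_group) != expected_core_size:
        raise ValueError(f"core group has {len(core_group)} residues, "
                         f"expected {expected_core_size}")
    ref = _group_heavy_coords(reference, core_group)
    rmsds = np.array([kabsch_rmsd(_group_heavy_coords(s, core_group), ref)
                      for s in snapshots])
    hi = max(bin_width, float(np.ceil(rmsds.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(rmsds, bins=edges)
    return rmsds, counts, edges


def rmsd_timecourse(snapshots: Sequence[Structure], reference_index: int
                    ) -> np.ndarray:
    """All-heavy-atom Kabsch RMSD of each snapshot vs a reference snapshot."""
    if not 0 <= reference_index < len(snapshots):
        raise IndexError("reference index out of range")
    ref = snapshots[reference_index].heavy_coords()
    return np.array([kabsch_rmsd(s.heavy_coords(), ref) for s in snapshots])


# ---------------------------------------------------------------------------
# buried interface ("clash") area
# ---------------------------------------------------------------------------

def interface_area(a: Structure, b: Structure, n_points: int = 128,
                   half: bool = True) -> float:
    """Buried interface area between two structures, nm^2.

    (SASA(a) + SASA(b) - SASA(a u b)) / 2 by default; ``half=False`` returns
    the total delta-SASA instead.
    """
    ff = ForceFieldLite()
    pa, pb = ff.params(a), ff.params(b)
    _, sa_a = sasa(pa, n_points=n_points, ff=ff)
    _, sa_b = sasa(pb, n_points=n_points, ff=ff)
    from .rescoring import AtomParams
    merged = AtomParams(np.concatenate([pa.charge, pb.charge]),
                        np.concatenate([pa.sigma, pb.sigma]),
                        np.concatenate([pa.epsilon, pb.epsilon]),
                        np.concatenate([pa.radius, pb.radius]),
                        np.vstack([pa.coords, pb.coords]))
    _, sa_ab = sasa(merged, n_points=n_points, ff=ff)
    buried = sa_a + sa_b - sa_ab
    return float(buried / 2.0 if half else buried)


def clash_area(cm: ComplexModel, ref_receptor: Structure, ref_partner: Structure,
               align_group: set[tuple[str, int]], n_points: int = 128,
               half: bool = True) -> float:
    """Steric-clash proxy: aptamer/partner buried area after superposition.

    The complex's receptor is Kabsch-superposed onto ``ref_receptor`` using
    the heavy atoms of ``align_group`` (present in both receptors, e.g. the
    RBD core); the transplanted aptamer is then evaluated against the
    reference receptor's natural partner ``ref_partner``.
    """
    mob = _group_heavy_coords(cm.receptor, align_group)
    ref = _group_heavy_coords(ref_receptor, align_group)
    if mob.shape != ref.shape:
        raise ValueError("alignment group mismatch between receptors")
    _, rot, trans = kabsch_rmsd(mob, ref, return_transform=True)
    apt = cm.ligand.with_coords((rot @ cm.ligand.coords().T).T + trans)
    return interface_area(apt, ref_partner, n_points=n_points, half=half)
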