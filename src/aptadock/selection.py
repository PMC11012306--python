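"""Ensemble bookkeeping: contact tests, attachment criteria, top-k selection.

The attachment criteria formalise the study's pose filter: the RBD-binding
aptamer unit must contact the receptor-binding domains and the HBD-binding
unit must contact the heparin-binding domains, where "contact" means at least
one protein side-chain heavy atom within 0.45 nm of a DNA heavy atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import DomainMap, DomainRole, ResidueKind, Structure

CONTACT_CUTOFF = 0.45  # nm, side-chain heavy atom vs DNA heavy atom


@dataclass
class EnsembleManifest:
    """Campaign arithmetic: variants x snapshots on each side, top-k kept."""

    n_receptor_variants: int = 7
    n_receptor_snapshots: int = 20
    n_ligand_variants: int = 12
    n_ligand_snapshots: int = 20
    top_k: int = 3

    def __post_init__(self) -> None:
        for name in ("n_receptor_variants", "n_receptor_snapshots",
                     "n_ligand_variants", "n_ligand_snapshots", "top_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ComplexModel:
    """A receptor/ligand pair with the ligand already in its posed position."""

    receptor: Structure
    receptor_map: DomainMap
    ligand: Structure
    ligand_map: DomainMap
    pose: object | None = None     # DockPose metadata, if docked
    label: object | None = None    # PoseLabel, once classified

    def merged(self) -> Structure:
        """Single structure with sequential serials (no collisions)."""
        residues = []
        serial = 0
        for src in (self.receptor, self.ligand):
            for r in src.copy().residues:
                for a in r.atoms:
                    serial += 1
                    a.serial = serial
                    a.attached_hydrogens = []
                residues.append(r)
        from .structio import annotate
        merged = Structure(residues, title="complex")
        return annotate(merged)


# ---------------------------------------------------------------------------
# contacts & attachment criteria
# ---------------------------------------------------------------------------

def _sidechain_heavy_coords(s: Structure, keys: Iterable[tuple[str, int]]) -> np.ndarray:
    keys = set(keys)
    pts = [a.coords for r in s.residues if r.key in keys
           for a in r.atoms
           if not a.is_hydrogen and (a.is_sidechain if r.kind is ResidueKind.PROTEIN else True)]
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def contacts(cm: ComplexModel, group_a: str | Iterable[tuple[str, int]],
             group_b: str | Iterable[tuple[str, int]],
             cutoff: float = CONTACT_CUTOFF) -> tuple[bool, int]:
    """Contact test between a receptor group and a ligand group.

    Counts (protein side-chain heavy atom, DNA heavy atom) pairs within
    ``cutoff``; returns (any_contact, pair_count). Groups may be passed as
    names in the respective domain maps or as explicit residue-key sets.
    """
    keys_a = cm.receptor_map.group(group_a) if isinstance(group_a, str) else set(group_a)
    keys_b = cm.ligand_map.group(group_b) if isinstance(group_b, str) else set(group_b)
    if not keys_a or not keys_b:
        raise ValueError("empty contact group")
    pa = _sidechain_heavy_coords(cm.receptor, keys_a)
    pb = _sidechain_heavy_coords(cm.ligand, keys_b)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("contact group selects no heavy atoms")
    count = cKDTree(pa).count_neighbors(cKDTree(pb), cutoff)
    return bool(count), int(count)


def _role_union(dm: DomainMap, role: DomainRole) -> set[tuple[str, int]]:
    return dm.union(dm.by_role(role))


def attachment_filter(cm: ComplexModel, cutoff: float = CONTACT_CUTOFF) -> bool:
    """True iff every aptamer binding unit touches its designated domain set.

    Heterodimers must have the RBD-binder unit in contact with RBD1|RBD2 and
    the HBD-binder unit in contact with HBD1|HBD2; a monomer passes iff its
    single unit contacts its role's domain set.
    """
    rbd_unit = _role_union(cm.ligand_map, DomainRole.APT_RBD_BINDER)
    hbd_unit = _role_union(cm.ligand_map, DomainRole.APT_HBD_BINDER)
    if not rbd_unit and not hbd_unit:
        raise ValueError("ligand domain map declares no binding-unit role")
    rbd_domains = _role_union(cm.receptor_map, DomainRole.RBD)
    hbd_domains = _role_union(cm.receptor_map, DomainRole.HBD)
    if rbd_unit:
        ok, _ = contacts(cm, rbd_domains, rbd_unit, cutoff)
        if not ok:
            return False
    if hbd_unit:
        ok, _ = contacts(cm, hbd_domains, hbd_unit, cutoff)
        if not ok:
            return False
    return True


# ---------------------------------------------------------------------------
# top-k selection & manifest arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredPose:
    """A docked pose reduced to what selection needs (higher score = better)."""

    pose_id: str
    score: float
    passed: bool  # attachment criteria


def select_top_k(groups: Mapping[Hashable, Sequence[ScoredPose]],
                 k: int) -> dict[Hashable, list[ScoredPose]]:
    """Per variant pair, keep the best min(k, available) attachment-passing poses.

    Sorting is by score descending with a deterministic pose_id tie-break.
    Groups with fewer than k passing poses keep all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[Hashable, list[ScoredPose]] = {}
    for key, poses in groups.items():
        passing = [p for p in poses if p.passed]
        passing.sort(key=lambda p: (-p.score, p.pose_id))
        out[key] = passing[:k]
    return out


def manifest_counts(m: EnsembleManifest) -> dict[str, int]:
    """Closed-form campaign arithmetic (docked pairs, variants, max selected)."""
    docked = (m.n_receptor_variants * m.n_receptor_snapshots
              * m.n_ligand_variants * m.n_ligand_snapshots)
    variants = m.n_receptor_variants * m.n_ligand_variants
    return {
        "docked_pairs": docked,
        "variants": variants,
        "max_selected": variants * m.top_k,
    }
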