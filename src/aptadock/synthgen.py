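"""Seeded synthetic receptor/aptamer structures and ground-truth fixtures.

The generator emulates the geometry the pipeline assumes without any real
input data: a homodimeric protein whose two monomers each consist of a
receptor-binding globule (RBD) and a heparin-binding globule (HBD) joined by
a flexible 12-residue linker; DNA aptamer monomers (one carrying a
12-residue quadruplex core built as three stacked 4-residue rings) and
heterodimers joined by a 10-residue thymine linker; and fixtures with planted
poses and hydrogen bonds that close the loop with the analysis module.

Globular domains are beads on a jittered FCC lattice inside a sphere; linkers
are bond-length-renormalised bridge walks. Every residue carries a backbone
node, one to three pseudo side-chain heavy atoms pointing radially outward,
and explicit hydrogens on donors, so interface contacts and H-bond geometry
are well defined. All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .selection import ComplexModel
from .structio import (Atom, DomainMap, DomainRole, Provenance, Residue,
                       ResidueKind, Structure, annotate)

# side-chain templates: atom name, element, offset multiplier along the
# outward direction (nm). Hydrogens are added for donor atoms afterwards.
_PROT_SIDE = {
    "ALA": [("CB", "C", 0.14)],
    "PRO": [("CB", "C", 0.14)],
    "LEU": [("CB", "C", 0.14), ("CG", "C", 0.28), ("CD1", "C", 0.42)],
    "ILE": [("CB", "C", 0.14), ("CG1", "C", 0.28)],
    "SER": [("CB", "C", 0.14), ("OG", "O", 0.28)],
    "TYR": [("CB", "C", 0.14), ("CG", "C", 0.28), ("OH", "O", 0.42)],
    "ASN": [("CB", "C", 0.14), ("OD1", "O", 0.28), ("ND2", "N", 0.40)],
    "GLN": [("CB", "C", 0.14), ("OE1", "O", 0.28), ("NE2", "N", 0.40)],
    "ASP": [("CB", "C", 0.14), ("OD1", "O", 0.28)],
    "GLU": [("CB", "C", 0.14), ("OE1", "O", 0.28)],
    "ARG": [("CB", "C", 0.14), ("CD", "C", 0.28), ("NH1", "N", 0.42)],
    "LYS": [("CB", "C", 0.14), ("NZ", "N", 0.28)],
}
#: donor heavy atoms that receive one explicit hydrogen
_PROT_DONOR_H = {"OG", "OH", "ND2", "NE2", "NH1", "NZ"}

_DNA_SIDE = {
    "DG": [("C1'", "C", 0.15), ("N2", "N", 0.28), ("O6", "O", 0.38), ("N7", "N", 0.30)],
    "DT": [("C1'", "C", 0.15), ("N3", "N", 0.28), ("O4", "O", 0.38)],
    "DA": [("C1'", "C", 0.15), ("N6", "N", 0.28), ("N7", "N", 0.38)],
    "DC": [("C1'", "C", 0.15), ("N4", "N", 0.28), ("O2", "O", 0.38)],
}
_DNA_DONOR_H = {"N2", "N3", "N6", "N4"}

#: resname palette cycled over globule residues (mix of charge, polarity, size)
_GLOBULE_PALETTE = ["ALA", "SER", "ARG", "ASP", "LEU", "ASN", "LYS", "GLU",
                    "TYR", "GLN", "ILE", "ALA"]
#: the receptor interdomain linker sequence (one-letter RPKKDRARQENP)
_LINKER_SEQ = ["ARG", "PRO", "LYS", "LYS", "ASP", "ARG", "ALA", "ARG",
               "GLN", "GLU", "ASN", "PRO"]
_DNA_PALETTE = ["DT", "DA", "DC", "DG"]


@dataclass
class GenParams:
    """Knobs of the synthetic universe (lengths in residues, distances in nm)."""

    seed: int = 1
    n_res_rbd: int = 110
    n_res_hbd: int = 55
    linker_len_receptor: int = 12
    apt_core_len: int = 12
    apt_linker_len: int = 10
    apt_tail_len: int = 8
    apt_plain_len: int = 18
    bead_spacing: float = 0.55
    domain_radius: float | None = None  # derived from counts when None
    hbd_separation: float = 5.5         # nm, HBD1-HBD2 COM distance of the build
    hbd_height: float = 2.2             # nm, HBDs sit above the RBD dimer core
    apt_unit_separation: float = 3.0    # nm, heterodimer unit-unit distance
    dna_bond: float = 0.65              # nm, backbone spacing in DNA chains

    def __post_init__(self) -> None:
        for name in ("n_res_rbd", "n_res_hbd", "linker_len_receptor",
                     "apt_core_len", "apt_linker_len", "apt_tail_len",
                     "apt_plain_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bead_spacing <= 0:
            raise ValueError("bead_spacing must be > 0")


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _fcc_globule(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """n jittered FCC lattice points inside a sphere, centred at the origin."""
    a = spacing * math.sqrt(2.0)
    m = max(2, int(math.ceil((n / 4.0) ** (1 / 3))) + 2)
    base = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    cells = np.array([[i, j, k] for i in range(-m, m + 1)
                      for j in range(-m, m + 1) for k in range(-m, m + 1)])
    pts = (cells[:, None, :] + base[None, :, :]).reshape(-1, 3) * a
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    pts = pts[order[:n]]
    pts = pts - pts.mean(axis=0)
    return pts + rng.normal(scale=0.02, size=pts.shape)


def _bridge_chain(start: np.ndarray, end: np.ndarray, n: int, bond: float,
                  rng: np.random.Generator) -> np.ndarray:
    """n interior beads of a helical bridge from start to end.

    The path winds around the start-end axis with a sine radial envelope
    (endpoints exactly on the anchors) and a total turn chosen so the contour
    length roughly matches (n+1) bonds, then gets a small seeded jitter and a
    bond-length relaxation with the endpoints pinned. The permanent kinks
    matter: a straight bead chain would be a torsional mechanism in the
    pairwise-spring elastic network.
    """
    axis = end - start
    span = float(np.linalg.norm(axis))
    u = axis / span if span > 1e-9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(u, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    radius = 0.45 * bond
    contour = bond * (n + 1)
    excess = contour ** 2 - span ** 2
    total_turn = math.sqrt(excess) / radius if excess > 0 else 2.0 * math.pi
    phase = rng.uniform(0, 2 * math.pi)
    t = np.arange(1, n + 1) / (n + 1.0)
    theta = total_turn * t + phase
    envelope = radius * np.sin(math.pi * t)
    pts = (start + np.outer(t, axis)
           + envelope[:, None] * (np.cos(theta)[:, None] * e1
                                  + np.sin(theta)[:, None] * e2))
    pts = pts + rng.normal(scale=0.02, size=pts.shape)
    pts = np.vstack([start, pts, end])
    for _ in range(20):  # relax interior bond lengths toward `bond`
        for i in range(1, n + 1):
            for j in (i - 1, i + 1):
                v = pts[i] - pts[j]
                d = np.linalg.norm(v)
                if d > 1e-9:
                    pts[i] = pts[j] + v * (0.5 + 0.5 * bond / d)
    return pts[1:-1]


def _protein_residue(chain: str, resseq: int, resname: str, ca: np.ndarray,
                     out_dir: np.ndarray, serial: list[int]) -> Residue:
    atoms = [Atom(_next(serial), "CA", "C", ca)]
    for name, elem, off in _PROT_SIDE[resname]:
        pos = ca + out_dir * off
        atoms.append(Atom(_next(serial), name, elem, pos))
        if name in _PROT_DONOR_H:
            atoms.append(Atom(_next(serial), "H" + name[1:], "H", pos + out_dir * 0.10,
                              is_hydrogen=True))
    return Residue(chain, resseq, resname, ResidueKind.PROTEIN, atoms)


def _dna_residue(chain: str, resseq: int, resname: str, p: np.ndarray,
                 out_dir: np.ndarray, serial: list[int]) -> Residue:
    # fan the base atoms over distinct directions so no donor hydrogen can
    # land on a sibling heavy atom and get mis-attached
    ref = np.array([0.0, 0.0, 1.0])
    if abs(out_dir @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    perp = np.cross(out_dir, ref)
    perp /= np.linalg.norm(perp)
    atoms = [Atom(_next(serial), "P", "P", p)]
    for k, (name, elem, off) in enumerate(_DNA_SIDE[resname]):
        ang = 0.55 * k
        d = math.cos(ang) * out_dir + math.sin(ang) * perp
        pos = p + d * off
        atoms.append(Atom(_next(serial), name, elem, pos))
        if name in _DNA_DONOR_H:
            atoms.append(Atom(_next(serial), "H" + name[1:], "H", pos + d * 0.10,
                              is_hydrogen=True))
    return Residue(chain, resseq, resname, ResidueKind.DNA, atoms)


def _next(counter: list[int]) -> int:
    counter[0] += 1
    return counter[0]


def _out_dirs(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    d = points - center
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    fallback = np.tile([1.0, 0.0, 0.0], (len(points), 1))
    return np.where(norms > 1e-9, d / np.maximum(norms, 1e-9), fallback)


def _chain_out_dirs(points: np.ndarray) -> np.ndarray:
    """Directions roughly perpendicular to the local chain tangent."""
    tang = np.gradient(points, axis=0)
    z = np.array([0.0, 0.0, 1.0])
    out = np.cross(tang, z)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    out = np.where(norms > 1e-9, out / np.maximum(norms, 1e-9),
                   np.tile([1.0, 0.0, 0.0], (len(points), 1)))
    return out


# ---------------------------------------------------------------------------
# receptor
# ---------------------------------------------------------------------------

def make_toy_receptor(p: GenParams) -> tuple[Structure, DomainMap]:
    """Homodimeric two-domain receptor with flexible interdomain linkers.

    Chain A is monomer 1 (RBD1 residues 1..n_rbd, then the linker, then
    HBD1); chain B mirrors it. The two RBD globules pack as the dimer core
    and each HBD is tethered above it, so the default HBD1-HBD2 COM distance
    sits inside the 3-9 nm window the ensemble grid spans.
    """
    rng = np.random.default_rng(p.seed)
    serial = [0]
    rbd_local = [_fcc_globule(p.n_res_rbd, p.bead_spacing, rng) for _ in range(2)]
    hbd_local = [_fcc_globule(p.n_res_hbd, p.bead_spacing, rng) for _ in range(2)]
    r_rbd = max(float(np.linalg.norm(loc, axis=1).max()) for loc in rbd_local)
    half = r_rbd + 0.15
    rbd_centers = [np.array([-half, 0.0, 0.0]), np.array([half, 0.0, 0.0])]
    hbd_centers = [np.array([-p.hbd_separation / 2, p.hbd_height, 0.0]),
                   np.array([p.hbd_separation / 2, p.hbd_height, 0.0])]

    residues: list[Residue] = []
    groups: dict[str, set[tuple[str, int]]] = {}
    roles: dict[str, DomainRole] = {}

    for mono, chain in enumerate("AB"):
        rbd_pts = rbd_local[mono] + rbd_centers[mono]
        hbd_pts = hbd_local[mono] + hbd_centers[mono]
        # linker anchors: the globule beads nearest the other domain's centre
        a_idx = int(np.argmin(np.linalg.norm(rbd_pts - hbd_centers[mono], axis=1)))
        b_idx = int(np.argmin(np.linalg.norm(hbd_pts - rbd_centers[mono], axis=1)))
        link_pts = _bridge_chain(rbd_pts[a_idx], hbd_pts[b_idx],
                                 p.linker_len_receptor, 0.35, rng)

        resseq = 0
        seqs: list[tuple[str, np.ndarray, np.ndarray, str]] = []
        for i, pt in enumerate(rbd_pts):
            seqs.append((_GLOBULE_PALETTE[i % len(_GLOBULE_PALETTE)], pt,
                         None, "RBD"))
        link_names = (_LINKER_SEQ if p.linker_len_receptor == len(_LINKER_SEQ)
                      else [_GLOBULE_PALETTE[i % len(_GLOBULE_PALETTE)]
                            for i in range(p.linker_len_receptor)])
        link_dirs = _chain_out_dirs(link_pts)
        for i, pt in enumerate(link_pts):
            seqs.append((link_names[i], pt, link_dirs[i], "LINKER"))
        for i, pt in enumerate(hbd_pts):
            seqs.append((_GLOBULE_PALETTE[(i + 3) % len(_GLOBULE_PALETTE)], pt,
                         None, "HBD"))

        rbd_dirs = _out_dirs(rbd_pts, rbd_centers[mono])
        hbd_dirs = _out_dirs(hbd_pts, hbd_centers[mono])
        group_keys = {"RBD": set(), "LINKER": set(), "HBD": set()}
        i_rbd = i_hbd = 0
        for resname, pt, out, tag in seqs:
            resseq += 1
            if out is None:
                if tag == "RBD":
                    out = rbd_dirs[i_rbd]
                    i_rbd += 1
                else:
                    out = hbd_dirs[i_hbd]
                    i_hbd += 1
            residues.append(_protein_residue(chain, resseq, resname, pt, out, serial))
            group_keys[tag].add((chain, resseq))
        idx = mono + 1
        groups[f"RBD{idx}"] = group_keys["RBD"]
        roles[f"RBD{idx}"] = DomainRole.RBD
        groups[f"LINKER{idx}"] = group_keys["LINKER"]
        roles[f"LINKER{idx}"] = DomainRole.LINKER
        groups[f"HBD{idx}"] = group_keys["HBD"]
        roles[f"HBD{idx}"] = DomainRole.HBD

    s = annotate(Structure(residues, title="synthetic two-domain homodimer receptor",
                           provenance=Provenance.SYNTHETIC))
    return s, DomainMap(groups, roles)


# ---------------------------------------------------------------------------
# aptamers
# ---------------------------------------------------------------------------

def _quad_unit(chain: str, first_resseq: int, center: np.ndarray,
               serial: list[int], p: GenParams,
               rng: np.random.Generator) -> tuple[list[Residue], list[int]]:
    """Quadruplex-core unit: stacked 4-residue rings plus a short tail.

    Returns the residues and the resseq list of the core (for the RMSD group).
    """
    n_rings = max(1, p.apt_core_len // 4)
    per_ring = 4
    ring_radius = 0.55
    stack = 0.34
    residues: list[Residue] = []
    core_resseqs: list[int] = []
    resseq = first_resseq - 1
    pts = []
    for ring in range(n_rings):
        z = (ring - (n_rings - 1) / 2) * stack
        for j in range(per_ring):
            theta = 2 * math.pi * (j / per_ring) + 0.3 * ring
            pts.append(center + np.array([ring_radius * math.cos(theta),
                                          ring_radius * math.sin(theta), z]))
    extra = p.apt_core_len - n_rings * per_ring
    for j in range(extra):  # remainder residues continue the top ring
        theta = 2 * math.pi * (j + 0.5) / per_ring
        z = (n_rings / 2) * stack
        pts.append(center + np.array([ring_radius * math.cos(theta),
                                      ring_radius * math.sin(theta), z]))
    for pt in pts:
        resseq += 1
        core_resseqs.append(resseq)
        out = _out_dirs(pt[None, :], center)[0]
        residues.append(_dna_residue(chain, resseq, "DG", pt, out, serial))
    # tail: short chain leaving the core radially
    exit_dir = np.array([0.0, -1.0, 0.3])
    exit_dir /= np.linalg.norm(exit_dir)
    start = pts[-1]
    end = start + exit_dir * (p.apt_tail_len * p.dna_bond * 0.7)
    tail_pts = _bridge_chain(start, end, p.apt_tail_len, p.dna_bond, rng)
    tail_dirs = _chain_out_dirs(tail_pts)
    for i, pt in enumerate(tail_pts):
        resseq += 1
        residues.append(_dna_residue(chain, resseq, "DT", pt, tail_dirs[i], serial))
    return residues, core_resseqs


def _plain_unit(chain: str, first_resseq: int, center: np.ndarray,
                serial: list[int], p: GenParams,
                rng: np.random.Generator) -> list[Residue]:
    pts = _fcc_globule(p.apt_plain_len, p.dna_bond * 0.9, rng) + center
    dirs = _out_dirs(pts, center)
    residues = []
    for i, pt in enumerate(pts):
        resname = _DNA_PALETTE[i % len(_DNA_PALETTE)]
        residues.append(_dna_residue(chain, first_resseq + i, resname, pt,
                                     dirs[i], serial))
    return residues


def make_toy_aptamer(kind: str, p: GenParams) -> tuple[Structure, DomainMap]:
    """Synthetic aptamer: 'monomer_quad', 'monomer_plain' or 'heterodimer'.

    The heterodimer is one quadruplex-bearing RBD-binding unit and one plain
    HBD-binding unit joined by a 10-residue thymine linker, with role tags
    APT_RBD_BINDER / APT_HBD_BINDER driving the attachment criteria.
    """
    if kind not in ("monomer_quad", "monomer_plain", "heterodimer"):
        raise ValueError(f"unknown aptamer kind {kind!r}")
    rng = np.random.default_rng(p.seed + 104729)
    serial = [0]
    chain = "C"
    groups: dict[str, set[tuple[str, int]]] = {}
    roles: dict[str, DomainRole] = {}
    residues: list[Residue] = []

    if kind == "monomer_quad":
        residues, core = _quad_unit(chain, 1, np.zeros(3), serial, p, rng)
        groups["QUAD_CORE"] = {(chain, r) for r in core}
        roles["QUAD_CORE"] = DomainRole.APT_RBD_BINDER
        tail = {(chain, r.resseq) for r in residues} - groups["QUAD_CORE"]
        groups["APT_TAIL"] = tail
        roles["APT_TAIL"] = DomainRole.APT_RBD_BINDER
    elif kind == "monomer_plain":
        residues = _plain_unit(chain, 1, np.zeros(3), serial, p, rng)
        groups["APT_A"] = {(chain, r.resseq) for r in residues}
        roles["APT_A"] = DomainRole.APT_HBD_BINDER
    else:
        unit_a, core = _quad_unit(chain, 1, np.zeros(3), serial, p, rng)
        n_a = len(unit_a)
        b_center = np.array([p.apt_unit_separation, 0.0, 0.0])
        unit_b = _plain_unit(chain, n_a + p.apt_linker_len + 1, b_center, serial, p, rng)
        start = unit_a[-1].atom("P").coords
        end_idx = int(np.argmin([np.linalg.norm(r.atom("P").coords - start)
                                 for r in unit_b]))
        end = unit_b[end_idx].atom("P").coords
        link_pts = _bridge_chain(start, end, p.apt_linker_len, p.dna_bond, rng)
        link_dirs = _chain_out_dirs(link_pts)
        linker = [_dna_residue(chain, n_a + 1 + i, "DT", pt, link_dirs[i], serial)
                  for i, pt in enumerate(link_pts)]
        residues = unit_a + linker + unit_b
        groups["QUAD_CORE"] = {(chain, r) for r in core}
        roles["QUAD_CORE"] = DomainRole.APT_RBD_BINDER
        groups["APT_TAIL"] = {(chain, r.resseq) for r in unit_a} - groups["QUAD_CORE"]
        roles["APT_TAIL"] = DomainRole.APT_RBD_BINDER
        groups["APT_LINKER"] = {(chain, r.resseq) for r in linker}
        roles["APT_LINKER"] = DomainRole.LINKER
        groups["APT_B"] = {(chain, r.resseq) for r in unit_b}
        roles["APT_B"] = DomainRole.APT_HBD_BINDER

    s = annotate(Structure(residues, title=f"synthetic aptamer ({kind})",
                           provenance=Provenance.SYNTHETIC))
    return s, DomainMap(groups, roles)


# ---------------------------------------------------------------------------
# pose fixtures
# ---------------------------------------------------------------------------

def _translate_group(s: Structure, keys: set[tuple[str, int]], delta: np.ndarray) -> None:
    for r in s.residues:
        if r.key in keys:
            for a in r.atoms:
                a.coords = a.coords + delta


def _rotate_group(s: Structure, keys: set[tuple[str, int]], rot,
                  pivot: np.ndarray) -> None:
    """Rigidly rotate the listed residues about ``pivot`` (scipy Rotation)."""
    for r in s.residues:
        if r.key in keys:
            for a in r.atoms:
                a.coords = rot.apply(a.coords - pivot) + pivot


def _group_heavy(s: Structure, keys: set[tuple[str, int]],
                 sidechain_only: bool = False) -> tuple[np.ndarray, list]:
    atoms = [a for r in s.residues if r.key in keys for a in r.atoms
             if not a.is_hydrogen and (a.is_sidechain or not sidechain_only)]
    return np.array([a.coords for a in atoms]), atoms


def _redraw_linker(s: Structure, keys: set[tuple[str, int]], start: np.ndarray,
                   end: np.ndarray, bond: float, rng: np.random.Generator,
                   detour: np.ndarray | None = None,
                   detour_amp: float = 0.0) -> None:
    """Re-draw a linker chain between new anchors.

    ``detour`` bends the path sideways with a sine envelope of amplitude
    ``detour_amp`` (nm) so the chain can be routed around a body instead of
    through it.
    """
    link = sorted([r for r in s.residues if r.key in keys], key=lambda r: r.resseq)
    pts = _bridge_chain(start, end, len(link), bond, rng)
    if detour is not None and detour_amp > 0.0:
        t = np.arange(1, len(link) + 1) / (len(link) + 1.0)
        pts = pts + np.outer(np.sin(math.pi * t) * detour_amp, detour)
    # translate each linker residue rigidly onto its new backbone point
    for res, pt in zip(link, pts):
        delta = pt - res.atom("P").coords
        for a in res.atoms:
            a.coords = a.coords + delta


def make_pose_fixture(label: str, p: GenParams) -> ComplexModel:
    """Receptor/heterodimer complex constructed to classify as ``label``.

    Labels: 'sandwich' (one aptamer unit touching both HBDs), 'side'
    (HBD-binder on one HBD, RBD-binder outside) or 'hug' (RBD-binder wedged
    into the RBD dimer interface, HBD-binder on one HBD). The construction is
    verified against the classifier before returning (closed loop).
    """
    if label not in ("sandwich", "side", "hug"):
        raise ValueError(f"unknown pose label {label!r}")
    rng = np.random.default_rng(p.seed + 7919)
    receptor, rmap = make_toy_receptor(p)
    ligand, lmap = make_toy_aptamer("heterodimer", p)
    unit_a = lmap.union(["QUAD_CORE", "APT_TAIL"])
    unit_b = lmap.group("APT_B")
    all_lig = {r.key for r in ligand.residues}

    hbd1_pts, hbd1_atoms = _group_heavy(receptor, rmap.group("HBD1"), sidechain_only=True)
    h1 = hbd1_pts[np.argmax(hbd1_pts[:, 1])]  # outermost HBD1 side-chain atom (+y)

    b_pts, _ = _group_heavy(ligand, unit_b)
    b_low = b_pts[np.argmin(b_pts[:, 1])]
    # park the whole aptamer so unit B touches HBD1 from above
    _translate_group(ligand, all_lig, h1 + np.array([0.0, 0.25, 0.0]) - b_low)

    if label == "sandwich":
        # bring HBD2 down onto the other face of unit B
        b_pts, _ = _group_heavy(ligand, unit_b)
        b_high = b_pts[np.argmax(b_pts[:, 1])]
        hbd2_pts, _ = _group_heavy(receptor, rmap.group("HBD2"), sidechain_only=True)
        h2 = hbd2_pts[np.argmin(hbd2_pts[:, 1])]
        _translate_group(receptor, rmap.group("HBD2"),
                         b_high + np.array([0.0, 0.25, 0.0]) - h2)
        # keep HBD2's linker anchored plausibly: linker is metadata here
    elif label == "hug":
        # wedge unit A onto the closest side-chain pair across the RBD interface
        r1_pts, _ = _group_heavy(receptor, rmap.group("RBD1"), sidechain_only=True)
        r2_pts, _ = _group_heavy(receptor, rmap.group("RBD2"), sidechain_only=True)
        # closest cross-interface pair, preferring the upper (+y) half
        d = np.linalg.norm(r1_pts[:, None, :] - r2_pts[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        mid = 0.5 * (r1_pts[i] + r2_pts[j])
        a_pts, _ = _group_heavy(ligand, unit_a)
        a_low = a_pts[np.argmin(a_pts[:, 1])]
        _translate_group(ligand, unit_a, mid + np.array([0.0, 0.05, 0.0]) - a_low)
        last_a = max(unit_a, key=lambda k: k[1])
        first_b = min(unit_b, key=lambda k: k[1])
        _redraw_linker(ligand, lmap.group("APT_LINKER"),
                       ligand.residue(*last_a).atom("P").coords,
                       ligand.residue(*first_b).atom("P").coords,
                       p.dna_bond, rng)

    cm = ComplexModel(receptor, rmap, ligand, lmap)
    from .analysis import classify_pose  # closed-loop self-verification
    got = classify_pose(cm).value
    if got != label:
        raise RuntimeError(f"pose fixture self-check failed: wanted {label}, got {got}")
    return cm


# ---------------------------------------------------------------------------
# H-bond fixtures
# ---------------------------------------------------------------------------

def make_hbond_fixture(n: int, p: GenParams) -> ComplexModel:
    """Complex with exactly n interface H-bonds plus single-criterion decoys.

    Each planted bond is a serine OG donor (with explicit hydrogen) facing a
    thymine O4 acceptor at 3.0 A and 0 deg. Decoys violate exactly one
    criterion each: distance decoys at 3.6 A / 10 deg, angle decoys at
    3.0 A / 45 deg. max(n, 1) decoys of each kind are planted, so the decoy
    count is always >= n.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    serial = [0]
    don_res: list[Residue] = []
    acc_res: list[Residue] = []

    def plant(idx: int, row: float, d_da: float, angle_deg: float) -> None:
        base = np.array([1.2 * idx, row, 0.0])
        og = base
        h = og + np.array([0.10, 0.0, 0.0])
        th = math.radians(angle_deg)
        acc = og + d_da * np.array([math.cos(th), math.sin(th), 0.0])
        rs = len(don_res) + 1
        don_res.append(Residue("A", rs, "SER", ResidueKind.PROTEIN, [
            Atom(_next(serial), "CA", "C", og + np.array([0.0, 0.0, -0.30])),
            Atom(_next(serial), "OG", "O", og),
            Atom(_next(serial), "HG", "H", h, is_hydrogen=True),
        ]))
        acc_res.append(Residue("C", rs, "DT", ResidueKind.DNA, [
            Atom(_next(serial), "P", "P", acc + np.array([0.0, 0.0, 0.35])),
            Atom(_next(serial), "O4", "O", acc),
        ]))

    for i in range(n):
        plant(i, 0.0, 0.30, 0.0)        # genuine: 3.0 A, 0 deg
    for i in range(max(n, 1)):
        plant(i, 2.0, 0.36, 10.0)       # distance decoy: 3.6 A
    for i in range(max(n, 1)):
        plant(i, 4.0, 0.30, 45.0)       # angle decoy: 45 deg

    receptor = annotate(Structure(don_res, title="H-bond fixture donors",
                                  provenance=Provenance.SYNTHETIC))
    ligand = annotate(Structure(acc_res, title="H-bond fixture acceptors",
                                provenance=Provenance.SYNTHETIC))
    rmap = DomainMap({"DON": {r.key for r in receptor.residues}},
                     {"DON": DomainRole.RBD})
    lmap = DomainMap({"ACC": {r.key for r in ligand.residues}},
                     {"ACC": DomainRole.APT_HBD_BINDER})
    return ComplexModel(receptor, rmap, ligand, lmap)
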