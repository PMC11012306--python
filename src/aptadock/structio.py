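"""Structure model, PDB v3.3 I/O, and domain-map binding.

Internal length unit is the nanometre; PDB files are read and written in
Angstrom. Residue numbering is taken verbatim from the PDB ``resSeq`` field
(1-based), so key-residue lists address records directly.

The model is deliberately residue/atom-level and annotation-rich: every atom
carries a hydrogen-bond role (donor / acceptor / both / none), a side-chain
flag and the serials of its attached hydrogens, because the contact rule,
the H-bond detector and the force-field assignment all key on these.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml

NM_PER_ANGSTROM = 0.1


class HBondRole(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    BOTH = "donor_and_acceptor"
    NONE = "none"


class ResidueKind(str, Enum):
    PROTEIN = "protein"
    DNA = "dna"


class Provenance(str, Enum):
    READ = "read"
    SYNTHETIC = "synthetic"
    DERIVED = "derived"


class DomainRole(str, Enum):
    RBD = "RBD"
    HBD = "HBD"
    APT_RBD_BINDER = "APT_RBD_BINDER"
    APT_HBD_BINDER = "APT_HBD_BINDER"
    LINKER = "LINKER"


class PDBError(ValueError):
    """Raised on malformed or unsupported PDB content."""


#: Residue names recognised as DNA.
DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DN", "DU", "A", "C", "G", "T", "U"}

#: Backbone atom names (everything else is side chain / base).
PROTEIN_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}
DNA_BACKBONE = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "O4'", "C2'", "C1'",
                "HO5'", "H5'", "H5''", "H4'", "H3'", "H2'", "H2''", "H1'", "HO3'"}

# H-bond roles keyed on (resname, atom name) for the residue alphabet the
# synthetic generator emits plus common standard names. Element-based reading
# of foreign PDBs falls back to this table too.
_HBOND_TABLE: dict[tuple[str, str], HBondRole] = {}
for _res in ("ALA", "LEU", "SER", "ASN", "ASP", "GLU", "ARG", "LYS", "TYR", "ILE", "GLN",
             "GLY", "VAL", "THR", "PRO"):
    _HBOND_TABLE[(_res, "N")] = HBondRole.DONOR
    _HBOND_TABLE[(_res, "O")] = HBondRole.ACCEPTOR
_HBOND_TABLE.update({
    ("SER", "OG"): HBondRole.BOTH,
    ("THR", "OG1"): HBondRole.BOTH,
    ("TYR", "OH"): HBondRole.BOTH,
    ("ASN", "OD1"): HBondRole.ACCEPTOR,
    ("ASN", "ND2"): HBondRole.DONOR,
    ("GLN", "OE1"): HBondRole.ACCEPTOR,
    ("GLN", "NE2"): HBondRole.DONOR,
    ("ASP", "OD1"): HBondRole.ACCEPTOR,
    ("ASP", "OD2"): HBondRole.ACCEPTOR,
    ("GLU", "OE1"): HBondRole.ACCEPTOR,
    ("GLU", "OE2"): HBondRole.ACCEPTOR,
    ("ARG", "NE"): HBondRole.DONOR,
    ("ARG", "NH1"): HBondRole.DONOR,
    ("ARG", "NH2"): HBondRole.DONOR,
    ("LYS", "NZ"): HBondRole.DONOR,
})
for _res in ("DA", "DC", "DG", "DT"):
    for _nm in ("OP1", "OP2", "O5'", "O3'", "O4'"):
        _HBOND_TABLE[(_res, _nm)] = HBondRole.ACCEPTOR
_HBOND_TABLE.update({
    ("DG", "O6"): HBondRole.ACCEPTOR,
    ("DG", "N7"): HBondRole.ACCEPTOR,
    ("DG", "N2"): HBondRole.DONOR,
    ("DG", "N1"): HBondRole.DONOR,
    ("DT", "O4"): HBondRole.ACCEPTOR,
    ("DT", "O2"): HBondRole.ACCEPTOR,
    ("DT", "N3"): HBondRole.DONOR,
    ("DA", "N6"): HBondRole.DONOR,
    ("DA", "N7"): HBondRole.ACCEPTOR,
    ("DA", "N1"): HBondRole.ACCEPTOR,
    ("DC", "N4"): HBondRole.DONOR,
    ("DC", "O2"): HBondRole.ACCEPTOR,
})


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,), nm
    is_hydrogen: bool = False
    is_sidechain: bool = False
    hbond_role: HBondRole = HBondRole.NONE
    attached_hydrogens: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.serial}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")


@dataclass
class Residue:
    chain_id: str
    resseq: int
    resname: str
    kind: ResidueKind
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.resseq)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"no atom {name!r} in {self.chain_id}{self.resseq}")


@dataclass
class Structure:
    residues: list[Residue]
    title: str = ""
    provenance: Provenance = Provenance.SYNTHETIC

    def __post_init__(self) -> None:
        seen_res: set[tuple[str, int]] = set()
        seen_serial: set[int] = set()
        for r in self.residues:
            if r.key in seen_res:
                raise ValueError(f"duplicate residue {r.key}")
            seen_res.add(r.key)
            if not r.atoms:
                raise ValueError(f"residue {r.key} has no atoms")
            for a in r.atoms:
                if a.serial in seen_serial:
                    raise ValueError(f"duplicate atom serial {a.serial}")
                seen_serial.add(a.serial)

    # -- iteration helpers ---------------------------------------------------
    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        """All atom coordinates in input order, (n_atoms, 3), nm."""
        return np.array([a.coords for _, a in self.iter_atoms()], dtype=float)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for _, a in self.iter_atoms() if not a.is_hydrogen],
                        dtype=float)

    def residue(self, chain_id: str, resseq: int) -> Residue:
        for r in self.residues:
            if r.chain_id == chain_id and r.resseq == resseq:
                return r
        raise KeyError(f"no residue {chain_id}/{resseq}")

    def residue_index(self) -> dict[tuple[str, int], Residue]:
        return {r.key: r for r in self.residues}

    def copy(self) -> "Structure":
        residues = [Residue(r.chain_id, r.resseq, r.resname, r.kind,
                            [replace(a, coords=a.coords.copy(),
                                     attached_hydrogens=list(a.attached_hydrogens))
                             for a in r.atoms])
                    for r in self.residues]
        return Structure(residues, title=self.title, provenance=self.provenance)

    def with_coords(self, coords: np.ndarray,
                    provenance: Provenance = Provenance.DERIVED) -> "Structure":
        """New structure with the same topology/annotations but new coordinates.

        ``coords`` must be in :meth:`coords` (all-atom input) order.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected {(self.n_atoms, 3)} coords, got {coords.shape}")
        out = self.copy()
        i = 0
        for r in out.residues:
            for a in r.atoms:
                a.coords = coords[i].copy()
                i += 1
        out.provenance = provenance
        return out

    def atom_by_serial(self) -> dict[int, tuple[Residue, Atom]]:
        return {a.serial: (r, a) for r, a in self.iter_atoms()}


@dataclass
class DomainMap:
    """Named residue groups with role tags, shared by every filter/classifier."""

    groups: dict[str, set[tuple[str, int]]]
    roles: dict[str, DomainRole]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for name, keys in self.groups.items():
            if name not in self.roles:
                raise ValueError(f"group {name!r} has no role tag")
            overlap = seen & keys
            if overlap:
                raise ValueError(f"group {name!r} overlaps earlier groups on {sorted(overlap)[:3]}")
            seen |= keys

    def group(self, name: str) -> set[tuple[str, int]]:
        return self.groups[name]

    def union(self, names: Iterable[str]) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for n in names:
            out |= self.groups[n]
        return out

    def by_role(self, role: DomainRole) -> list[str]:
        return [n for n, r in self.roles.items() if r == role]

    def all_keys(self) -> set[tuple[str, int]]:
        return self.union(self.groups)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate(structure: Structure) -> Structure:
    """Assign side-chain flags, H-bond roles and attached hydrogens in place.

    Roles come from the built-in (resname, atom name) table; hydrogens are
    attached to the nearest heavy atom of the same residue within 0.15 nm.
    """
    for res in structure.residues:
        backbone = PROTEIN_BACKBONE if res.kind is ResidueKind.PROTEIN else DNA_BACKBONE
        heavy = res.heavy_atoms()
        for a in res.atoms:
            a.is_hydrogen = a.element == "H"
            a.is_sidechain = a.name not in backbone
            if not a.is_hydrogen:
                a.hbond_role = _HBOND_TABLE.get((res.resname, a.name), HBondRole.NONE)
                a.attached_hydrogens = []
        for a in res.atoms:
            if not a.is_hydrogen or not heavy:
                continue
            d = [float(np.linalg.norm(a.coords - h.coords)) for h in heavy]
            j = int(np.argmin(d))
            if d[j] <= 0.15:
                heavy[j].attached_hydrogens.append(a.serial)
                a.is_sidechain = heavy[j].is_sidechain
    return structure


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _infer_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        raise PDBError("empty atom name")
    # two-character elements in our alphabet would be right-justified in the
    # name field; single letters cover C/N/O/P/S/H here
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise PDBError(f"cannot infer element from atom name {name!r}")


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB v3.3 coordinate file into a :class:`Structure`.

    ATOM/HETATM records with altloc '' or 'A' are kept; coordinates are
    converted from Angstrom to nm; insertion codes are rejected.
    """
    path = Path(path)
    residues: list[Residue] = []
    index: dict[tuple[str, int], Residue] = {}
    title = ""
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "TITLE ":
                title = (title + " " + line[10:80].strip()).strip()
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBError(f"{path.name}:{lineno}: truncated coordinate record")
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip() or line[17:21].strip()
                chain_id = line[21].strip() or "A"
                resseq = int(line[22:26])
                icode = line[26]
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBError(f"{path.name}:{lineno}: malformed record: {exc}") from exc
            if altloc not in (" ", "", "A"):
                continue
            if icode not in (" ", ""):
                raise PDBError(f"{path.name}:{lineno}: insertion codes are not supported")
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name)
            element = element.capitalize()
            kind = ResidueKind.DNA if resname in DNA_RESNAMES else ResidueKind.PROTEIN
            key = (chain_id, resseq)
            if key not in index:
                res = Residue(chain_id, resseq, resname, kind, [])
                index[key] = res
                residues.append(res)
            coords = np.array([x, y, z]) * NM_PER_ANGSTROM
            index[key].atoms.append(Atom(serial, name, element, coords,
                                         is_hydrogen=element == "H"))
    if not residues:
        raise PDBError(f"{path.name}: no coordinate records found")
    s = Structure(residues, title=title, provenance=Provenance.READ)
    return annotate(s)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-width PDB v3.3; residues in input order, TER between chains."""
    path = Path(path)
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:70]}")
    prev_chain: str | None = None
    last = None
    for res in structure.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append(_ter_line(last))
        prev_chain = res.chain_id
        for a in res.atoms:
            if a.serial > 99999:
                raise PDBError(f"atom serial {a.serial} exceeds PDB limit 99999")
            if res.resseq > 9999:
                raise PDBError(f"residue number {res.resseq} exceeds PDB limit 9999")
            x, y, z = a.coords / NM_PER_ANGSTROM
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.serial:5d} {name:<4.4s} {res.resname:<3.3s} {res.chain_id:1.1s}"
                f"{res.resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2.2s}"
            )
            last = (a, res)
    lines.append(_ter_line(last))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _ter_line(last: tuple[Atom, Residue] | None) -> str:
    if last is None:
        return "TER"
    a, res = last
    return f"TER   {a.serial + 1:5d}      {res.resname:<3.3s} {res.chain_id:1.1s}{res.resseq:4d}"


# ---------------------------------------------------------------------------
# domain-map binding
# ---------------------------------------------------------------------------

def bind_domain_map(structure: Structure, cfg: Mapping[str, Mapping]) -> DomainMap:
    """Bind a {name: {chain, first, last, role}} config to a structure.

    Every residue in every declared range must exist; groups must be disjoint.
    """
    index = structure.residue_index()
    groups: dict[str, set[tuple[str, int]]] = {}
    roles: dict[str, DomainRole] = {}
    for name, entry in cfg.items():
        chain = str(entry["chain"])
        first, last = int(entry["first"]), int(entry["last"])
        if last < first:
            raise ValueError(f"group {name!r}: last < first")
        keys = set()
        for resseq in range(first, last + 1):
            if (chain, resseq) not in index:
                raise ValueError(f"group {name!r}: residue {chain}/{resseq} absent from structure")
            keys.add((chain, resseq))
        groups[name] = keys
        roles[name] = DomainRole(entry["role"])
    return DomainMap(groups, roles)


def load_domain_map(structure: Structure, path: str | Path) -> DomainMap:
    """Load a YAML or JSON domain-map config file and bind it."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return bind_domain_map(structure, cfg["groups"] if "groups" in cfg else cfg)


def dump_domain_map(dm: DomainMap, path: str | Path) -> None:
    """Write a domain map back out as YAML ranges (contiguous per group)."""
    cfg = {}
    for name, keys in dm.groups.items():
        chains = {c for c, _ in keys}
        if len(chains) != 1:
            raise ValueError(f"group {name!r} spans chains; cannot serialise as a range")
        nums = sorted(r for _, r in keys)
        if nums != list(range(nums[0], nums[-1] + 1)):
            raise ValueError(f"group {name!r} is not contiguous")
        cfg[name] = {"chain": chains.pop(), "first": nums[0], "last": nums[-1],
                     "role": dm.roles[name].value}
    Path(path).write_text(yaml.safe_dump({"groups": cfg}, sort_keys=False))
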