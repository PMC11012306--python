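"""Single-trajectory MM/GBSA-style end-point rescoring.

Per snapshot the binding free energy is

    dG_bind = dE_MM(inter) + dG_GB + gamma * dSASA

with dE_MM the intermolecular Coulomb + 12-6 Lennard-Jones energy (the
intramolecular terms cancel identically in the single-trajectory scheme and
are excluded), dG_GB the generalized-Born polar solvation change (Still
pairwise form with HCT pairwise-descreening effective Born radii) and the
nonpolar term proportional to the solvent-accessible surface area change
(gamma = 0.0072 kcal mol^-1 A^-2, offset 0). The solute entropy term is
omitted. Results are comparative, not absolute: the parameter set is a small
element-based table with integer formal charges on charged side chains and
phosphates, not a biomolecular force field.

Energies in kcal/mol, lengths internally nm (converted to Angstrom where the
conventional constants demand it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .selection import ComplexModel
from .structio import Residue, ResidueKind, Structure

K_COULOMB = 332.0636    # kcal A mol^-1 e^-2
EPS_IN = 1.0
EPS_OUT = 78.5
SURFACE_TENSION = 0.0072  # kcal mol^-1 A^-2
PROBE_RADIUS = 0.14       # nm
HCT_SCREEN = 0.8          # uniform descreening scale factor

# element-based parameters: (LJ sigma nm, LJ epsilon kcal/mol, GB radius nm)
_ELEMENT_PARAMS = {
    "C": (0.340, 0.090, 0.170),
    "N": (0.325, 0.170, 0.155),
    "O": (0.296, 0.210, 0.150),
    "P": (0.374, 0.200, 0.185),
    "S": (0.356, 0.250, 0.180),
    "H": (0.107, 0.016, 0.120),
}

# formal charges placed on single named atoms: charged side chains and the
# DNA phosphate
_CHARGE_TABLE = {
    ("ARG", "NH1"): +1.0,
    ("LYS", "NZ"): +1.0,
    ("ASP", "OD1"): -1.0,
    ("GLU", "OE1"): -1.0,
}


@dataclass
class ForceFieldLite:
    """Small element-based parameter table with named-atom formal charges."""

    eps_in: float = EPS_IN
    eps_out: float = EPS_OUT
    surface_tension: float = SURFACE_TENSION

    def params(self, s: Structure) -> "AtomParams":
        charges, sigma, eps, radii = [], [], [], []
        for res, a in s.iter_atoms():
            try:
                sg, ep, rad = _ELEMENT_PARAMS[a.element]
            except KeyError:
                raise ValueError(
                    f"unparameterized atom {a.name!r} (element {a.element!r}) "
                    f"in residue {res.chain_id}{res.resseq}") from None
            q = _CHARGE_TABLE.get((res.resname, a.name), 0.0)
            if res.kind is ResidueKind.DNA and a.name == "P":
                q = -1.0
            charges.append(q)
            sigma.append(sg)
            eps.append(ep)
            radii.append(rad)
        return AtomParams(np.array(charges), np.array(sigma), np.array(eps),
                          np.array(radii), s.coords())


@dataclass
class AtomParams:
    charge: np.ndarray   # e
    sigma: np.ndarray    # nm
    epsilon: np.ndarray  # kcal/mol
    radius: np.ndarray   # nm (GB intrinsic = SASA radius)
    coords: np.ndarray   # (n, 3) nm


@dataclass
class EnergyBreakdown:
    e_coul: float
    e_lj: float
    g_gb: float
    g_sa: float

    @property
    def total(self) -> float:
        return self.e_coul + self.e_lj + self.g_gb + self.g_sa


# ---------------------------------------------------------------------------
# molecular mechanics
# ---------------------------------------------------------------------------

def mm_energy(cm: ComplexModel, ff: ForceFieldLite) -> tuple[float, float]:
    """Intermolecular (receptor-ligand) Coulomb and 12-6 LJ sums, kcal/mol."""
    pa = ff.params(cm.receptor)
    pb = ff.params(cm.ligand)
    # r in Angstrom for the Coulomb constant
    diff = pa.coords[:, None, :] - pb.coords[None, :, :]
    r_nm = np.linalg.norm(diff, axis=2)
    r_nm = np.maximum(r_nm, 1e-6)
    e_coul = K_COULOMB * float(np.sum(np.outer(pa.charge, pb.charge) / (r_nm * 10.0)))
    sig = 0.5 * (pa.sigma[:, None] + pb.sigma[None, :])
    eps = np.sqrt(np.outer(pa.epsilon, pb.epsilon))
    sr6 = (sig / r_nm) ** 6
    e_lj = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    return e_coul, e_lj


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def _effective_born_radii(coords: np.ndarray, rho: np.ndarray,
                          screen: float = HCT_SCREEN) -> np.ndarray:
    """HCT pairwise-descreening effective radii (coords nm, radii nm)."""
    n = len(rho)
    inv_r = 1.0 / rho
    if n == 1:
        return rho.copy()
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    sj = screen * rho[None, :]
    ri = rho[:, None]
    lower = np.maximum(np.abs(d - sj), ri)
    upper = d + sj
    # pairs where atom j's scaled sphere is entirely inside atom i contribute 0
    mask = upper > ri
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (1.0 / lower - 1.0 / upper
                + (d / 4.0) * (1.0 / upper**2 - 1.0 / lower**2)
                + (1.0 / (2.0 * d)) * np.log(lower / upper)
                + (sj**2 / (4.0 * d)) * (1.0 / lower**2 - 1.0 / upper**2))
    term = np.where(mask & np.isfinite(term), term, 0.0)
    inv_eff = inv_r - 0.5 * term.sum(axis=1)
    # descreening can overshoot for deeply buried atoms; keep radii positive
    inv_eff = np.clip(inv_eff, 1.0 / (20.0 * rho.max()), None)
    return 1.0 / inv_eff


def gb_energy(s: Structure | AtomParams, ff: ForceFieldLite | None = None,
              eps_in: float | None = None, eps_out: float | None = None) -> float:
    """Still-form pairwise GB polar solvation energy of a molecule, kcal/mol.

    dG = -1/2 (1/eps_in - 1/eps_out) k_e sum_ij q_i q_j / f_GB(r_ij, R_i, R_j)
    with f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i R_j)); the sum includes
    the i = j self terms (f_GB(0) = R_i, the Born formula).
    """
    ff = ff or ForceFieldLite()
    p = ff.params(s) if isinstance(s, Structure) else s
    e_in = ff.eps_in if eps_in is None else eps_in
    e_out = ff.eps_out if eps_out is None else eps_out
    if np.any(p.radius <= 0):
        raise ValueError("non-positive GB radius")
    if not np.any(p.charge):
        return 0.0
    reff = _effective_born_radii(p.coords, p.radius)
    r2 = np.sum((p.coords[:, None, :] - p.coords[None, :, :]) ** 2, axis=2)
    rr = np.outer(reff, reff)
    f_gb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))  # nm
    tau = (1.0 / e_in - 1.0 / e_out)
    qq = np.outer(p.charge, p.charge)
    return float(-0.5 * tau * K_COULOMB * np.sum(qq / (f_gb * 10.0)))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley with a deterministic Fibonacci sphere)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(s: Structure | AtomParams, probe: float = PROBE_RADIUS,
         n_points: int = 256, ff: ForceFieldLite | None = None
         ) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Deterministic Fibonacci quadrature with ``n_points`` per atom; a point is
    exposed iff it lies outside every neighbour's probe-expanded sphere.
    Returns (per-atom areas, total), nm^2. Hydrogens carry their own (small)
    radii and are included.
    """
    ff = ff or ForceFieldLite()
    p = ff.params(s) if isinstance(s, Structure) else s
    coords = p.coords
    radii = p.radius + probe
    n = len(coords)
    unit = _fibonacci_sphere(n_points)
    areas = np.zeros(n)
    tree = cKDTree(coords)
    rmax = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                 if j != i]
        if neigh:
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (radii[neigh][None, :] ** 2), axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * radii[i] ** 2
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------

def snapshot_energy(cm: ComplexModel, ff: ForceFieldLite | None = None,
                    n_sasa_points: int = 128) -> EnergyBreakdown:
    """Single-snapshot dG_bind decomposition (single-trajectory scheme)."""
    ff = ff or ForceFieldLite()
    e_coul, e_lj = mm_energy(cm, ff)
    p_rec = ff.params(cm.receptor)
    p_lig = ff.params(cm.ligand)
    p_cpx = AtomParams(np.concatenate([p_rec.charge, p_lig.charge]),
                       np.concatenate([p_rec.sigma, p_lig.sigma]),
                       np.concatenate([p_rec.epsilon, p_lig.epsilon]),
                       np.concatenate([p_rec.radius, p_lig.radius]),
                       np.vstack([p_rec.coords, p_lig.coords]))
    g_gb = (gb_energy(p_cpx, ff) - gb_energy(p_rec, ff) - gb_energy(p_lig, ff))
    _, a_cpx = sasa(p_cpx, n_points=n_sasa_points, ff=ff)
    _, a_rec = sasa(p_rec, n_points=n_sasa_points, ff=ff)
    _, a_lig = sasa(p_lig, n_points=n_sasa_points, ff=ff)
    g_sa = ff.surface_tension * (a_cpx - a_rec - a_lig) * 100.0  # nm^2 -> A^2
    return EnergyBreakdown(e_coul, e_lj, g_gb, g_sa)


@dataclass
class EnsembleEnergy:
    mean: EnergyBreakdown
    sd: float                 # sd of the per-snapshot totals
    per_snapshot: list[EnergyBreakdown]


def binding_free_energy(snapshots: Sequence[ComplexModel],
                        ff: ForceFieldLite | None = None,
                        n_sasa_points: int = 128) -> EnsembleEnergy:
    """Ensemble mean +- sd of the per-snapshot binding free energy."""
    if not snapshots:
        raise ValueError("need at least one snapshot")
    ff = ff or ForceFieldLite()
    per = [snapshot_energy(cm, ff, n_sasa_points) for cm in snapshots]
    totals = np.array([e.total for e in per])
    mean = EnergyBreakdown(float(np.mean([e.e_coul for e in per])),
                           float(np.mean([e.e_lj for e in per])),
                           float(np.mean([e.g_gb for e in per])),
                           float(np.mean([e.g_sa for e in per])))
    sd = float(np.std(totals, ddof=0)) if len(per) > 1 else 0.0
    return EnsembleEnergy(mean, sd, per)


# ---------------------------------------------------------------------------
# docking re-score potential
# ---------------------------------------------------------------------------

def pair_potential(coords_a: np.ndarray, coords_b: np.ndarray,
                   attract_lo: float = 0.30, attract_hi: float = 0.60,
                   clash: float = 0.25, clash_penalty: float = 10.0) -> float:
    """Soft distance-dependent contact score between two heavy-atom sets.

    +1 per pair in the attractive shell [attract_lo, attract_hi] nm and
    -clash_penalty per pair closer than ``clash`` nm. Higher is better.
    """
    ta, tb = cKDTree(coords_a), cKDTree(coords_b)
    n_hi = ta.count_neighbors(tb, attract_hi)
    n_lo = ta.count_neighbors(tb, attract_lo)
    n_clash = ta.count_neighbors(tb, clash)
    return float((n_hi - n_lo) - clash_penalty * n_clash)
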