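"""Rigid-body docking: exhaustive rotations x FFT translational correlation.

The receptor is immobilized; the ligand is rotated on a deterministic
quasi-uniform SO(3) grid (default nearest-neighbour spacing 15 deg) and, for
each rotation, translated exhaustively on a cubic lattice (default 0.12 nm)
by correlating Katchalski-Katzir-style shape grids with the FFT. Receptor
surface cells carry weight 1 and core cells an imaginary penalty weight
(9i); ligand cells carry weight 1, so the correlation's real part counts
surface contacts and its imaginary part core overlap. The top-ten
translations per rotation by shape score are re-scored with a soft pairwise
contact potential and the best re-scored translation is kept per rotation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
from scipy.spatial.transform import Rotation

from .rescoring import pair_potential
from .structio import Structure

# van der Waals radii for grid rasterisation, nm
_VDW = {"C": 0.170, "N": 0.155, "O": 0.152, "P": 0.180, "S": 0.180, "H": 0.120}
DEFAULT_SPACING = 0.12   # nm, translational lattice
DEFAULT_INTERVAL = 15.0  # deg, rotational sampling
CORE_PENALTY = 9.0
TOP_T_PER_ROTATION = 10
ROTATION_BASE_COUNT = 576  # count at 15 deg; scales as (15/interval)^3


@dataclass
class DockGridSpec:
    spacing: float = DEFAULT_SPACING
    dims: tuple[int, int, int] = (64, 64, 64)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # nm
    core_penalty: float = CORE_PENALTY

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        for d in self.dims:
            if d < 2 or (d & (d - 1)) != 0:
                raise ValueError("grid dims must be powers of two >= 2")
        self.origin = np.asarray(self.origin, dtype=float)


@dataclass
class DockPose:
    rotation: np.ndarray       # unit quaternion (x, y, z, w)
    translation: np.ndarray    # nm, grid-aligned ligand COM shift
    shape_score: float
    rescore: float | None = None
    pose_id: str = ""

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        n = np.linalg.norm(self.rotation)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("pose quaternion must be unit length")
        self.translation = np.asarray(self.translation, dtype=float)


@dataclass
class DockParams:
    interval_deg: float = DEFAULT_INTERVAL
    spacing: float = DEFAULT_SPACING
    top_t: int = TOP_T_PER_ROTATION
    core_penalty: float = CORE_PENALTY
    clearance: float = 0.3  # nm of empty margin around the pair

    @classmethod
    def coarse(cls) -> "DockParams":
        """Test-scale preset: 30 deg rotations, 0.3 nm lattice."""
        return cls(interval_deg=30.0, spacing=0.3)


# ---------------------------------------------------------------------------
# rotation sampling
# ---------------------------------------------------------------------------

def sample_rotations(interval_deg: float = DEFAULT_INTERVAL) -> np.ndarray:
    """Deterministic quasi-uniform unit quaternions with ~interval spacing.

    Uses a super-Fibonacci spiral on S^3 with a count scaling as
    576 * (15/interval)^3, then snaps the member nearest the identity onto
    the exact identity so the input orientation is always sampled.
    Returns an (n, 4) array of (x, y, z, w) quaternions.
    """
    if not (0.0 < interval_deg <= 90.0):
        raise ValueError("interval must be in (0, 90] degrees")
    n = max(1, round(ROTATION_BASE_COUNT * (DEFAULT_INTERVAL / interval_deg) ** 3))
    s = np.arange(n) + 0.5
    t = s / n
    d = 2.0 * math.pi * s
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    phi = 1.4142135623730951        # sqrt(2)
    psi = 1.533751168755204288118041
    alpha, beta = d / phi, d / psi
    quats = np.column_stack([r * np.sin(alpha), r * np.cos(alpha),
                             big_r * np.sin(beta), big_r * np.cos(beta)])
    # snap the closest element to the exact identity (w = 1)
    ident = np.array([0.0, 0.0, 0.0, 1.0])
    dots = np.abs(quats @ ident)
    quats[int(np.argmax(dots))] = ident
    return quats


def geodesic_angle_deg(q1: np.ndarray, q2: np.ndarray) -> float:
    """Rotation angle (deg) between two unit quaternions."""
    dot = abs(float(np.dot(q1, q2)))
    return math.degrees(2.0 * math.acos(min(1.0, dot)))


# ---------------------------------------------------------------------------
# grid projection & FFT scoring
# ---------------------------------------------------------------------------

def _next_pow2(x: int) -> int:
    return 1 << max(1, (x - 1)).bit_length()


def make_grid_spec(receptor: Structure, ligand: Structure,
                   params: DockParams) -> DockGridSpec:
    """Grid dims accommodating the receptor plus the rotated ligand anywhere."""
    rc = receptor.heavy_coords()
    lc = ligand.heavy_coords()
    lig_radius = float(np.linalg.norm(lc - lc.mean(axis=0), axis=1).max())
    lo = rc.min(axis=0) - lig_radius - 2 * params.clearance
    hi = rc.max(axis=0) + lig_radius + 2 * params.clearance
    span = float((hi - lo).max())
    dim = _next_pow2(int(math.ceil(span / params.spacing)) + 1)
    center = 0.5 * (rc.min(axis=0) + rc.max(axis=0))
    origin = center - 0.5 * dim * params.spacing
    return DockGridSpec(params.spacing, (dim, dim, dim), origin,
                        params.core_penalty)


def grid_project(s: Structure, spec: DockGridSpec, role: str) -> np.ndarray:
    """Digitize heavy atoms onto the lattice (Katchalski-Katzir weights).

    role 'receptor': complex grid, surface cells 1, core cells
    i*core_penalty (core = occupancy eroded by one grid layer).
    role 'ligand': real grid, occupied cells 1.
    """
    if role not in ("receptor", "ligand"):
        raise ValueError("role must be 'receptor' or 'ligand'")
    coords = s.heavy_coords()
    radii = _heavy_radii(s)
    return _project_coords(coords, radii, spec, role)


def _heavy_radii(s: Structure) -> np.ndarray:
    return np.array([_VDW.get(a.element, 0.17)
                     for _, a in s.iter_atoms() if not a.is_hydrogen])


def _project_coords(coords: np.ndarray, radii: np.ndarray, spec: DockGridSpec,
                    role: str) -> np.ndarray:
    if coords.size == 0:
        raise ValueError("structure has no heavy atoms to project")
    dims = spec.dims
    occ = np.zeros(dims, dtype=bool)
    rel = (coords - spec.origin) / spec.spacing
    if np.any(rel < 0) or np.any(rel >= np.array(dims)):
        raise ValueError("structure exceeds the docking grid")
    for (cx, cy, cz), rad in zip(rel, radii / spec.spacing):
        lo = np.maximum(np.floor([cx - rad, cy - rad, cz - rad]).astype(int), 0)
        hi = np.minimum(np.ceil([cx + rad, cy + rad, cz + rad]).astype(int) + 1,
                        dims)
        if np.any(lo >= hi):
            continue
        ix, iy, iz = [np.arange(lo[k], hi[k]) for k in range(3)]
        dx2 = (ix - cx)[:, None, None] ** 2
        dy2 = (iy - cy)[None, :, None] ** 2
        dz2 = (iz - cz)[None, None, :] ** 2
        occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= \
            (dx2 + dy2 + dz2) <= rad * rad
    if role == "ligand":
        return occ.astype(float)
    core = scipy.ndimage.binary_erosion(occ)
    surface = occ & ~core
    return surface.astype(complex) + 1j * spec.core_penalty * core.astype(complex)


def fft_translate_score(receptor_grid: np.ndarray,
                        ligand_grid: np.ndarray) -> np.ndarray:
    """Shape-complementarity score for every lattice translation of the ligand.

    With c(t) = sum_x conj(R(x)) L(x + t) the real part counts surface
    contacts and the imaginary part is -core_penalty times the core overlap,
    so score(t) = Re[c(t)] + Im[c(t)] = surface - core_penalty * core.
    Computed with the FFT; equals the direct O(N^2) correlation to roundoff.
    """
    if receptor_grid.shape != ligand_grid.shape:
        raise ValueError("grid dimension mismatch")
    c = np.fft.ifftn(np.fft.fftn(ligand_grid) * np.conj(np.fft.fftn(receptor_grid)))
    return np.real(c) + np.imag(c)


def _wrap_shift(idx: np.ndarray, dims: tuple[int, int, int]) -> np.ndarray:
    """Map non-negative lattice indices to signed shifts (wrap-around alias)."""
    out = np.asarray(idx, dtype=int).copy()
    for k in range(3):
        if out[k] > dims[k] // 2:
            out[k] -= dims[k]
    return out


# ---------------------------------------------------------------------------
# full docking protocol
# ---------------------------------------------------------------------------

def dock(receptor: Structure, ligand: Structure,
         params: DockParams | None = None) -> list[DockPose]:
    """Two-stage rigid docking; returns poses ranked by re-score (best first).

    For each rotation the top-``params.top_t`` translations by shape score
    are re-scored with the pairwise contact potential and only the best
    re-scored translation per rotation is kept, so the output has at most one
    pose per rotation. Deterministic: ties break by (rotation index,
    translation index).
    """
    params = params or DockParams()
    spec = make_grid_spec(receptor, ligand, params)
    rec_grid = grid_project(receptor, spec, "receptor")
    rec_coords = receptor.heavy_coords()
    lig_coords = ligand.heavy_coords()
    lig_radii = _heavy_radii(ligand)
    lig_com = lig_coords.mean(axis=0)
    quats = sample_rotations(params.interval_deg)
    dims = spec.dims
    poses: list[DockPose] = []
    for ri, q in enumerate(quats):
        rot = Rotation.from_quat(q)
        rotated = rot.apply(lig_coords - lig_com) + lig_com
        try:
            lig_grid = _project_coords(rotated, lig_radii, spec, "ligand")
        except ValueError:
            continue  # rotated ligand pokes out of the grid margin
        smap = fft_translate_score(rec_grid, lig_grid)
        flat = smap.ravel()
        top = min(params.top_t, flat.size)
        cand = np.argpartition(-flat, top - 1)[:top]
        cand = cand[np.lexsort((cand, -flat[cand]))]  # score desc, index asc
        best: tuple[float, int, np.ndarray] | None = None
        for ti in cand:
            if flat[ti] <= 0:
                continue  # fully clashing / no surface contact
            shift = _wrap_shift(np.array(np.unravel_index(ti, dims)), dims)
            trans = shift * spec.spacing
            score = pair_potential(rec_coords, rotated + trans)
            if best is None or score > best[0]:
                best = (score, int(ti), trans)
        if best is None:
            continue
        score, ti, trans = best
        poses.append(DockPose(q, trans, float(flat[ti]), rescore=score,
                              pose_id=f"r{ri:04d}t{ti:08d}"))
    if not poses:
        warnings.warn("no rotation produced a non-clashing pose", stacklevel=2)
        return []
    order = sorted(range(len(poses)),
                   key=lambda i: (-poses[i].rescore, poses[i].pose_id))
    return [poses[i] for i in order]


def apply_pose(ligand: Structure, pose: DockPose) -> Structure:
    """Ligand coordinates under a pose (rotation about its COM, then shift)."""
    coords = ligand.coords()
    heavy = ligand.heavy_coords()
    com = heavy.mean(axis=0)
    rot = Rotation.from_quat(pose.rotation)
    return ligand.with_coords(rot.apply(coords - com) + com + pose.translation)
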