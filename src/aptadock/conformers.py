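"""Conformer ensembles along the lowest elastic-network modes.

Large-scale variants are produced by displacing the structure along the
low-frequency mode that best overlaps the inter-domain centre-of-mass (COM)
distance coordinate and relaxing in the low-mode subspace under a harmonic
distance restraint (force constant 1000 kJ mol^-1 nm^-2); each variant is
then decorated with small-scale snapshots: seeded random superpositions of
the lowest non-rigid modes re-restrained to the target distance. This is a
deterministic desk-scale surrogate for restrained molecular dynamics: the
purpose of the restrained simulations is solely to realise target COM
distances along the soft collective modes, which the surrogate achieves
directly.

COM here means the unweighted centroid of a group's heavy atoms. Snapshot 0
of every variant is the driven (unperturbed) structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import scipy.optimize

from . import anm
from .structio import Structure

K_RESTRAINT = 1000.0    # harmonic COM-distance restraint, energy nm^-2
DIST_TOL = 0.05         # nm, targeting tolerance for driven structures
OVERLAP_MIN = 0.3       # minimum mode/distance-coordinate overlap
N_DRIVE_MODES = 20      # low-mode subspace dimension for driving
N_PERTURB_MODES = 10    # lowest non-rigid modes used for snapshots
PERTURB_AMP = 0.1       # nm, RMS node displacement of snapshots
MAX_DRIVE_RMS = 5.0     # nm, RMS node displacement beyond which the linear
                        # mode picture is meaningless and driving fails


class DriveError(RuntimeError):
    """Target COM distance could not be reached; carries the best achieved."""

    def __init__(self, target: float, achieved: float):
        super().__init__(f"could not reach target {target:.3f} nm; "
                         f"best achieved {achieved:.3f} nm")
        self.target = target
        self.achieved = achieved


@dataclass
class DistanceGrid:
    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.stop < self.start:
            raise ValueError("stop must be >= start")

    def targets(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.targets())


@dataclass
class ConformerMember:
    structure: Structure
    target_distance: float
    achieved_distance: float
    snapshot_index: int


@dataclass
class ConformerEnsemble:
    members: list[ConformerMember]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def structures(self) -> list[Structure]:
        return [m.structure for m in self.members]


# ---------------------------------------------------------------------------
# COM distance
# ---------------------------------------------------------------------------

def _group_centroid(s: Structure, keys: set[tuple[str, int]]) -> np.ndarray:
    pts = [a.coords for r in s.residues if r.key in keys
           for a in r.atoms if not a.is_hydrogen]
    if not pts:
        raise ValueError("empty selection for centroid")
    return np.mean(pts, axis=0)


def com_distance(s: Structure, group_a: Iterable[tuple[str, int]],
                 group_b: Iterable[tuple[str, int]]) -> float:
    """Distance between the unweighted heavy-atom centroids of two groups, nm."""
    return float(np.linalg.norm(_group_centroid(s, set(group_a))
                                - _group_centroid(s, set(group_b))))


# ---------------------------------------------------------------------------
# mode-space machinery
# ---------------------------------------------------------------------------

def _residue_atom_counts(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (n_atoms, n_heavy) arrays in residue order."""
    n_atoms = np.array([len(r.atoms) for r in s.residues])
    n_heavy = np.array([len(r.heavy_atoms()) for r in s.residues])
    return n_atoms, n_heavy


def _apply_node_displacement(s: Structure, disp_nodes: np.ndarray) -> Structure:
    """Move each residue rigidly by its node displacement ((N,3) nm)."""
    n_atoms, _ = _residue_atom_counts(s)
    per_atom = np.repeat(disp_nodes, n_atoms, axis=0)
    return s.with_coords(s.coords() + per_atom)


def _distance_matrix(s: Structure, model: anm.ENMModel, modes: anm.ModeSet,
                     mode_cols: np.ndarray, keys_a: set, keys_b: set):
    """Linear map from mode amplitudes to the group-separation vector.

    Returns (r0, M) with separation(a) = r0 + M @ a, where centroids are
    heavy-atom weighted means of the (rigid per-residue) node displacements.
    """
    _, n_heavy = _residue_atom_counts(s)
    res_keys = [r.key for r in s.residues]
    w_a = np.zeros(len(res_keys))
    w_b = np.zeros(len(res_keys))
    for i, k in enumerate(res_keys):
        if k in keys_a:
            w_a[i] = n_heavy[i]
        if k in keys_b:
            w_b[i] = n_heavy[i]
    w_a /= w_a.sum()
    w_b /= w_b.sum()
    r0 = _group_centroid(s, keys_a) - _group_centroid(s, keys_b)
    v = modes.eigenvectors[:, mode_cols]           # (3N, m)
    nodes = v.reshape(model.n_nodes, 3, -1)        # (N, 3, m)
    m_map = np.einsum("i,ixm->xm", w_a - w_b, nodes)
    return r0, m_map


def drive_to_distance(s: Structure, model: anm.ENMModel, modes: anm.ModeSet,
                      group_a: Iterable[tuple[str, int]],
                      group_b: Iterable[tuple[str, int]], target: float,
                      k_restraint: float = K_RESTRAINT,
                      dist_tol: float = DIST_TOL,
                      overlap_min: float = OVERLAP_MIN,
                      n_modes: int = N_DRIVE_MODES,
                      max_rms: float = MAX_DRIVE_RMS) -> Structure:
    """Displace along low modes so the inter-group COM distance hits ``target``.

    The displacement minimises the ENM elastic energy (quadratic in mode
    amplitudes) plus a harmonic restraint 0.5*k*(d - target)^2 over the
    ``n_modes`` lowest non-rigid modes. Raises :class:`DriveError` if the
    achieved distance misses the target by more than ``dist_tol`` or if
    reaching it would need an RMS node displacement above ``max_rms``
    (the error reports the best distance achieved within the bound).
    """
    if target <= 0:
        raise ValueError("target distance must be > 0")
    keys_a, keys_b = set(group_a), set(group_b)
    # ensure a driving mode exists (raises otherwise)
    anm.driving_mode(model, modes, keys_a, keys_b, overlap_min=overlap_min)
    nr = modes.nonrigid()[:n_modes]
    lam = modes.eigenvalues[nr]
    r0, m_map = _distance_matrix(s, model, modes, nr, keys_a, keys_b)

    def sep(a: np.ndarray) -> np.ndarray:
        return r0 + m_map @ a

    def objective(a: np.ndarray):
        r = sep(a)
        d = np.linalg.norm(r)
        miss = d - target
        f = 0.5 * float(lam @ (a * a)) + 0.5 * k_restraint * miss * miss
        g = lam * a + k_restraint * miss * (m_map.T @ (r / d))
        return f, g

    # initial guess: amplitude along the single best-coupled column
    d0 = float(np.linalg.norm(r0))
    coup = m_map.T @ (r0 / d0)
    j = int(np.argmax(np.abs(coup)))
    a0 = np.zeros(len(nr))
    a0[j] = (target - d0) / coup[j]
    res = scipy.optimize.minimize(objective, a0, jac=True, method="L-BFGS-B",
                                  options={"maxiter": 500, "ftol": 1e-14,
                                           "gtol": 1e-10})
    a = res.x
    rms = float(np.linalg.norm(a)) / np.sqrt(model.n_nodes)
    if rms > max_rms:
        a = a * (max_rms / rms)
        raise DriveError(target, float(np.linalg.norm(sep(a))))
    achieved = float(np.linalg.norm(sep(a)))
    if abs(achieved - target) > dist_tol:
        raise DriveError(target, achieved)
    disp_nodes = (modes.eigenvectors[:, nr] @ a).reshape(model.n_nodes, 3)
    return _apply_node_displacement(s, disp_nodes)


def _perturb_amplitudes(rng: np.random.Generator, n_modes: int, n_nodes: int,
                        amp: float) -> np.ndarray:
    """Random mode amplitudes giving RMS node displacement ``amp``."""
    a = rng.normal(size=n_modes)
    # eigenvectors are orthonormal over 3N coords: RMS node displacement of
    # V a is |a| / sqrt(N)
    norm = np.linalg.norm(a)
    if norm == 0 or amp == 0:
        return np.zeros(n_modes)
    return a * (amp * np.sqrt(n_nodes) / norm)


def _restrain_distance(s: Structure, model: anm.ENMModel, modes: anm.ModeSet,
                       drive_col: int, keys_a: set, keys_b: set,
                       target: float) -> Structure:
    """Scalar correction along the driving mode to restore the COM distance."""
    r0, m_map = _distance_matrix(s, model, modes, np.array([drive_col]),
                                 keys_a, keys_b)
    for _ in range(4):
        d = float(np.linalg.norm(r0))
        coup = float(m_map[:, 0] @ (r0 / d))
        if abs(coup) < 1e-9:
            break
        c = (target - d) / coup
        r0 = r0 + m_map[:, 0] * c
        disp = (modes.eigenvectors[:, drive_col] * c).reshape(model.n_nodes, 3)
        s = _apply_node_displacement(s, disp)
        if abs(np.linalg.norm(r0) - target) < 1e-6:
            break
    return s


def generate_ensemble(s: Structure, group_a: Iterable[tuple[str, int]],
                      group_b: Iterable[tuple[str, int]], grid: DistanceGrid,
                      n_snapshots: int, seed: int,
                      perturb_amp: float = PERTURB_AMP,
                      cutoff: float = anm.DEFAULT_CUTOFF) -> ConformerEnsemble:
    """Grid of driven variants, each decorated with perturbation snapshots.

    Ensemble size is exactly len(grid) * n_snapshots. Snapshot 0 of each
    variant is the driven structure; snapshots >= 1 superpose the input
    structure's lowest non-rigid modes with RMS amplitude ``perturb_amp``
    and are re-restrained to the target within 2x the driving tolerance.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    keys_a, keys_b = set(group_a), set(group_b)
    model = anm.build_enm(s, cutoff=cutoff)
    modes = anm.compute_modes(model, k=min(3 * model.n_nodes,
                                           N_DRIVE_MODES + 10))
    rng = np.random.default_rng(seed)
    members: list[ConformerMember] = []
    drive_col = anm.driving_mode(model, modes, keys_a, keys_b)
    nr = modes.nonrigid()[:N_PERTURB_MODES]
    for target in grid.targets():
        driven = drive_to_distance(s, model, modes, keys_a, keys_b, float(target))
        members.append(ConformerMember(driven, float(target),
                                       com_distance(driven, keys_a, keys_b), 0))
        for snap in range(1, n_snapshots):
            a = _perturb_amplitudes(rng, len(nr), model.n_nodes, perturb_amp)
            disp = (modes.eigenvectors[:, nr] @ a).reshape(model.n_nodes, 3)
            pert = _apply_node_displacement(driven, disp)
            pert = _restrain_distance(pert, model, modes, drive_col,
                                      keys_a, keys_b, float(target))
            achieved = com_distance(pert, keys_a, keys_b)
            if abs(achieved - target) > 2 * DIST_TOL:
                raise DriveError(float(target), achieved)
            members.append(ConformerMember(pert, float(target), achieved, snap))
    prov = {"seed": seed, "grid": (grid.start, grid.stop, grid.step),
            "n_snapshots": n_snapshots, "perturb_amp": perturb_amp}
    return ConformerEnsemble(members, prov)


def free_ensemble(s: Structure, n_snapshots: int, seed: int,
                  perturb_amp: float = PERTURB_AMP,
                  cutoff: float = anm.DEFAULT_CUTOFF) -> ConformerEnsemble:
    """Unrestrained perturbation snapshots of a monomeric structure.

    Member 0 is the input structure itself; members 1..n-1 superpose the
    lowest non-rigid modes with RMS amplitude ``perturb_amp``.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    model = anm.build_enm(s, cutoff=cutoff)
    modes = anm.compute_modes(model, k=min(3 * model.n_nodes, N_PERTURB_MODES + 8))
    nr = modes.nonrigid()[:N_PERTURB_MODES]
    rng = np.random.default_rng(seed)
    members = [ConformerMember(s, float("nan"), float("nan"), 0)]
    for snap in range(1, n_snapshots):
        a = _perturb_amplitudes(rng, len(nr), model.n_nodes, perturb_amp)
        disp = (modes.eigenvectors[:, nr] @ a).reshape(model.n_nodes, 3)
        members.append(ConformerMember(_apply_node_displacement(s, disp),
                                       float("nan"), float("nan"), snap))
    return ConformerEnsemble(members, {"seed": seed, "n_snapshots": n_snapshots,
                                       "perturb_amp": perturb_amp})
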