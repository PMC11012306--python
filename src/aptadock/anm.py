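"""Anisotropic network model (ANM) normal modes on coarse-grained nodes.

One node per residue: the Calpha atom for protein residues and the backbone
phosphate node for DNA residues. For a node pair within the cutoff the
Hessian off-diagonal 3x3 block is -gamma * (r_ij r_ij^T) / |r_ij|^2 and the
diagonal blocks enforce translation invariance (zero block-row sums). The
lowest non-rigid eigenmodes approximate the collective inter-domain motions
that the conformer generator follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg
from scipy.spatial import cKDTree

from .structio import DomainMap, Residue, ResidueKind, Structure

DEFAULT_CUTOFF = 1.5  # nm; residue-level ANM practice for mixed protein/DNA
DEFAULT_GAMMA = 1.0   # uniform spring constant; cancels in mode shapes
RIGID_TOL_FACTOR = 1e-8
DENSE_LIMIT = 3000    # 3N above which the iterative eigensolver is used


def node_atom(res: Residue):
    """The coarse-grain node atom of a residue (Calpha / P, with fallback)."""
    want = "CA" if res.kind is ResidueKind.PROTEIN else "P"
    for a in res.atoms:
        if a.name == want:
            return a
    heavy = res.heavy_atoms()
    if not heavy:
        raise ValueError(f"residue {res.key} has no heavy atoms")
    return heavy[0]


@dataclass
class ENMModel:
    node_coords: np.ndarray                 # (N, 3), nm
    node_index: dict[tuple[str, int], int]  # (chain, resseq) -> node row
    cutoff: float
    gamma: float
    hessian: np.ndarray                     # (3N, 3N)
    connected: bool = True
    n_components: int = 1

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


@dataclass
class ModeSet:
    eigenvalues: np.ndarray   # ascending, length k
    eigenvectors: np.ndarray  # (3N, k), orthonormal columns
    n_rigid: int
    rigid_tol: float

    def nonrigid(self) -> np.ndarray:
        """Column indices of the non-rigid modes, lowest frequency first."""
        return np.arange(self.n_rigid, len(self.eigenvalues))


def build_enm(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
              gamma: float = DEFAULT_GAMMA) -> ENMModel:
    """Build the ANM Hessian on one node per residue."""
    nodes = [node_atom(r) for r in structure.residues]
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes to build an elastic network")
    coords = np.array([a.coords for a in nodes])
    node_index = {r.key: i for i, r in enumerate(structure.residues)}
    n = len(nodes)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    hessian = np.zeros((3 * n, 3 * n))
    adj_rows, adj_cols = [], []
    for i, j in pairs:
        rij = coords[j] - coords[i]
        d2 = float(rij @ rij)
        if d2 == 0.0:
            continue
        block = -gamma * np.outer(rij, rij) / d2
        hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
        adj_rows.append(i)
        adj_cols.append(j)

    adj = scipy.sparse.coo_matrix((np.ones(len(adj_rows)), (adj_rows, adj_cols)),
                                  shape=(n, n))
    n_comp = scipy.sparse.csgraph.connected_components(adj, directed=False,
                                                       return_labels=False)
    connected = n_comp == 1
    if not connected:
        warnings.warn(f"elastic network has {n_comp} components; "
                      "more than 6 near-zero modes expected", stacklevel=2)
    return ENMModel(coords, node_index, cutoff, gamma, hessian,
                    connected=connected, n_components=int(n_comp))


def compute_modes(model: ENMModel, k: int) -> ModeSet:
    """The k lowest-eigenvalue normal modes, ascending; rigid modes flagged."""
    dim = model.hessian.shape[0]
    if k > dim:
        raise ValueError(f"k={k} exceeds 3N={dim}")
    if dim <= DENSE_LIMIT or k >= dim - 1:
        evals, evecs = scipy.linalg.eigh(model.hessian)
        lam_max = float(evals[-1])
        evals, evecs = evals[:k], evecs[:, :k]
    else:
        h = scipy.sparse.csr_matrix(model.hessian)
        lam_max = float(scipy.sparse.linalg.eigsh(h, k=1, which="LA",
                                                  return_eigenvectors=False)[0])
        # shift-invert about a small negative shift: the matrix is singular at 0
        evals, evecs = scipy.sparse.linalg.eigsh(h, k=k, sigma=-1e-6 * max(lam_max, 1.0),
                                                 which="LM")
        order = np.argsort(evals)
        evals, evecs = evals[order], evecs[:, order]
    rigid_tol = RIGID_TOL_FACTOR * max(lam_max, np.finfo(float).tiny)
    if np.any(evals < -1e3 * rigid_tol):
        raise RuntimeError("eigensolver produced significantly negative eigenvalues")
    n_rigid = int(np.sum(np.abs(evals) < rigid_tol))
    return ModeSet(np.asarray(evals, dtype=float), np.asarray(evecs, dtype=float),
                   n_rigid, rigid_tol)


def _group_nodes(model: ENMModel, group: Iterable[tuple[str, int]]) -> np.ndarray:
    idx = sorted(model.node_index[key] for key in group if key in model.node_index)
    if not idx:
        raise ValueError("group maps to no elastic-network nodes")
    return np.asarray(idx, dtype=int)


def distance_gradient(model: ENMModel, group_a: Iterable[tuple[str, int]],
                      group_b: Iterable[tuple[str, int]]) -> np.ndarray:
    """Gradient of the COM-COM distance of two node groups, (3N,) unit-normalised."""
    ia, ib = _group_nodes(model, group_a), _group_nodes(model, group_b)
    ca, cb = model.node_coords[ia].mean(axis=0), model.node_coords[ib].mean(axis=0)
    sep = ca - cb
    d = float(np.linalg.norm(sep))
    if d == 0.0:
        raise ValueError("coincident group centroids: distance gradient undefined")
    u = sep / d
    g = np.zeros((model.n_nodes, 3))
    g[ia] += u / len(ia)
    g[ib] -= u / len(ib)
    g = g.ravel()
    return g / np.linalg.norm(g)


def mode_distance_overlap(model: ENMModel, modes: ModeSet,
                          group_a: Iterable[tuple[str, int]],
                          group_b: Iterable[tuple[str, int]]) -> np.ndarray:
    """|cos| overlap of each mode with the inter-group COM-distance gradient.

    Values are in [0, 1]; the mode of maximal overlap is the one that most
    directly drives the distance between the two domains (the scissoring
    coordinate for the receptor's two HBD units).
    """
    g = distance_gradient(model, group_a, group_b)
    return np.abs(modes.eigenvectors.T @ g)


def driving_mode(model: ENMModel, modes: ModeSet,
                 group_a: Iterable[tuple[str, int]],
                 group_b: Iterable[tuple[str, int]],
                 overlap_min: float = 0.0) -> int:
    """Index (into the ModeSet columns) of the non-rigid mode of maximal overlap."""
    overlaps = mode_distance_overlap(model, modes, group_a, group_b)
    nr = modes.nonrigid()
    if nr.size == 0:
        raise ValueError("mode set contains no non-rigid modes")
    best = int(nr[np.argmax(overlaps[nr])])
    if overlaps[best] <= overlap_min:
        raise ValueError(
            f"no mode overlaps the distance coordinate above {overlap_min} "
            f"(best {overlaps[best]:.3f})")
    return best
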