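"""Conformational analysis: superposition, gromos clustering, GNM hinges.

Three classical trajectory post-processing steps:

* least-squares (Kabsch) superposition and RMSD, via
  ``scipy.spatial.transform.Rotation.align_vectors``;
* the gromos/Daura greedy neighbour-count clustering of an ensemble with a
  pairwise-RMSD cutoff, plus extraction of the "middle" structure of a
  cluster (the member with the smallest summed RMSD to the rest);
* a Gaussian network model (GNM) on CA nodes whose slowest internal mode
  locates hinge residues at sign changes, the principle behind
  HingeProt-style hinge detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Frame, Trajectory

__all__ = [
    "ClusterResult",
    "GnmResult",
    "kabsch_superpose",
    "pairwise_rmsd",
    "daura_cluster",
    "middle_structure",
    "gnm_modes",
    "detect_hinges",
]


def _selection_indices(frame_or_traj, selection) -> np.ndarray:
    """Atom indices for a selection: None/'CA' → CA atoms, an atom-name
    string → all atoms of that name, or an explicit index array."""
    top = frame_or_traj.topology
    if selection is None:
        selection = "CA"
    if isinstance(selection, str):
        idx = np.flatnonzero(top.atom_names == selection)
        if idx.size == 0:
            raise ValueError(f"selection {selection!r} matches no atoms")
        return idx
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    return idx


def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray):
    """Optimal proper rotation + translation; returns (R, t_mobile_centroid,
    t_ref_centroid, rmsd)."""
    if mobile_xyz.shape != ref_xyz.shape:
        raise ValueError(
            f"selection size mismatch: mobile {mobile_xyz.shape[0]} vs "
            f"reference {ref_xyz.shape[0]} atoms"
        )
    mc = mobile_xyz.mean(axis=0)
    rc = ref_xyz.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_xyz - rc, mobile_xyz - mc)
    rmsd = rssd / np.sqrt(mobile_xyz.shape[0])
    return rot, mc, rc, float(rmsd)


def kabsch_superpose(mobile: Frame, reference: Frame, selection=None) -> tuple[Frame, float]:
    """Superpose ``mobile`` onto ``reference`` (least-squares over the
    selection) and return the rotated frame plus the selection RMSD in Å.

    The fitted transform is a proper rotation (det = +1) plus translation,
    applied to *all* atoms of the mobile frame.
    """
    idx_m = _selection_indices(mobile, selection)
    idx_r = _selection_indices(reference, selection)
    rot, mc, rc, rmsd = _kabsch(mobile.coords[idx_m], reference.coords[idx_r])
    moved = rot.apply(mobile.coords - mc) + rc
    return Frame(mobile.topology, moved, mobile.time), rmsd


def pairwise_rmsd(traj: Trajectory, selection=None) -> np.ndarray:
    """Symmetric matrix of pairwise best-fit RMSDs over the selection."""
    idx = _selection_indices(traj, selection)
    xyz = traj.coords[:, idx, :]
    xyz = xyz - xyz.mean(axis=1, keepdims=True)
    n = traj.n_frames
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, rssd = Rotation.align_vectors(xyz[i], xyz[j])
            out[i, j] = out[j, i] = rssd / np.sqrt(idx.size)
    return out


@dataclass
class ClusterResult:
    """Greedy-clustering output: frame-index clusters (largest first, the
    extraction order breaking ties), one center per cluster, the cutoff."""

    clusters: list[list[int]]
    centers: list[int]
    cutoff: float
    selection: object = None

    def __post_init__(self) -> None:
        for c, members in zip(self.centers, self.clusters):
            if c not in members:
                raise ValueError("cluster center must belong to its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[int, int]:
        """frame index → cluster rank (0 = most populated)."""
        return {f: k for k, members in enumerate(self.clusters) for f in members}


def daura_cluster(traj: Trajectory, cutoff: float = 1.0, selection=None) -> ClusterResult:
    """Gromos (Daura) clustering of a trajectory.

    From the pairwise best-fit RMSD matrix, repeatedly take the frame with
    the most neighbours within ``cutoff`` (ties → lowest frame index) as a
    cluster center, assign it and its unclustered neighbours to a new
    cluster, remove them, and iterate until no frames remain.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rmsd = pairwise_rmsd(traj, selection)
    n = traj.n_frames
    neighbor = rmsd <= cutoff  # includes self (diagonal 0)
    remaining = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    centers: list[int] = []
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & remaining)
        clusters.append(members.tolist())
        centers.append(center)
        remaining[members] = False
    order = sorted(range(len(clusters)), key=lambda k: (-len(clusters[k]), k))
    return ClusterResult(
        clusters=[clusters[k] for k in order],
        centers=[centers[k] for k in order],
        cutoff=cutoff,
        selection=selection,
    )


def middle_structure(traj: Trajectory, result: ClusterResult) -> Frame:
    """Middle structure of the most populated cluster: the member whose
    summed RMSD to every other member is minimal (ties → lowest index)."""
    if not result.clusters:
        raise ValueError("empty cluster result")
    members = sorted(result.clusters[0])
    if len(members) == 1:
        return traj[members[0]]
    sub = Trajectory(
        traj.topology,
        traj.coords[members],
        traj.times[members],
        label=traj.label,
    )
    sums = pairwise_rmsd(sub, result.selection).sum(axis=1)
    return traj[members[int(np.argmin(sums))]]


@dataclass
class GnmResult:
    """Gaussian-network-model eigendecomposition on CA nodes.

    ``kirchhoff`` is the cutoff-graph Laplacian (−1 for node pairs within
    the cutoff, degree on the diagonal); eigenvalues are ascending.  The
    slowest internal mode is the eigenvector after the zero modes (one per
    connected component).
    """

    kirchhoff: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    residue_numbers: np.ndarray
    chain_ids: np.ndarray
    cutoff: float
    n_zero_modes: int

    @property
    def slow_mode(self) -> np.ndarray:
        """Slowest nonzero mode, one component per residue node."""
        if self.n_zero_modes >= self.eigenvectors.shape[1]:
            raise ValueError("no internal modes: GNM graph has no connected pairs")
        return self.eigenvectors[:, self.n_zero_modes]


def gnm_modes(frame: Frame, cutoff: float = 10.0, selection="CA") -> GnmResult:
    """Build and diagonalize the GNM Kirchhoff matrix of a structure.

    One node per residue (its CA atom, or whatever ``selection`` names);
    node pairs closer than ``cutoff`` Å are springs.  A disconnected contact
    graph is reported with a warning and a zero-eigenvalue multiplicity
    equal to the number of components.
    """
    idx = _selection_indices(frame, selection)
    if idx.size < 3:
        raise ValueError("GNM needs at least 3 residue nodes")
    xyz = frame.coords[idx]
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    contact = (dist <= cutoff) & ~np.eye(idx.size, dtype=bool)
    kirchhoff = np.diag(contact.sum(axis=1)).astype(float) - contact.astype(float)
    evals, evecs = np.linalg.eigh(kirchhoff)
    evals[np.abs(evals) < 1e-9] = 0.0
    n_zero = int(np.count_nonzero(evals == 0.0))
    if n_zero > 1:
        warnings.warn(
            f"GNM contact graph is disconnected: {n_zero} components "
            f"(zero-eigenvalue multiplicity {n_zero})",
            stacklevel=2,
        )
    return GnmResult(
        kirchhoff=kirchhoff,
        eigenvalues=evals,
        eigenvectors=evecs,
        residue_numbers=frame.topology.residue_numbers[idx].copy(),
        chain_ids=frame.topology.chain_ids[idx].copy(),
        cutoff=cutoff,
        n_zero_modes=n_zero,
    )


def detect_hinges(gnm: GnmResult, min_segment: int = 4) -> list[tuple[int, int]]:
    """Hinge residue pairs from sign changes of the slowest GNM mode.

    A hinge is reported between consecutive residues (within one chain)
    whose slow-mode components have opposite sign, provided the same-sign
    runs on both sides span at least ``min_segment`` residues — shorter
    runs are treated as noise.  The result is invariant to a global sign
    flip of the mode.
    """
    if min_segment < 1:
        raise ValueError("min_segment must be >= 1")
    mode = gnm.slow_mode
    hinges: list[tuple[int, int]] = []
    for chain in dict.fromkeys(str(c) for c in gnm.chain_ids):
        sel = np.flatnonzero(gnm.chain_ids == chain)
        comp = mode[sel]
        resnums = gnm.residue_numbers[sel]
        signs = np.where(comp >= 0, 1, -1)
        # run-length encode the sign sequence
        runs: list[tuple[int, int]] = []  # (start, length)
        start = 0
        for i in range(1, len(signs) + 1):
            if i == len(signs) or signs[i] != signs[start]:
                runs.append((start, i - start))
                start = i
        for (s1, l1), (s2, l2) in zip(runs, runs[1:]):
            if l1 >= min_segment and l2 >= min_segment:
                left = int(resnums[s1 + l1 - 1])
                right = int(resnums[s2])
                hinges.append((left, right))
    return hinges
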