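"""Multi-frame conformational ensembles and rigid-body alignment.

An :class:`Ensemble` binds F coordinate frames to one topology
(:class:`~dimerlink.structio.StructureModel`).  Frames come from multi-model
PDB files or DCD trajectories (read through mdtraj's low-level DCD reader,
which keeps the native Å units of the format).

Alignment is mass-unweighted Kabsch superposition on a caller-supplied atom
selection (C-alpha by default), mirroring how the downstream per-residue
fluctuation and PCA quantities are defined on C-alpha coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .structio import StructureModel, ca_indices, read_pdb

__all__ = ["Ensemble", "load_ensemble", "align_frames", "kabsch", "write_dcd"]


@dataclass
class Ensemble:
    """F frames of coordinates bound to one topology."""

    topology: StructureModel
    frames: np.ndarray  # (F, A, 3) Å
    frame_interval: float | None = None  # ps per saved frame, metadata only

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def _read_dcd(path: str) -> np.ndarray:
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(path) as fh:
        xyz, _cell_lengths, _cell_angles = fh.read()
    return np.asarray(xyz, dtype=float)


def _read_multimodel_pdb(path) -> np.ndarray:
    frames = []
    i = 0
    while True:
        try:
            model = read_pdb(path, model_index=i)
        except IndexError:
            break
        frames.append(model.coords())
        i += 1
    return np.stack(frames)


def load_ensemble(
    topology: StructureModel,
    trajectory,
    stride: int = 1,
    first_frame: int = 0,
    frame_interval: float | None = None,
) -> Ensemble:
    """Load frames ``[first_frame::stride]`` from a DCD or multi-model PDB.

    The trajectory's atom count must match the topology; pre-filter the
    topology (e.g. with :func:`~dimerlink.structio.protein_only`) before
    loading protein-only trajectories.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = os.fspath(trajectory) if not hasattr(trajectory, "read") else None
    if path is not None and path.endswith(".dcd"):
        xyz = _read_dcd(path)
    else:
        xyz = _read_multimodel_pdb(trajectory)
    if xyz.shape[1] != topology.n_atoms:
        raise ValueError(
            f"trajectory has {xyz.shape[1]} atoms but topology has {topology.n_atoms}"
        )
    sel = xyz[first_frame::stride]
    if sel.shape[0] == 0:
        raise ValueError("frame selection is empty")
    return Ensemble(topology=topology, frames=sel, frame_interval=frame_interval)


def write_dcd(ensemble: Ensemble, path) -> None:
    """Write frames to a DCD file (CHARMM/NAMD dialect, Å, 32-bit float)."""
    from mdtraj.formats import DCDTrajectoryFile

    with DCDTrajectoryFile(os.fspath(path), "w") as fh:
        fh.write(np.asarray(ensemble.frames, dtype=np.float32))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    The rotation is proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must share shape (n, 3)")
    if P.shape[0] < 3:
        raise ValueError("at least 3 points are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # collinearity check: rank of the centered point cloud
    if np.linalg.matrix_rank(P0, tol=1e-8 * max(1.0, np.abs(P0).max())) < 2:
        raise ValueError("degenerate selection: points are collinear")
    H = P0.T @ Q0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def align_frames(
    ensemble: Ensemble,
    reference: int | np.ndarray = 0,
    selection: np.ndarray | None = None,
) -> Ensemble:
    """Rigid-body align every frame to a reference over an atom selection.

    ``reference`` is a frame index or an external (A, 3) coordinate array;
    ``selection`` holds flat atom indices (default: protein C-alpha atoms).
    The transform fitted on the selection is applied to all atoms.
    """
    if selection is None:
        selection = ca_indices(ensemble.topology)
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty alignment selection")
    ref = ensemble.frames[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, float)
    if ref.shape != (ensemble.n_atoms, 3):
        raise ValueError("reference frame has wrong shape")
    ref_sel = ref[selection]
    out = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        R, t, _ = kabsch(ensemble.frames[f][selection], ref_sel)
        out[f] = ensemble.frames[f] @ R.T + t
    return Ensemble(topology=ensemble.topology, frames=out, frame_interval=ensemble.frame_interval)
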