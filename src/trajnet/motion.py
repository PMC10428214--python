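"""Superposition-based motion statistics: RMSD, RMSF, and the DCCM.

Superposition uses the Kabsch algorithm (SVD with determinant correction,
so reflections are never produced). RMSF and the dynamic cross-correlation
map are computed against the mean structure obtained by a two-pass
alignment: align to the first frame, form the mean, then re-align every
frame to that mean. Set ``align=False`` to analyse absolute coordinates
(useful when frames are already superposed, or deliberately not rigid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, SpecError
from .structures_io import Trajectory

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "rmsf_blocks",
    "dccm",
    "dccm_tsv",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray     # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float              # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns rotation R and translation t minimising |R·mobile + t − ref|²,
    with det(R) = +1 enforced. Degenerate inputs (< 3 points, or points
    that are all collinear/coincident) raise :class:`DegeneracyError`.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise SpecError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise DegeneracyError(f"superposition needs >= 3 points, got {n}")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    p, q = mob - cm, ref - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    scale = max(np.linalg.norm(p), np.linalg.norm(q))
    if scale == 0 or s[1] <= 1e-12 * max(s[0], 1e-300):
        # identical points or a collinear set: rotation is underdetermined
        if np.allclose(p, q, atol=1e-12):
            rot = np.eye(3)
            return SuperpositionResult(rot, cr - cm @ rot.T, 0.0)
        raise DegeneracyError("point set is degenerate (collinear or coincident)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - cm @ rot.T
    moved = mob @ rot.T + trans
    rmsd = math.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
    return SuperpositionResult(rot, trans, rmsd)


def _selected(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return traj.frames
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SpecError("empty selection")
    return traj.frames[:, idx, :]


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection=None,
    align: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) against one reference frame over a selection."""
    coords = _selected(traj, selection)
    ref = coords[reference_frame]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        if align:
            out[i] = kabsch_superpose(coords[i], ref).rmsd
        else:
            out[i] = math.sqrt(np.mean(np.sum((coords[i] - ref) ** 2, axis=1)))
    return out


def _aligned_to_mean(coords: np.ndarray, align: bool) -> np.ndarray:
    """Two-pass alignment: to frame 0, then to the resulting mean."""
    if not align:
        return coords
    pass1 = np.empty_like(coords)
    for i in range(coords.shape[0]):
        pass1[i] = kabsch_superpose(coords[i], coords[0]).apply(coords[i])
    mean = pass1.mean(axis=0)
    pass2 = np.empty_like(coords)
    for i in range(coords.shape[0]):
        pass2[i] = kabsch_superpose(coords[i], mean).apply(coords[i])
    return pass2


def rmsf(traj: Trajectory, selection=None, align: bool = True) -> np.ndarray:
    """Per-node RMSF (Å): sqrt of mean squared displacement from the mean."""
    if traj.n_frames < 2:
        raise SpecError("rmsf requires at least 2 frames")
    coords = _aligned_to_mean(_selected(traj, selection), align)
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def rmsf_blocks(
    traj: Trajectory, n_blocks: int, selection=None, align: bool = True
) -> np.ndarray:
    """Block-averaged RMSF: mean of per-chunk RMSF over equal frame chunks."""
    if n_blocks < 1:
        raise SpecError("n_blocks must be >= 1")
    if traj.n_frames < 2 * n_blocks:
        raise SpecError("each block needs at least 2 frames")
    coords = _selected(traj, selection)
    size = traj.n_frames // n_blocks
    per_block = []
    for b in range(n_blocks):
        hi = (b + 1) * size if b < n_blocks - 1 else traj.n_frames
        chunk = _aligned_to_mean(coords[b * size:hi], align)
        mean = chunk.mean(axis=0)
        per_block.append(
            np.sqrt(np.mean(np.sum((chunk - mean) ** 2, axis=2), axis=0))
        )
    return np.mean(per_block, axis=0)


def dccm(traj: Trajectory, selection=None, align: bool = True) -> np.ndarray:
    """Dynamic cross-correlation map over the selected nodes.

    C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), Δr the displacement
    from the node's mean position. Symmetric with unit diagonal; a node
    with zero displacement variance raises :class:`SpecError` naming it.
    """
    if traj.n_frames < 2:
        raise SpecError("dccm requires at least 2 frames")
    coords = _aligned_to_mean(_selected(traj, selection), align)
    delta = coords - coords.mean(axis=0)
    # ⟨Δr_i·Δr_j⟩: sum over xyz of per-pair frame averages
    cov = np.einsum("fic,fjc->ij", delta, delta) / delta.shape[0]
    var = np.diag(cov).copy()
    dead = np.flatnonzero(var <= 0)
    if dead.size:
        raise SpecError(
            f"zero-variance node(s) at selected index {dead.tolist()}: "
            "correlation undefined"
        )
    denom = np.sqrt(np.outer(var, var))
    c = cov / denom
    np.fill_diagonal(c, 1.0)
    return c


def dccm_tsv(matrix: np.ndarray, labels: list[str] | None = None) -> str:
    n = matrix.shape[0]
    labels = labels or [str(i) for i in range(n)]
    lines = ["node\t" + "\t".join(labels)]
    for i in range(n):
        row = "\t".join(f"{matrix[i, j]:.6f}" for j in range(n))
        lines.append(f"{labels[i]}\t{row}")
    return "\n".join(lines) + "\n"
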