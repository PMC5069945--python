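"""Preprocessing of segmented cardiac geometry before shape modelling.

The chain mirrors how short-axis cine segmentations are prepared for
population analysis: correct the in-plane slice misalignment caused by
inconsistent breath holds, loft contour stacks into closed surfaces,
rigidly align the population (rotation + translation only — size is a
disease signal and is deliberately not normalised away), resample the
cardiac cycle to a common number of frames, and identify the ED/ES
phases from the blood-pool volume curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    GapError,
    IncompatiblePopulationError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .mesh import (
    BiVentricleMesh,
    Surface,
    build_ring_shell,
    check_shared_topology,
    mesh_volume,
)

SURFACE_NAMES = ("lv_endo", "lv_epi", "rv_endo")


@dataclass(frozen=True)
class ContourSlice:
    """One image slice: z position (mm) and closed point loops per surface."""

    z: float
    contours: dict  # surface name -> (P, 3) ordered closed loop

    def shifted(self, dx: float, dy: float) -> "ContourSlice":
        moved = {
            k: v + np.array([dx, dy, 0.0]) for k, v in self.contours.items()
        }
        return ContourSlice(self.z, moved)


@dataclass(frozen=True)
class ContourStack:
    """A stack of contour slices for one cardiac frame, sorted by z."""

    slices: tuple
    phase_index: int = 0
    frame_count: int = 1

    def __post_init__(self) -> None:
        zs = [s.z for s in self.slices]
        if any(b < a for a, b in zip(zs, zs[1:])):
            object.__setattr__(
                self, "slices", tuple(sorted(self.slices, key=lambda s: s.z))
            )

    def surface_slices(self, name: str) -> list[ContourSlice]:
        return [s for s in self.slices if name in s.contours]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (proper orthonormal) plus translation; no scaling."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if r.shape != (3, 3):
            raise InvalidArgumentError("rotation must be 3x3")
        if np.abs(r @ r.T - np.eye(3)).max() > 1e-9 or np.linalg.det(r) < 0:
            raise InvalidArgumentError("rotation must be proper orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def correct_slice_misalignment(stack: ContourStack) -> ContourStack:
    """Translate each slice in-plane so LV-epicardial centroids are collinear.

    Breath-hold misalignment shifts whole slices independently in the
    image plane.  The per-slice LV-epicardium centroid is the most
    stable landmark available, so each slice is shifted so its centroid
    falls on the least-squares line of in-plane centroid position
    regressed on z (z positions are exact scanner geometry; in-plane
    positions carry the misalignment).  All surfaces on a slice receive
    that slice's shift; z is untouched.
    """
    if len(stack.slices) < 3:
        raise InsufficientDataError("misalignment correction needs >= 3 slices")
    centroids = []
    for s in stack.slices:
        if "lv_epi" not in s.contours:
            raise GapError(f"slice at z={s.z} has no lv_epi contour")
        centroids.append(s.contours["lv_epi"].mean(axis=0))
    centroids = np.asarray(centroids)
    z = np.array([s.z for s in stack.slices])
    # least-squares line (x, y) = a + b z
    design = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(design, centroids[:, :2], rcond=None)
    on_line = design @ coef  # (n_slices, 2)
    shifts = on_line - centroids[:, :2]
    new_slices = tuple(
        s.shifted(dx, dy) for s, (dx, dy) in zip(stack.slices, shifts)
    )
    return ContourStack(new_slices, stack.phase_index, stack.frame_count)


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of source onto target (no scaling)."""
    ps, pt = source.mean(axis=0), target.mean(axis=0)
    h = (source - ps).T @ (target - pt)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, pt - r @ ps)


def rigid_align_population(
    meshes: list[BiVentricleMesh],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[BiVentricleMesh], list[RigidTransform]]:
    """Generalised Procrustes alignment, rotation + translation only.

    Iterates rigid superposition of every subject onto the running mean
    shape (initialised from the first subject) until the mean changes by
    less than ``tol`` mm or ``max_iter`` iterations.  No scaling is
    applied anywhere: size differences are preserved for analysis.  The
    final mean centroid is moved to the origin.
    """
    if len(meshes) < 2:
        raise InsufficientDataError("alignment needs >= 2 meshes")
    check_shared_topology(meshes)
    originals = [
        np.vstack([s.vertices for _, s in m.surfaces()]) for m in meshes
    ]
    mean = originals[0].copy()
    transforms = [RigidTransform.identity() for _ in meshes]
    for _ in range(max_iter):
        transforms = [_kabsch(p, mean) for p in originals]
        aligned = [t.apply(p) for t, p in zip(transforms, originals)]
        new_mean = np.mean(aligned, axis=0)
        delta = np.abs(new_mean - mean).max()
        mean = new_mean
        if delta < tol:
            break
    shift = -mean.mean(axis=0)
    transforms = [
        RigidTransform(t.rotation, t.translation + shift) for t in transforms
    ]
    aligned_meshes = [
        m.transformed(t.rotation, t.translation)
        for m, t in zip(meshes, transforms)
    ]
    return aligned_meshes, transforms


def resample_temporal(
    sequence: list, target_frames: int
) -> list:
    """Resample a cine sequence of per-frame point arrays to ``target_frames``.

    Frames are placed at normalised cycle times ``i / (F - 1)``; output
    frames at ``j / (target_frames - 1)`` are per-point linear
    interpolations.  The cycle is treated as non-periodic between the
    first and last acquired frame (frame 0 is acquisition-triggered).
    Accepts any sequence of equally-shaped coordinate arrays.
    """
    if len(sequence) < 2:
        raise InsufficientDataError("temporal resampling needs >= 2 frames")
    if target_frames < 2:
        raise InvalidArgumentError("target_frames must be >= 2")
    arrays = [np.asarray(f, dtype=np.float64) for f in sequence]
    shape0 = arrays[0].shape
    if any(a.shape != shape0 for a in arrays):
        raise IncompatiblePopulationError(
            "point counts differ across frames; cannot resample"
        )
    stackarr = np.stack(arrays)  # (F, ...)
    f = len(arrays)
    t_src = np.linspace(0.0, 1.0, f)
    t_dst = np.linspace(0.0, 1.0, target_frames)
    flat = stackarr.reshape(f, -1)
    out = np.empty((target_frames, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(t_dst, t_src, flat[:, j])
    return [frame.reshape(shape0) for frame in out]


def detect_ed_es(volume_curve: list[float]) -> tuple[int, int]:
    """ED = frame of maximal, ES = frame of minimal blood-pool volume.

    Ties are broken toward the earliest frame.  Volumes must be
    positive (a closed blood pool always has positive volume).
    """
    v = np.asarray(volume_curve, dtype=np.float64)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 frames to identify ED/ES")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise InvalidArgumentError("volumes must be positive and finite")
    return int(np.argmax(v)), int(np.argmin(v))


# ---------------------------------------------------------------------------
# Lofting contour stacks into surfaces
# ---------------------------------------------------------------------------


def _resample_loop(loop: np.ndarray, n: int, start_offset: float = 0.0) -> np.ndarray:
    """Resample a closed loop to ``n`` points uniformly in arc length.

    ``start_offset`` is a fraction of total perimeter at which the first
    output point is placed (used for minimal-twist matching).
    """
    loop = np.asarray(loop, dtype=np.float64)
    closed = np.vstack([loop, loop[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = (start_offset * total + np.arange(n) / n * total) % total
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, cum, closed[:, d])
    return out


def _min_twist_offset(ring: np.ndarray, prev: np.ndarray, n_cand: int = 96) -> float:
    """Start offset (fraction of perimeter) minimising twist w.r.t. ``prev``."""
    n = prev.shape[0]
    best, best_cost = 0.0, np.inf
    for off in np.arange(n_cand) / n_cand:
        cand = _resample_loop(ring, n, start_offset=off)
        cost = np.sum((cand - prev) ** 2)
        if cost < best_cost - 1e-12:
            best, best_cost = off, cost
    return best


def loft_surface(
    loops: list[np.ndarray], circumferential_resolution: int
) -> Surface:
    """Loft ordered slice loops (apex-to-base by z) into a closed surface.

    Each loop is resampled to the template's circumferential count by
    arc length; adjacent rings are matched with a minimal-twist start
    offset; the apex end is closed with a fan to the lowest ring's
    centroid, the base with a flat cap at the highest ring's centroid.
    The output shares the template vertex layout (apex pole, rings,
    basal centre).
    """
    if len(loops) < 3:
        raise InsufficientDataError("lofting needs loops on >= 3 slices")
    nc = circumferential_resolution
    rings = [_resample_loop(loops[0], nc)]
    for loop in loops[1:]:
        off = _min_twist_offset(loop, rings[-1])
        rings.append(_resample_loop(loop, nc, start_offset=off))
    rings = np.asarray(rings)  # (na, nc, 3), apex-to-base
    apex = rings[0].mean(axis=0)
    base_center = rings[-1].mean(axis=0)
    return build_ring_shell(rings, apex, base_center)


def loft_contours(
    stack: ContourStack, circumferential_resolution: int = 24
) -> BiVentricleMesh:
    """Loft a (misalignment-corrected) contour stack into a bi-ventricle mesh.

    Every surface must be present on a contiguous run of >= 3 slices; a
    surface missing on an interior slice of its run is a segmentation
    gap and raises :class:`GapError`.
    """
    parts = {}
    for name in SURFACE_NAMES:
        present = [name in s.contours for s in stack.slices]
        if sum(present) < 3:
            raise GapError(f"surface {name!r} present on fewer than 3 slices")
        first, last = present.index(True), len(present) - present[::-1].index(True) - 1
        if not all(present[first : last + 1]):
            raise GapError(f"surface {name!r} missing on an interior slice")
        loops = [
            stack.slices[i].contours[name] for i in range(first, last + 1)
        ]
        parts[name] = loft_surface(loops, circumferential_resolution)
    return BiVentricleMesh(**parts)


def blood_pool_volume(mesh: BiVentricleMesh) -> float:
    """Combined LV + RV endocardial (blood pool) volume, mm^3."""
    return mesh_volume(mesh.lv_endo) + mesh_volume(mesh.rv_endo)
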