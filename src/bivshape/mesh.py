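"""Triangulated surfaces and the bi-ventricle mesh container.

The unit of shape in this package is a :class:`BiVentricleMesh`: three
closed triangulated surfaces (LV endocardium, LV epicardium, RV
endocardium) sharing one template topology, so that point correspondence
across a population is by vertex index.  The RV epicardium is not
modelled; the RV wall is too thin to delineate reliably on short-axis
cine images.

Coordinates are millimetres in a right-handed frame with the long axis
along +z, the base at z = 0 and the apex at negative z.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import trimesh

from .errors import IncompatiblePopulationError, NonWatertightError

SURFACE_NAMES = ("lv_endo", "lv_epi", "rv_endo")


@dataclass(frozen=True)
class Surface:
    """A triangulated surface: ``vertices`` (V, 3) float mm, ``faces`` (F, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (V, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (F, 3), got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices contain non-finite coordinates")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def with_vertices(self, vertices: np.ndarray) -> "Surface":
        return Surface(np.asarray(vertices, dtype=np.float64), self.faces)

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )


def mesh_volume(surface: Surface) -> float:
    """Signed enclosed volume (mm^3) by the divergence theorem.

    Sums the signed volumes of tetrahedra joining each triangle to the
    origin; the result is positive for consistent outward orientation
    and independent of the choice of origin for a closed surface.

    Raises
    ------
    NonWatertightError
        If the surface has boundary edges (is not closed).
    """
    if not surface.is_closed():
        raise NonWatertightError(
            "mesh_volume requires a closed surface (boundary edges present)"
        )
    tri = surface.vertices[surface.faces]  # (F, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def build_ring_shell(
    rings: np.ndarray, apex: np.ndarray, base_center: np.ndarray
) -> Surface:
    """Close a stack of rings into a watertight shell.

    ``rings`` is (na, nc, 3) ordered apex-to-base; vertex layout is apex
    pole, then the rings, then the basal-cap centre — the shared
    template topology.  Faces are oriented outward (positive signed
    volume).
    """
    rings = np.asarray(rings, dtype=np.float64)
    na, nc, _ = rings.shape
    vertices = np.vstack(
        [np.asarray(apex).reshape(1, 3), rings.reshape(na * nc, 3),
         np.asarray(base_center).reshape(1, 3)]
    )
    faces: list[tuple[int, int, int]] = []
    ring = lambda i, j: 1 + i * nc + (j % nc)  # noqa: E731
    for j in range(nc):  # apex fan
        faces.append((0, ring(0, j), ring(0, j + 1)))
    for i in range(na - 1):  # quad strips
        for j in range(nc):
            faces.append((ring(i, j), ring(i + 1, j), ring(i + 1, j + 1)))
            faces.append((ring(i, j), ring(i + 1, j + 1), ring(i, j + 1)))
    base_idx = vertices.shape[0] - 1
    for j in range(nc):  # flat basal cap
        faces.append((base_idx, ring(na - 1, j + 1), ring(na - 1, j)))
    surf = Surface(vertices, np.asarray(faces, dtype=np.int64))
    if mesh_volume(surf) < 0:
        surf = Surface(vertices, surf.faces[:, ::-1])
    return surf


@dataclass(frozen=True)
class BiVentricleMesh:
    """Three co-registered cardiac surfaces plus a cardiac-phase label."""

    lv_endo: Surface
    lv_epi: Surface
    rv_endo: Surface
    phase_label: str = "ED"

    def surfaces(self) -> Iterator[tuple[str, Surface]]:
        for name in SURFACE_NAMES:
            yield name, getattr(self, name)

    @property
    def n_vertices_total(self) -> int:
        return sum(s.n_vertices for _, s in self.surfaces())

    def flatten(self) -> np.ndarray:
        """Concatenated vertex coordinates, order LV endo | LV epi | RV endo."""
        return np.concatenate(
            [s.vertices.ravel() for _, s in self.surfaces()]
        )

    def surface_slices(self) -> dict[str, slice]:
        """Index ranges of each surface inside the flattened vector."""
        out: dict[str, slice] = {}
        start = 0
        for name, s in self.surfaces():
            stop = start + 3 * s.n_vertices
            out[name] = slice(start, stop)
            start = stop
        return out

    def with_flat(self, flat: np.ndarray, phase_label: str | None = None) -> "BiVentricleMesh":
        """Rebuild a mesh with the same topology from a flattened vector."""
        flat = np.asarray(flat, dtype=np.float64)
        if flat.size != 3 * self.n_vertices_total:
            raise IncompatiblePopulationError(
                f"flat vector of length {flat.size} does not match "
                f"{3 * self.n_vertices_total} coordinates"
            )
        parts = {}
        for name, s in self.surfaces():
            sl = self.surface_slices()[name]
            parts[name] = s.with_vertices(flat[sl].reshape(-1, 3))
        return BiVentricleMesh(
            phase_label=self.phase_label if phase_label is None else phase_label,
            **parts,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BiVentricleMesh":
        """Apply a rigid transform x -> R x + t to every surface."""
        parts = {
            name: s.with_vertices(s.vertices @ np.asarray(rotation).T + translation)
            for name, s in self.surfaces()
        }
        return BiVentricleMesh(phase_label=self.phase_label, **parts)

    def same_topology(self, other: "BiVentricleMesh") -> bool:
        return all(
            a.vertices.shape == b.vertices.shape and np.array_equal(a.faces, b.faces)
            for (_, a), (_, b) in zip(self.surfaces(), other.surfaces())
        )


def check_shared_topology(meshes: list[BiVentricleMesh]) -> None:
    """Raise IncompatiblePopulationError unless all meshes share topology."""
    if not meshes:
        return
    ref = meshes[0]
    for i, m in enumerate(meshes[1:], start=1):
        if not ref.same_topology(m):
            raise IncompatiblePopulationError(
                f"mesh {i} does not share the template topology of mesh 0"
            )


def save_ply(mesh: BiVentricleMesh, stem: str | Path) -> list[Path]:
    """Write one ASCII PLY per surface, suffixed _lvendo/_lvepi/_rvendo."""
    stem = Path(stem)
    suffix = {"lv_endo": "_lvendo", "lv_epi": "_lvepi", "rv_endo": "_rvendo"}
    paths = []
    for name, s in mesh.surfaces():
        path = stem.with_name(stem.name + suffix[name] + ".ply")
        s.to_trimesh().export(path, encoding="ascii")
        paths.append(path)
    return paths


def load_ply(stem: str | Path, phase_label: str = "ED") -> BiVentricleMesh:
    """Load a bi-ventricle mesh written by :func:`save_ply`."""
    stem = Path(stem)
    suffix = {"lv_endo": "_lvendo", "lv_epi": "_lvepi", "rv_endo": "_rvendo"}
    parts = {}
    for name, suf in suffix.items():
        tm = trimesh.load(stem.with_name(stem.name + suf + ".ply"), process=False)
        parts[name] = Surface(np.asarray(tm.vertices), np.asarray(tm.faces))
    return BiVentricleMesh(phase_label=phase_label, **parts)
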