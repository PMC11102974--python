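"""Muscle morphometry from segmented triangulated surfaces.

Muscle volumes and maximal anatomical cross-sectional areas (CSA) are
computed from watertight STL surfaces exported by MRI segmentation.
Vertex coordinates are assumed to be in millimetres (DICOM-derived
meshes); volumes are reported in cm^3 and areas in mm^2, matching the
conventions of MRI muscle morphometry.  The volume is the divergence-
theorem (signed tetrahedron) sum over faces; the CSA is obtained by
slicing the surface with planes perpendicular to a chosen axis — by
default the scanner's axial (z) direction — and taking the maximal total
area of the closed intersection polygons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import trimesh

from .errors import InvalidParameterError, MeshError

__all__ = [
    "MuscleMesh",
    "MuscleMorphometry",
    "load_stl",
    "mesh_volume",
    "max_csa",
    "normalize_morphometry",
]

log = logging.getLogger(__name__)

MM3_PER_CM3 = 1000.0


@dataclass(frozen=True)
class MuscleMesh:
    """A labelled, watertight triangulated muscle surface (mm units)."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""
    side: Literal["left", "right", ""] = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise InvalidParameterError("vertices must be (n,3) and faces (m,3)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass(frozen=True)
class MuscleMorphometry:
    """Morphometric summary for one muscle."""

    label: str
    volume_cm3: float
    csa_max_mm2: float
    csa_axis: tuple[float, float, float]
    csa_location_mm: float
    volume_per_bmi: Optional[float] = None


def load_stl(path: str | Path, label: str = "", side: str = "") -> MuscleMesh:
    """Load an STL file (binary or ASCII) as a :class:`MuscleMesh`."""
    mesh = trimesh.load_mesh(str(path), file_type="stl")
    return MuscleMesh(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces),
                      label=label or Path(path).stem, side=side)  # type: ignore[arg-type]


def _checked_trimesh(mesh: MuscleMesh) -> trimesh.Trimesh:
    tm = mesh.to_trimesh()
    areas = tm.area_faces
    n_degenerate = int(np.sum(areas <= 0))
    if n_degenerate:
        log.info("dropping %d degenerate faces from %s", n_degenerate, mesh.label or "mesh")
        tm.update_faces(areas > 0)
    if not tm.is_watertight:
        n_open = len(trimesh.grouping.group_rows(tm.edges_sorted, require_count=1))
        raise MeshError(
            f"mesh {mesh.label or ''!r} is not watertight: {n_open} boundary edges"
        )
    return tm


def mesh_volume(mesh: MuscleMesh) -> float:
    """Enclosed volume of a watertight surface, in cm^3.

    Computed as the absolute value of the signed-tetrahedron sum
    ``sum(det[v0, v1, v2]) / 6`` over faces (divergence theorem), so the
    result is independent of global orientation and of any translation of
    the mesh.
    """
    tm = _checked_trimesh(mesh)
    v = tm.vertices - tm.vertices.mean(axis=0)  # recenter for numerical hygiene
    tri = v[tm.faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return abs(float(signed.sum())) / MM3_PER_CM3


def max_csa(
    mesh: MuscleMesh,
    axis: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 1.0),
    slice_step_mm: float = 2.0,
) -> tuple[float, float]:
    """Maximal anatomical cross-sectional area along an axis.

    The surface is intersected with planes perpendicular to ``axis`` at a
    ``slice_step_mm`` spacing (2 mm by default, the usual axial MRI slice
    thickness); each plane's area is the summed area of its closed
    intersection polygons.  Returns ``(csa_max_mm2, location_mm)`` where
    the location is the coordinate of the maximal slice along the axis,
    measured from the mesh's lower extent.

    Raises :class:`MeshError` if no plane intersects the surface.
    """
    axis = np.asarray(axis, dtype=float)
    norm = float(np.linalg.norm(axis))
    if norm == 0:
        raise InvalidParameterError("axis must be non-zero")
    if slice_step_mm <= 0:
        raise InvalidParameterError("slice_step_mm must be positive")
    axis = axis / norm
    tm = _checked_trimesh(mesh)
    proj = tm.vertices @ axis
    lo, hi = float(proj.min()), float(proj.max())
    # planes centred on the mid-extent so symmetric solids get a slice
    # through their widest section; endpoint planes would graze the surface
    mid = (lo + hi) / 2.0
    k_max = int(np.floor((hi - lo) / 2.0 / slice_step_mm - 1e-9))
    heights = mid + slice_step_mm * np.arange(-k_max, k_max + 1)
    origin = np.zeros(3)
    sections = tm.section_multiplane(plane_origin=origin, plane_normal=axis,
                                     heights=heights)
    best_area, best_h = 0.0, None
    for h, sec in zip(heights, sections):
        if sec is None:
            continue
        area = float(sec.area)
        if area > best_area:
            best_area, best_h = area, float(h)
    if best_h is None:
        raise MeshError("no slicing plane intersects the surface")
    return best_area, best_h - lo


def normalize_morphometry(m: MuscleMorphometry, bmi: float) -> MuscleMorphometry:
    """Add the BMI-normalized volume (cm^3 per kg/m^2) to a morphometry record.

    Normalizing by body mass index removes the confounding effect of
    stature and mass when comparing muscle volumes across subjects.
    """
    if bmi <= 0:
        raise InvalidParameterError("bmi must be positive")
    return replace(m, volume_per_bmi=m.volume_cm3 / bmi)


def measure_muscle(
    mesh: MuscleMesh,
    axis: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 1.0),
    slice_step_mm: float = 2.0,
    bmi: Optional[float] = None,
) -> MuscleMorphometry:
    """Convenience wrapper: volume + maximal CSA (+ BMI normalization)."""
    vol = mesh_volume(mesh)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    csa, loc = max_csa(mesh, axis=ax, slice_step_mm=slice_step_mm)
    result = MuscleMorphometry(
        label=mesh.label, volume_cm3=vol, csa_max_mm2=csa,
        csa_axis=(float(ax[0]), float(ax[1]), float(ax[2])), csa_location_mm=loc,
    )
    return normalize_morphometry(result, bmi) if bmi is not None else result
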