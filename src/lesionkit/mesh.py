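"""Watertight triangular meshes and lesion measurements.

Each labeled lesion is converted to a closed triangular surface (iso-surface
of its binary indicator at level 0.5, in world millimetres), smoothed with a
shrink-limited two-step (Taubin) filter to remove voxel jaggedness, and then
measured: signed volume by the divergence theorem, surface area as the sum of
triangle areas, and maximum diameter as the 3D caliper (Feret) diameter over
convex-hull vertices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import ConvexHull
from skimage import measure as skmeasure

from .volume import LabeledMask, SUVVolume

__all__ = [
    "MeshConfig",
    "LesionMetrics",
    "voxels_to_mesh",
    "smooth_mesh",
    "mesh_volume",
    "mesh_surface",
    "max_diameter",
    "measure_lesions",
]

log = logging.getLogger(__name__)


@dataclass
class MeshConfig:
    """Smoothing defaults: 30 Taubin passes with the classic lambda/mu pair,
    which keeps digitized-sphere volume and surface within ~2% of analytic."""

    smooth_iterations: int = 30
    smooth_strength: float = 0.5


@dataclass
class LesionMetrics:
    """Per-lesion measurements in world units (mm, mm^2, mm^3)."""

    label: int
    volume: float
    surface: float
    suvmax: float
    max_diameter: float
    centroid: np.ndarray
    voxel_count: int


def _check_watertight(mesh: trimesh.Trimesh) -> None:
    """Every edge must be shared by exactly two faces."""
    edges = mesh.edges_sorted
    _, counts = np.unique(edges, axis=0, return_counts=True)
    bad = counts != 2
    if bad.any():
        uniq = np.unique(edges, axis=0)
        raise ValueError(
            f"mesh is not watertight: {int(bad.sum())} edges with face incidence != 2, "
            f"e.g. {uniq[bad][:5].tolist()}"
        )


def voxels_to_mesh(mask: LabeledMask, label: int) -> trimesh.Trimesh:
    """Extract the closed iso-surface of one labeled component.

    Marching cubes runs on the 0/1 indicator at level 0.5; the binary field
    is zero-padded so components touching the grid edge still close. Vertices
    land in world coordinates honoring anisotropic spacing and origin.
    """
    binary = mask.values == label
    if not binary.any():
        raise ValueError(f"label {label} not present in mask")
    padded = np.pad(binary, 1).astype(np.float32)
    # classic Lorensen tables stay closed on binary fields at level 0.5;
    # the Lewiner variant can leave open edges on speckled components
    verts, faces, _, _ = skmeasure.marching_cubes(
        padded, level=0.5, spacing=tuple(mask.spacing), method="lorensen"
    )
    verts = verts - mask.spacing + mask.origin  # undo the 1-voxel pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    mesh.update_faces(mesh.nondegenerate_faces())
    if mesh.volume < 0:
        mesh.invert()
    _check_watertight(mesh)
    return mesh


def smooth_mesh(
    mesh: trimesh.Trimesh, iterations: int = 30, strength: float = 0.5
) -> trimesh.Trimesh:
    """Shrink-limited smoothing (Taubin positive/negative relaxation).

    ``iterations=0`` is the identity. The smoothed mesh must stay watertight
    and keep its volume: a parameter choice that moves volume by more than
    10% is rejected.
    """
    if iterations == 0:
        return mesh.copy()
    if not 0 < strength < 1:
        raise ValueError(f"strength must be in (0, 1), got {strength}")
    out = mesh.copy()
    v0 = mesh.volume
    # nu slightly beyond lambda is the classic shrink-compensating pair
    trimesh.smoothing.filter_taubin(out, lamb=strength, nu=min(strength + 0.03, 0.99), iterations=iterations)
    _check_watertight(out)
    change = abs(out.volume - v0) / v0
    if change > 0.10:
        raise ValueError(
            f"smoothing parameters (iterations={iterations}, strength={strength}) changed "
            f"volume by {change:.1%} (> 10%); refusing to measure a distorted mesh"
        )
    return out


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Signed volume by the divergence theorem: V = (1/6) sum v0 . (v1 x v2)."""
    _check_watertight(mesh)
    tri = mesh.vertices[mesh.faces]
    v = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    return float(v)


def mesh_surface(mesh: trimesh.Trimesh) -> float:
    """Total surface area: sum of 0.5 * |(v1 - v0) x (v2 - v0)| over faces."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def max_diameter(mesh: trimesh.Trimesh) -> float:
    """Maximum pairwise vertex distance (3D Feret/caliper diameter).

    The maximum is attained on the convex hull, so only hull vertices enter
    the pairwise search.
    """
    pts = np.asarray(mesh.vertices, dtype=float)
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # degenerate (flat) vertex sets fall back to all pairs
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def measure_lesions(
    mask: LabeledMask, volume: SUVVolume, config: MeshConfig | None = None
) -> list[LesionMetrics]:
    """Mesh, smooth, and measure every labeled lesion.

    Per-lesion failures are logged and skipped so one pathological component
    does not abort the remaining lesions.
    """
    cfg = config or MeshConfig()
    if not mask.same_geometry(volume):
        raise ValueError("mask geometry does not match the SUV volume")
    out: list[LesionMetrics] = []
    for k in mask.labels:
        try:
            raw = voxels_to_mesh(mask, k)
            v_raw = raw.volume
            smoothed = smooth_mesh(raw, cfg.smooth_iterations, cfg.smooth_strength)
            comp = mask.values == k
            idx = np.argwhere(comp)
            metrics = LesionMetrics(
                label=k,
                volume=mesh_volume(smoothed),
                surface=mesh_surface(smoothed),
                suvmax=float(volume.values[comp].max()),
                max_diameter=max_diameter(smoothed),
                centroid=mask.world_coords(idx).mean(axis=0),
                voxel_count=int(comp.sum()),
            )
            log.info(
                "lesion %d: volume %.1f mm^3 (pre-smoothing %.1f), surface %.1f mm^2, "
                "diameter %.1f mm",
                k, metrics.volume, v_raw, metrics.surface, metrics.max_diameter,
            )
            out.append(metrics)
        except Exception as exc:  # keep measuring the remaining lesions
            log.error("lesion %d failed: %s", k, exc)
    return out
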