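"""Cell segmentation, tracking, and conversion of masks to finite-element meshes.

Segmentation is deliberately simple (Gaussian smoothing + Otsu/fixed threshold
+ morphology): the inverse problem downstream does not depend on how the cell
outline was obtained, and externally produced mask TIFFs can be supplied
instead.

Meshing (2D): the 0.5 iso-contour of the mask is extracted, smoothed by a few
Laplacian passes (pixelated outlines otherwise imprint spurious oscillations on
the recovered boundary velocity), resampled at the target edge length and
filled with a near-hexagonal point lattice; a Delaunay triangulation restricted
to the polygon gives the mesh. 3D masks are meshed by splitting interior voxels
into six tetrahedra (Kuhn decomposition), which is exact with respect to the
voxelised volume.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage import measure, morphology, filters
from scipy import ndimage

from .errors import MeshingError, NoCellFound
from .imaging import ImageSequence

__all__ = [
    "CellMask",
    "FEMesh",
    "segment_and_track",
    "mask_to_mesh",
    "mesh_polygon",
    "rectangle_mesh",
    "disk_mesh",
    "load_masks",
    "save_masks",
]


@dataclass
class CellMask:
    """Binary cell-interior mask for one frame."""

    mask: np.ndarray  # bool array, same geometry as the frame
    frame_index: int = 0

    def area(self, pixel_size: float) -> float:
        """Foreground measure in μm² (2D) or voxel volume in μm³-per-z (3D)."""
        return float(self.mask.sum()) * pixel_size ** self.mask.ndim

    def centroid(self, pixel_size: float) -> np.ndarray:
        """Foreground centroid in physical (x, y[, z]) μm coordinates."""
        idx = np.argwhere(self.mask).mean(axis=0)
        return (idx[::-1] + 0.5) * pixel_size


@dataclass
class FEMesh:
    """Simplicial mesh of the cell interior in physical μm coordinates.

    ``simplices`` are positively oriented; ``boundary_facets`` (edges in 2D,
    triangles in 3D) are stored with outward unit ``boundary_normals`` and
    together form the closed domain boundary Γ.
    """

    nodes: np.ndarray            # (n, d)
    simplices: np.ndarray        # (m, d+1) int
    boundary_facets: np.ndarray  # (b, d) int
    boundary_normals: np.ndarray  # (b, d)
    target_edge_length: float = 0.0

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def simplex_measures(self) -> np.ndarray:
        """Area (2D) / volume (3D) of each simplex."""
        v = self.nodes[self.simplices]
        edges = v[:, 1:] - v[:, :1]
        return np.linalg.det(edges) / _factorial(self.dim)

    def measure(self) -> float:
        return float(self.simplex_measures().sum())

    def facet_measures(self) -> np.ndarray:
        """Length (2D) / area (3D) of each boundary facet."""
        v = self.nodes[self.boundary_facets]
        if self.dim == 2:
            return np.linalg.norm(v[:, 1] - v[:, 0], axis=1)
        cr = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    @property
    def boundary_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_facets)


def _factorial(d: int) -> int:
    out = 1
    for k in range(2, d + 1):
        out *= k
    return out


# ---------------------------------------------------------------------------
# Segmentation & tracking
# ---------------------------------------------------------------------------

def segment_and_track(
    seq: ImageSequence,
    threshold_mode: str = "auto",
    min_area: float = 10.0,
    smoothing_sigma: float = 2.0,
    fixed_threshold: float | None = None,
) -> list[CellMask]:
    """Segment the (single) cell in every frame and link masks through time.

    Each frame is Gaussian-smoothed, thresholded (Otsu in ``auto`` mode, a
    user value in ``fixed`` mode), cleaned by morphological closing and hole
    filling, and reduced to one connected component. Components are linked
    frame-to-frame by maximal overlap with the previous mask (single-cell
    assumption).

    Raises
    ------
    NoCellFound
        If a frame has no component of at least ``min_area`` μm².
    """
    if threshold_mode not in ("auto", "fixed"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    if threshold_mode == "fixed" and fixed_threshold is None:
        raise ValueError("fixed threshold_mode requires fixed_threshold")
    min_px = max(1, int(round(min_area / seq.pixel_size ** 2)))
    masks: list[CellMask] = []
    prev: np.ndarray | None = None
    for t, frame in enumerate(seq.frames):
        sm = ndimage.gaussian_filter(frame, smoothing_sigma)
        if threshold_mode == "auto":
            if np.ptp(sm) <= 0:
                raise NoCellFound(t, f"frame {t} is constant")
            thr = filters.threshold_otsu(sm)
        else:
            thr = fixed_threshold
        binary = sm > thr
        binary = morphology.closing(binary, morphology.disk(2) if frame.ndim == 2 else morphology.ball(2))
        binary = ndimage.binary_fill_holes(binary)
        labels, n = ndimage.label(binary)
        if n == 0:
            raise NoCellFound(t)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        candidates = np.flatnonzero(sizes >= min_px) + 1
        if candidates.size == 0:
            raise NoCellFound(t, f"no component above {min_area} μm² in frame {t}")
        if prev is None:
            best = candidates[np.argmax(sizes[candidates - 1])]
        else:
            overlaps = ndimage.sum_labels(prev.astype(float), labels, index=candidates)
            best = (
                candidates[np.argmax(overlaps)]
                if overlaps.max() > 0
                else candidates[np.argmax(sizes[candidates - 1])]
            )
        mask = labels == best
        masks.append(CellMask(mask, frame_index=t))
        prev = mask
    return masks


def load_masks(path) -> list[CellMask]:
    """Read per-frame binary masks from a multi-page TIFF."""
    pages = np.asarray(tifffile.imread(path))
    if pages.ndim == 2:
        pages = pages[None]
    return [CellMask(pages[i] > 0, frame_index=i) for i in range(pages.shape[0])]


def save_masks(path, masks: list[CellMask]) -> None:
    tifffile.imwrite(path, np.stack([m.mask.astype(np.uint8) for m in masks]),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# 2D meshing
# ---------------------------------------------------------------------------

_SMOOTHING_ITERS = 3


def _extract_contour(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    """Largest closed 0.5-iso contour in physical (x, y) coordinates."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise MeshingError("mask has no iso-contour (empty mask?)")
    contour = max(contours, key=len)
    rc = contour - 1.0  # undo padding
    # find_contours places the contour at inter-pixel positions relative to
    # pixel centres (integer indices); centres are at (i+0.5)*pixel_size
    xy = np.stack([rc[:, 1] + 0.5, rc[:, 0] + 0.5], axis=1) * pixel_size
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


def _laplacian_smooth(poly: np.ndarray, iters: int = _SMOOTHING_ITERS) -> np.ndarray:
    for _ in range(iters):
        poly = 0.5 * poly + 0.25 * (np.roll(poly, 1, axis=0) + np.roll(poly, -1, axis=0))
    return poly


def _resample_closed(poly: np.ndarray, spacing: float) -> np.ndarray:
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(8, int(round(total / spacing)))
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    y = np.interp(si, s, closed[:, 1])
    return np.stack([x, y], axis=1)


def mesh_polygon(boundary: np.ndarray, target_edge_length: float) -> FEMesh:
    """Triangulate the interior of a closed polygon at a target edge length.

    The polygon is resampled at the edge length, filled with a hexagonal
    lattice of interior points kept clear of the boundary, Delaunay
    triangulated, and clipped back to the polygon.
    """
    h = float(target_edge_length)
    poly = Polygon(boundary)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type != "Polygon":
            raise MeshingError("boundary polygon is self-intersecting")
    if poly.buffer(-h).is_empty:
        raise MeshingError(
            f"domain thinner than 2×edge length ({2 * h:.3g} μm) somewhere; "
            "reduce target_edge_length"
        )
    bnd = _resample_closed(np.asarray(poly.exterior.coords)[:-1], h)

    xmin, ymin, xmax, ymax = poly.bounds
    dy = h * np.sqrt(3) / 2
    rows = np.arange(ymin + dy, ymax, dy)
    interior_pts = []
    eroded = prep(poly.buffer(-0.7 * h))
    for j, y in enumerate(rows):
        xs = np.arange(xmin + (h / 2 if j % 2 else h), xmax, h)
        for x in xs:
            if eroded.contains(Point(x, y)):
                interior_pts.append((x, y))
    pts = np.vstack([bnd, np.asarray(interior_pts).reshape(-1, 2)])

    tri = Delaunay(pts)
    centroids = pts[tri.simplices].mean(axis=1)
    inside = prep(poly.buffer(1e-9 * max(1.0, h)))
    keep = np.fromiter(
        (inside.contains(Point(*c)) for c in centroids), bool, len(centroids)
    )
    v = pts[tri.simplices]
    area2 = (v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1]) - (
        v[:, 2, 0] - v[:, 0, 0]
    ) * (v[:, 1, 1] - v[:, 0, 1])
    keep &= np.abs(area2) > 1e-12 * h * h
    simplices = tri.simplices[keep]
    if len(simplices) == 0:
        raise MeshingError("no triangles survive clipping; domain too small")

    # drop unused nodes and re-index
    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = pts[used]
    simplices = remap[simplices]
    mesh = _finalise_mesh(nodes, simplices, h)
    return mesh


def _finalise_mesh(nodes: np.ndarray, simplices: np.ndarray, h: float) -> FEMesh:
    """Fix orientation, find boundary facets and outward normals."""
    d = nodes.shape[1]
    v = nodes[simplices]
    det = np.linalg.det(v[:, 1:] - v[:, :1])
    flip = det < 0
    simplices = simplices.copy()
    simplices[flip, -2], simplices[flip, -1] = (
        simplices[flip, -1].copy(),
        simplices[flip, -2].copy(),
    )

    facet_count: dict[tuple, list] = {}
    for si, simplex in enumerate(simplices):
        for omit in range(d + 1):
            facet = tuple(sorted(np.delete(simplex, omit)))
            facet_count.setdefault(facet, []).append((si, omit))
    boundary, normals = [], []
    for facet, owners in facet_count.items():
        if len(owners) != 1:
            continue
        si, omit = owners[0]
        fnodes = np.array(facet)
        opp = simplices[si][omit]
        n = _facet_normal(nodes[fnodes], nodes[opp])
        boundary.append(fnodes)
        normals.append(n)
    return FEMesh(
        nodes=np.ascontiguousarray(nodes, dtype=np.float64),
        simplices=np.ascontiguousarray(simplices, dtype=np.int64),
        boundary_facets=np.asarray(boundary, dtype=np.int64),
        boundary_normals=np.asarray(normals, dtype=np.float64),
        target_edge_length=h,
    )


def _facet_normal(facet_coords: np.ndarray, opposite: np.ndarray) -> np.ndarray:
    if facet_coords.shape[0] == 2:  # edge in 2D
        t = facet_coords[1] - facet_coords[0]
        n = np.array([t[1], -t[0]])
    else:  # triangle in 3D
        n = np.cross(facet_coords[1] - facet_coords[0], facet_coords[2] - facet_coords[0])
    n = n / np.linalg.norm(n)
    if np.dot(n, facet_coords.mean(axis=0) - opposite) < 0:
        n = -n
    return n


def mask_to_mesh(
    mask: CellMask | np.ndarray,
    pixel_size: float,
    target_edge_length: float | None = None,
    z_spacing: float | None = None,
) -> FEMesh:
    """Convert a binary mask into a simplicial mesh of the cell interior.

    2D masks go through contour extraction / smoothing / triangulation; 3D
    masks are split voxel-wise into tetrahedra. The resulting measure is
    required to match the mask measure within 3%.
    """
    arr = mask.mask if isinstance(mask, CellMask) else np.asarray(mask) > 0
    if target_edge_length is None:
        target_edge_length = 2.0 * pixel_size
    if target_edge_length < pixel_size:
        raise ValueError("target_edge_length must be at least one pixel")
    if arr.sum() < 4:
        raise MeshingError(f"mask has only {int(arr.sum())} foreground pixels")
    if arr.ndim == 2:
        contour = _extract_contour(arr, pixel_size)
        contour = _laplacian_smooth(contour)
        mesh = mesh_polygon(contour, target_edge_length)
        mask_area = float(arr.sum()) * pixel_size ** 2
        if abs(mesh.measure() - mask_area) > 0.03 * mask_area:
            raise MeshingError(
                f"mesh area {mesh.measure():.3g} deviates more than 3% from "
                f"mask area {mask_area:.3g} μm²; mask may be too thin or noisy"
            )
        return mesh
    if arr.ndim == 3:
        return _voxel_tet_mesh(arr, pixel_size, z_spacing or pixel_size, target_edge_length)
    raise ValueError("mask must be 2D or 3D")


# Kuhn decomposition of the unit cube into 6 tetrahedra; consistent across
# shared faces because it follows coordinate-sorted paths (0,0,0)->(1,1,1).
_KUHN_PATHS = list(itertools.permutations(range(3)))


def _voxel_tet_mesh(mask: np.ndarray, pixel_size: float, z_spacing: float, h: float) -> FEMesh:
    step = max(1, int(round(h / pixel_size)))
    if step > 1:  # coarsen by majority voting over blocks
        nz, ny, nx = (s // step for s in mask.shape)
        mask = mask[: nz * step, : ny * step, : nx * step]
        mask = (
            mask.reshape(nz, step, ny, step, nx, step).mean(axis=(1, 3, 5)) >= 0.5
        )
        pixel_size, z_spacing = pixel_size * step, z_spacing * step
    voxels = np.argwhere(mask)
    if len(voxels) == 0:
        raise MeshingError("empty 3D mask")
    spac = np.array([pixel_size, pixel_size, z_spacing])  # x, y, z
    corner_ids: dict[tuple, int] = {}
    nodes = []

    def node(iz, iy, ix):
        key = (iz, iy, ix)
        if key not in corner_ids:
            corner_ids[key] = len(nodes)
            nodes.append(np.array([ix, iy, iz]) * spac)
        return corner_ids[key]

    tets = []
    for iz, iy, ix in voxels:
        for path in _KUHN_PATHS:
            offs = np.zeros((4, 3), dtype=int)
            for k, axis in enumerate(path):
                offs[k + 1] = offs[k]
                offs[k + 1, axis] += 1
            tets.append(
                [node(iz + o[2], iy + o[1], ix + o[0]) for o in offs]
            )
    return _finalise_mesh(np.asarray(nodes, float), np.asarray(tets, int), pixel_size)


# ---------------------------------------------------------------------------
# Reference meshes for verification studies
# ---------------------------------------------------------------------------

def rectangle_mesh(
    width: float,
    height: float,
    nx: int,
    ny: int,
    origin: tuple[float, float] = (0.0, 0.0),
) -> FEMesh:
    """Structured criss-cross triangulation of a rectangle."""
    x = np.linspace(origin[0], origin[0] + width, nx + 1)
    y = np.linspace(origin[1], origin[1] + height, ny + 1)
    X, Y = np.meshgrid(x, y, indexing="xy")
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(i, j):
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    return _finalise_mesh(nodes, np.asarray(tris), max(width / nx, height / ny))


def disk_mesh(radius: float, target_edge_length: float, center=(0.0, 0.0)) -> FEMesh:
    """Unstructured triangulation of a disk."""
    n = max(16, int(round(2 * np.pi * radius / target_edge_length)))
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    boundary = np.stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)], axis=1
    )
    return mesh_polygon(boundary, target_edge_length)
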