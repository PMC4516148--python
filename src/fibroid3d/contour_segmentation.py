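"""Semi-automatic segmentation from operator-traced key-slice contours.

The operator traces closed curves around each structure on a sparse set of
key slices.  Slices in between are reconstructed by shape-based
interpolation: the signed Euclidean distance field of each neighboring
key-slice mask is blended linearly with the slice position and thresholded
at zero, which smoothly deforms one contour into the next.  A final
correction pass enforces 3D consistency (largest connected component for
body and endometrium, a minimum component size for fibroids, and
endometrium nested inside the body), removing false-positive voxels without
ever adding any.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon

from .volume_io import BODY, ENDOMETRIUM, FIBROID, LabelMap, Volume3D

#: voxels are painted in this order, so later labels win where structures overlap
LABEL_PRIORITY = (BODY, ENDOMETRIUM, FIBROID)


class ContourValidationError(ValueError):
    """Contour is not a valid simple closed polygon."""


class InterpolationError(ValueError):
    """Interpolation endpoints are unusable (both masks empty)."""


@dataclass
class Contour:
    """A closed planar polygon on one slice of one structure.

    ``vertices_mm`` is an ordered (N, 2) array of in-plane (x, y) world
    coordinates; closure is implicit (first vertex is not repeated) and the
    stored orientation is counterclockwise.
    """

    structure: int
    slice_index: int
    vertices_mm: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_mm, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ContourValidationError(f"vertices must be (N, 2), got {v.shape}")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]  # closure is implicit
        if len(v) < 3:
            raise ContourValidationError(f"a closed contour needs >= 3 vertices, got {len(v)}")
        poly = ShapelyPolygon(v)
        if not poly.is_valid or poly.area == 0:
            raise ContourValidationError(
                f"contour on slice {self.slice_index} is self-intersecting or degenerate"
            )
        if not poly.exterior.is_ccw:
            v = v[::-1].copy()
        self.vertices_mm = v

    @property
    def polygon(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.vertices_mm)


@dataclass
class KeySliceSet:
    """Contours grouped by structure, sorted by slice; multi-part slices allowed.

    ``empty_slices`` records key slices the operator inspected and found
    empty for a structure (a multi-part structure may vanish between two
    of its parts); propagation tapers against them instead of bridging
    the gap.
    """

    contours_by_structure: dict[int, list[Contour]] = field(default_factory=dict)
    empty_slices: dict[int, set[int]] = field(default_factory=dict)

    @classmethod
    def from_contours(
        cls,
        contours: Iterable[Contour],
        empty_slices: dict[int, set[int]] | None = None,
    ) -> "KeySliceSet":
        grouped: dict[int, list[Contour]] = {}
        for c in contours:
            grouped.setdefault(c.structure, []).append(c)
        for cs in grouped.values():
            cs.sort(key=lambda c: c.slice_index)
        return cls(grouped, {s: set(ks) for s, ks in (empty_slices or {}).items()})

    def structures(self) -> list[int]:
        return sorted(self.contours_by_structure)

    def key_slices(self, structure: int) -> list[int]:
        traced = {c.slice_index for c in self.contours_by_structure.get(structure, [])}
        return sorted(traced | self.empty_slices.get(structure, set()))

    def slice_contours(self, structure: int, k: int) -> list[Contour]:
        return [c for c in self.contours_by_structure.get(structure, []) if c.slice_index == k]

    def all_contours(self) -> list[Contour]:
        return [c for cs in self.contours_by_structure.values() for c in cs]


def rasterize_contour(
    contour: Contour,
    shape2d: tuple[int, int],
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """Rasterize a contour on the in-plane grid: a voxel belongs to the
    interior iff its center is inside the polygon (even-odd rule), with
    centers falling exactly on the boundary counted as interior."""
    ni, nj = shape2d
    sx, sy = float(spacing[0]), float(spacing[1])
    ox, oy = float(origin[0]), float(origin[1])
    xs = ox + np.arange(ni) * sx
    ys = oy + np.arange(nj) * sy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    path = MplPath(contour.vertices_mm)  # contains_points treats the path as closed
    # boundary ties resolved as interior: a point on the edge is reported
    # inside for one sign of the radius nudge (which sign depends on the
    # winding), so take the union of both
    eps = 1e-9 * max(sx, sy)
    inside = path.contains_points(pts, radius=eps) | path.contains_points(pts, radius=-eps)
    return inside.reshape(ni, nj)


def rasterize_slice(
    contours: Sequence[Contour],
    shape2d: tuple[int, int],
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """Union of the rasterizations of several (multi-part) contours."""
    mask = np.zeros(shape2d, dtype=bool)
    for c in contours:
        mask |= rasterize_contour(c, shape2d, spacing, origin)
    return mask


def signed_distance(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Signed Euclidean distance field in mm: negative inside, positive outside."""
    spacing = tuple(float(s) for s in spacing)
    if not mask.any():
        # uniformly positive field at the scale of one voxel
        return np.full(mask.shape, max(spacing))
    if mask.all():
        return np.full(mask.shape, -max(spacing))
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    return outside - inside


def interpolate_between(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    n_between: int,
    spacing: Sequence[float] = (1.0, 1.0),
) -> list[np.ndarray]:
    """Shape-based interpolation of ``n_between`` masks strictly between two
    key-slice masks.

    The signed distance fields of the endpoints are blended linearly with
    slice position and thresholded at zero (<= 0 is interior).  An empty
    endpoint is represented by a uniformly positive field so the structure
    tapers away toward it.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("endpoint masks must share a grid")
    if not mask_a.any() and not mask_b.any():
        raise InterpolationError("both endpoint masks are empty; nothing to interpolate")
    if n_between < 1:
        return []
    sdf_a = signed_distance(mask_a, spacing)
    sdf_b = signed_distance(mask_b, spacing)
    # an empty endpoint becomes a uniformly positive field scaled so the
    # structure tapers smoothly: deep enough to shrink every intermediate
    # slice, shallow enough that the slice next to the occupied key slice
    # is still non-empty
    if not mask_a.any():
        depth = max(-float(sdf_b.min()), max(spacing))
        sdf_a = np.full(mask_a.shape, depth / (n_between + 1))
    elif not mask_b.any():
        depth = max(-float(sdf_a.min()), max(spacing))
        sdf_b = np.full(mask_b.shape, depth / (n_between + 1))
    out = []
    for m in range(1, n_between + 1):
        w = m / (n_between + 1)
        out.append((1.0 - w) * sdf_a + w * sdf_b <= 0.0)
    return out


def propagate_segmentation(
    keyset: KeySliceSet,
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> LabelMap:
    """Rasterize key slices and propagate contours through the stack.

    Key slices reproduce their manual contours exactly; every slice strictly
    between two consecutive key slices of a structure is filled by
    :func:`interpolate_between`; slices beyond a structure's first/last key
    slice stay empty for it.  Overlaps resolve by label priority
    fibroid > endometrium > body.
    """
    ni, nj, nk = shape
    in_plane = (float(spacing[0]), float(spacing[1]))
    in_origin = (float(origin[0]), float(origin[1]))
    labels = np.zeros(shape, dtype=np.int16)
    for structure in LABEL_PRIORITY:  # paint in priority order, later wins
        key_slices = keyset.key_slices(structure)
        if not key_slices:
            continue
        if key_slices[0] < 0 or key_slices[-1] >= nk:
            raise IndexError(
                f"key slices {key_slices[0]}..{key_slices[-1]} outside stack of {nk} slices"
            )
        masks: dict[int, np.ndarray] = {
            k: rasterize_slice(keyset.slice_contours(structure, k), (ni, nj), in_plane, in_origin)
            for k in key_slices
        }
        for ka, kb in zip(key_slices[:-1], key_slices[1:]):
            gap = kb - ka - 1
            if gap < 1:
                continue
            if masks[ka].any() or masks[kb].any():
                between = interpolate_between(masks[ka], masks[kb], gap, in_plane)
            else:
                between = [np.zeros((ni, nj), dtype=bool)] * gap
            for offset, m in enumerate(between, start=1):
                masks[ka + offset] = m
        for k, m in masks.items():
            labels[:, :, k][m] = structure
    return LabelMap(labels, tuple(float(s) for s in spacing), tuple(float(o) for o in origin))


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def cross_plane_correct(
    labelmap: LabelMap,
    volume: Volume3D | None = None,
    min_fibroid_voxels: int = 5,
) -> LabelMap:
    """Validation/correction pass over the propagated segmentation.

    Realizes the cross-direction false-positive removal as 3D geometric
    consistency rules: body and endometrium keep only their largest
    26-connected component, fibroids keep every component of at least
    ``min_fibroid_voxels`` voxels, and endometrium voxels outside the
    body's filled interior are discarded.  The result is always a voxelwise
    subset of the input.  ``volume`` is accepted for interface symmetry;
    the rules are purely geometric.
    """
    labels = labelmap.labels.copy()

    for structure in (BODY, ENDOMETRIUM):
        mask = labels == structure
        if not mask.any():
            continue
        comp, n = ndimage.label(mask, structure=_CONN26)
        if n > 1:
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            labels[mask & (comp != keep)] = 0

    fib = labels == FIBROID
    if fib.any():
        comp, n = ndimage.label(fib, structure=_CONN26)
        sizes = ndimage.sum_labels(fib, comp, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_fibroid_voxels) + 1
        if small.size:
            labels[np.isin(comp, small)] = 0

    # nesting: the endometrial cavity lies within the uterine body.  The
    # body's "filled interior" includes cavities carved out of label 1 by
    # the nested structures themselves.
    endo = labels == ENDOMETRIUM
    if endo.any():
        body_filled = ndimage.binary_fill_holes(labels == BODY)
        labels[endo & ~body_filled] = 0

    return LabelMap(labels, labelmap.spacing, labelmap.origin)


def trace_slice_contours(
    mask2d: np.ndarray,
    structure: int,
    slice_index: int,
    spacing: Sequence[float],
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Contour]:
    """Extract closed contours around each blob of a 2D mask (sub-voxel,
    via the 0.5 iso-contour of the binary image), optionally perturbed by
    smooth radial jitter to emulate hand tracing."""
    from skimage import measure

    contours = []
    for poly in measure.find_contours(mask2d.astype(float), 0.5):
        if len(poly) < 4 or not np.allclose(poly[0], poly[-1]):
            continue  # open contour clipped by the image border; ignore
        verts = poly[:-1]
        xy = np.column_stack(
            [
                verts[:, 0] * spacing[0] + origin[0],
                verts[:, 1] * spacing[1] + origin[1],
            ]
        )
        if jitter > 0:
            if rng is None:
                rng = np.random.default_rng()
            xy = _radial_jitter(xy, jitter, rng)
        try:
            contours.append(Contour(structure, slice_index, xy))
        except ContourValidationError:
            continue  # sub-voxel blob too small to form a polygon
    return contours


def _radial_jitter(xy: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb vertices radially about the centroid with smooth noise.

    ``amplitude`` is the approximate peak boundary displacement in mm (the
    smoothed noise is scaled to two standard deviations).  Radial
    perturbation keeps star-shaped contours simple (no self-intersections)
    as long as the perturbed radius stays positive.
    """
    centroid = xy.mean(axis=0)
    rel = xy - centroid
    r = np.linalg.norm(rel, axis=1)
    noise = rng.normal(0.0, 1.0, size=len(xy))
    # circularly smooth the noise so neighboring vertices move together
    kernel = np.exp(-0.5 * (np.arange(-5, 6) / 2.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(np.tile(noise, 3), kernel, mode="same")[len(xy) : 2 * len(xy)]
    scale = amplitude / max(2.0 * np.std(smooth), 1e-12)
    new_r = np.maximum(r + smooth * scale, 0.1 * r)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-12)[:, None], 0.0)
    return centroid + unit * new_r[:, None]


# ---------------------------------------------------------------------------
# JSON exchange format: {"contours": [{structure, slice_index, vertices_mm}]}

def save_contours(keyset: KeySliceSet, path: str | os.PathLike) -> None:
    payload = {
        "contours": [
            {
                "structure": int(c.structure),
                "slice_index": int(c.slice_index),
                "vertices_mm": np.asarray(c.vertices_mm).tolist(),
            }
            for c in keyset.all_contours()
        ],
        "empty_slices": {
            str(s): sorted(int(k) for k in ks) for s, ks in keyset.empty_slices.items() if ks
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_contours(path: str | os.PathLike) -> KeySliceSet:
    payload = json.loads(Path(path).read_text())
    contours = [
        Contour(int(c["structure"]), int(c["slice_index"]), np.asarray(c["vertices_mm"]))
        for c in payload["contours"]
    ]
    empty = {int(s): set(ks) for s, ks in payload.get("empty_slices", {}).items()}
    return KeySliceSet.from_contours(contours, empty)
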