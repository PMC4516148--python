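"""Synthetic sagittal T2-like pelvic MR phantoms with known ground truth.

The phantom emulates the appearance of a 3D T2-weighted sagittal stack of a
fibroid uterus: an ellipsoidal uterine body of intermediate signal, a
hyperintense endometrial cavity nested inside it, and hypointense spherical
fibroids whose placement realizes one of the three anatomical types —
intramural (within the myometrial wall), subserosal (protruding beyond the
outer surface) or submucosal (reaching into the endometrial cavity).
Intensities get additive seeded Gaussian noise.  Fibroid voxels take
priority over endometrium, which takes priority over body, so each fibroid
is a distinct solid in the label map.

Defaults emulate a desk-scale crop of a clinical acquisition: 2 mm section
thickness along the slice axis, a uterus of roughly 8 x 5 x 6 cm, and a
case with three intramural fibroids plus one subserosal fibroid (the
commonest per-case pattern in fibroid series, where intramural lesions
dominate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import BODY, ENDOMETRIUM, FIBROID, LabelMap, Volume3D

FibroidType = Literal["intramural", "subserosal", "submucosal"]
FIBROID_TYPES = ("intramural", "subserosal", "submucosal")


class PhantomConfigError(ValueError):
    """Phantom configuration is geometrically inconsistent."""


@dataclass(frozen=True)
class FibroidSpec:
    """A spherical fibroid: center (mm), radius (mm) and intended type."""

    center: tuple[float, float, float]
    radius: float
    kind: FibroidType

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise PhantomConfigError(f"fibroid radius must be positive, got {self.radius}")
        if self.kind not in FIBROID_TYPES:
            raise PhantomConfigError(f"unknown fibroid type {self.kind!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic uterine phantom.

    Geometry is in mm; the body and endometrium are axis-aligned ellipsoids
    sharing a center, fibroids are spheres.  ``intensity_*`` are the noise-free
    mean signals (arbitrary units, T2-like ordering endometrium > body >
    fibroid); ``noise_sd`` is the standard deviation of additive Gaussian
    noise.  Identical configs (including ``seed``) generate bit-identical
    phantoms.
    """

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.0)
    body_center: tuple[float, float, float] | None = None  # default: grid center
    body_semiaxes: tuple[float, float, float] = (40.0, 25.0, 30.0)
    endo_semiaxes: tuple[float, float, float] = (16.0, 6.0, 10.0)
    fibroids: tuple[FibroidSpec, ...] = (
        FibroidSpec((-22.0, 6.0, 9.0), 8.0, "intramural"),
        FibroidSpec((16.0, -9.0, -11.0), 7.0, "intramural"),
        FibroidSpec((10.0, 10.0, 12.0), 5.0, "intramural"),
        FibroidSpec((-5.0, -24.0, 5.0), 9.0, "subserosal"),
    )
    intensity_background: float = 20.0
    intensity_body: float = 110.0
    intensity_endometrium: float = 230.0
    intensity_fibroid: float = 45.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise PhantomConfigError(f"degenerate shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomConfigError(f"non-positive spacing {self.spacing}")
        if any(e <= 0 for e in self.body_semiaxes + self.endo_semiaxes):
            raise PhantomConfigError("ellipsoid semi-axes must be positive")
        if not all(e < b for e, b in zip(self.endo_semiaxes, self.body_semiaxes)):
            raise PhantomConfigError(
                "endometrium ellipsoid must be strictly inside the body ellipsoid"
            )
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be non-negative")
        object.__setattr__(self, "fibroids", tuple(self.fibroids))

    @property
    def center_mm(self) -> np.ndarray:
        if self.body_center is not None:
            return np.asarray(self.body_center, dtype=float)
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)


@dataclass
class FibroidTruth:
    """Ground-truth record of one generated fibroid."""

    id: int
    center: tuple[float, float, float]
    radius: float
    kind: FibroidType


@dataclass
class PhantomTruth:
    """Ground-truth label map plus per-fibroid records."""

    labelmap: LabelMap
    fibroids: list[FibroidTruth]


def _coordinate_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grids, center, semiaxes) -> np.ndarray:
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _sphere_mask(grids, center, radius) -> np.ndarray:
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return q <= radius**2


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def generate_phantom(config: PhantomConfig) -> tuple[Volume3D, PhantomTruth]:
    """Voxelize the phantom and return the noisy volume plus its ground truth.

    Raises :class:`PhantomConfigError` when a fibroid's voxelized geometry
    contradicts its intended type (an "intramural" sphere poking through the
    serosa, say), when fibroid components merge, or when the endometrium is
    not strictly interior to the body.
    """
    grids = _coordinate_grids(config.shape, config.spacing)
    center = config.center_mm
    body = _ellipsoid_mask(grids, center, config.body_semiaxes)
    endo = _ellipsoid_mask(grids, center, config.endo_semiaxes)

    # strict nesting at voxel level: endometrium may not touch the serosa
    interior = ndimage.binary_erosion(body, iterations=1)
    if not np.all(endo <= interior):
        raise PhantomConfigError("endometrium touches or exceeds the body boundary")

    fibroid_mask = np.zeros(config.shape, dtype=bool)
    records: list[FibroidTruth] = []
    for idx, spec in enumerate(config.fibroids, start=1):
        # fibroid centers are given relative to the body center
        fmask = _sphere_mask(grids, center + np.asarray(spec.center, float), spec.radius)
        if not fmask.any():
            raise PhantomConfigError(f"fibroid {idx} voxelizes to nothing")
        _check_intended_type(fmask, spec, idx, body, endo)
        fibroid_mask |= fmask
        abs_center = tuple(float(c) for c in center + np.asarray(spec.center, float))
        records.append(FibroidTruth(idx, abs_center, spec.radius, spec.kind))

    n_components = ndimage.label(fibroid_mask, structure=_CONN26)[1]
    if n_components != len(config.fibroids):
        raise PhantomConfigError(
            f"{len(config.fibroids)} fibroids voxelize to {n_components} connected "
            "components; fibroids must not touch each other"
        )

    labels = np.zeros(config.shape, dtype=np.int16)
    labels[body] = BODY
    labels[endo] = ENDOMETRIUM
    labels[fibroid_mask] = FIBROID  # priority: fibroid > endometrium > body

    intensity = np.full(config.shape, config.intensity_background)
    intensity[labels == BODY] = config.intensity_body
    intensity[labels == ENDOMETRIUM] = config.intensity_endometrium
    intensity[labels == FIBROID] = config.intensity_fibroid
    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=config.shape)

    volume = Volume3D(intensity, config.spacing)
    truth = PhantomTruth(LabelMap(labels, config.spacing), records)
    return volume, truth


def _check_intended_type(fmask, spec, idx, body, endo) -> None:
    touches_endo = bool((fmask & endo).any())
    outside_body = bool((fmask & ~body).any())
    if spec.kind == "submucosal":
        if not touches_endo:
            raise PhantomConfigError(
                f"fibroid {idx} declared submucosal but does not reach the endometrium"
            )
    elif spec.kind == "subserosal":
        if not outside_body:
            raise PhantomConfigError(
                f"fibroid {idx} declared subserosal but does not extend outside the body"
            )
        if touches_endo:
            raise PhantomConfigError(f"fibroid {idx} declared subserosal but reaches the cavity")
    else:  # intramural
        if touches_endo or outside_body:
            raise PhantomConfigError(
                f"fibroid {idx} declared intramural but is not strictly within the wall"
            )


def ellipsoid_surface_distance(point, semiaxes) -> tuple[bool, float]:
    """Euclidean distance from a point to an origin-centered, axis-aligned
    ellipsoid surface, plus whether the point lies inside.

    Uses the standard nearest-point parametrization x_i = a_i^2 p_i /
    (t + a_i^2): the largest root t of  sum (a_i p_i / (t + a_i^2))^2 = 1
    gives the closest surface point; solved by bisection (the left side is
    strictly decreasing in t).
    """
    p = np.asarray(point, dtype=float)
    a = np.asarray(semiaxes, dtype=float)
    q = float(np.sqrt(np.sum((p / a) ** 2)))
    inside = q < 1.0
    if q == 0.0:
        return True, float(a.min())

    def g(t: float) -> float:
        return float(np.sum((a * p / (t + a**2)) ** 2)) - 1.0

    lo = -float(a.min() ** 2)
    lo += 1e-9 * float(a.min() ** 2)
    hi = float(np.linalg.norm(a * p))  # g(hi) <= 0 since each term <= (a p / (a p))...
    while g(hi) > 0:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    x = a**2 * p / (t + a**2)
    return inside, float(np.linalg.norm(p - x))


def sample_fibroid_specs(
    rng: np.random.Generator,
    config: PhantomConfig,
    n_intramural: int = 3,
    n_subserosal: int = 2,
    n_submucosal: int = 1,
    radius_range: tuple[float, float] = (5.0, 9.0),
    margin: float = 3.0,
    max_tries: int = 5000,
) -> tuple[FibroidSpec, ...]:
    """Randomly place non-touching fibroids that conform to their intended type.

    Candidate centers are proposed along random rays from the body center
    and accepted only when the true Euclidean clearances to the serosa and
    cavity surfaces satisfy the intended type with ``margin`` mm to spare:
    intramural spheres keep ``margin`` clear of both surfaces; subserosal
    spheres protrude through the serosa by 0.5-0.8 of their radius (so
    well over 10% of their volume is exterior) while staying clear of the
    cavity; submucosal spheres penetrate the cavity wall by at least
    ``margin`` while staying clear of the serosa.  Centers are returned
    relative to the body center, ready to drop into :class:`PhantomConfig`.
    """
    body = np.asarray(config.body_semiaxes)
    endo = np.asarray(config.endo_semiaxes)
    placed: list[FibroidSpec] = []
    wanted = (
        ["submucosal"] * n_submucosal
        + ["subserosal"] * n_subserosal
        + ["intramural"] * n_intramural
    )
    for kind in wanted:
        for _ in range(max_tries):
            radius = float(rng.uniform(*radius_range))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            # proposal band: distance to the ellipsoid surfaces along the ray
            t_body = 1.0 / np.sqrt(np.sum((direction / body) ** 2))
            t_endo = 1.0 / np.sqrt(np.sum((direction / endo) ** 2))
            if kind == "intramural":
                lo, hi = t_endo + radius + margin, t_body - radius - margin
            elif kind == "subserosal":
                lo, hi = t_body - 0.5 * radius, t_body - 0.2 * radius
            else:
                # center in the wall, margin..radius-margin beyond the cavity
                lo, hi = t_endo + margin, t_endo + radius - margin
            if hi <= lo or lo < 0:
                continue
            dist = float(rng.uniform(lo, hi))
            center = direction * dist
            in_body, d_body = ellipsoid_surface_distance(center, body)
            in_endo, d_endo = ellipsoid_surface_distance(center, endo)
            if kind == "intramural":
                ok = (
                    in_body and not in_endo
                    and d_body >= radius + margin
                    and d_endo >= radius + margin
                )
            elif kind == "subserosal":
                # center inside, 0.2-0.5 radii below the serosa: the sphere
                # protrudes by a tangent-plane cap of height >= 0.5 radius
                ok = (
                    in_body and not in_endo
                    and 0.2 * radius <= d_body <= 0.5 * radius
                    and d_endo >= radius + margin
                )
            else:  # submucosal: dips into the cavity, stays off the serosa
                ok = (
                    in_body and not in_endo
                    and margin <= radius - d_endo <= radius - margin
                    and d_body >= radius + margin
                )
            if not ok:
                continue
            spec = FibroidSpec(tuple(float(c) for c in center), radius, kind)  # type: ignore[arg-type]
            if _clear_of_others(spec, placed) and _inside_grid(spec, config):
                placed.append(spec)
                break
        else:
            raise PhantomConfigError(f"could not place a conforming {kind} fibroid")
    return tuple(placed)


def _clear_of_others(spec: FibroidSpec, others: Sequence[FibroidSpec], gap: float = 3.0) -> bool:
    c = np.asarray(spec.center)
    return all(
        np.linalg.norm(c - np.asarray(o.center)) > spec.radius + o.radius + gap for o in others
    )


def _inside_grid(spec: FibroidSpec, config: PhantomConfig) -> bool:
    center = config.center_mm + np.asarray(spec.center)
    extent = (np.asarray(config.shape) - 1) * np.asarray(config.spacing)
    return bool(np.all(center - spec.radius >= 0) and np.all(center + spec.radius <= extent))


def simulate_key_slice_tracing(
    truth: PhantomTruth,
    slice_step: int,
    jitter: float = 0.0,
    seed: int = 0,
):
    """Simulate an operator tracing closed contours on sparse key slices.

    For every structure present in ``truth``, contours are extracted on
    slices ``k = k_min, k_min + step, ...`` plus the last slice containing
    the structure.  Body and endometrium cross-sections are traced as their
    filled outlines (an operator outlines the organ, not the label holes
    that nested structures carve out); fibroid components are traced
    individually.  ``jitter`` adds smooth, seeded radial noise (mm) to the
    vertices, emulating imperfect manual tracing; with ``jitter=0`` the
    contours rasterize back to the truth slices exactly.
    """
    from .contour_segmentation import KeySliceSet, trace_slice_contours

    if slice_step < 1:
        raise ValueError("slice_step must be >= 1")
    rng = np.random.default_rng(seed)
    labels = truth.labelmap.labels
    spacing = truth.labelmap.spacing
    origin = truth.labelmap.origin
    contours = []
    empty_slices: dict[int, set[int]] = {}
    for structure in (BODY, ENDOMETRIUM, FIBROID):
        occupied = np.flatnonzero((labels == structure).any(axis=(0, 1)))
        if occupied.size == 0:
            continue
        key_slices = sorted(set(range(occupied[0], occupied[-1] + 1, slice_step)) | {occupied[-1]})
        for k in key_slices:
            mask2d = labels[:, :, k] == structure
            if structure in (BODY, ENDOMETRIUM):
                mask2d = ndimage.binary_fill_holes(mask2d)
            if not mask2d.any():
                # a multi-part structure can vanish between its parts; the
                # operator records the slice as inspected-and-empty so
                # propagation tapers instead of bridging the gap
                empty_slices.setdefault(structure, set()).add(int(k))
                continue
            contours.extend(
                trace_slice_contours(mask2d, structure, k, spacing, origin, jitter=jitter, rng=rng)
            )
    return KeySliceSet.from_contours(contours, empty_slices)
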