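"""Domain types and spatial primitives shared by the simulator and the fitter.

Coordinates are planar metres throughout (projected frame; no geographic CRS
handling).  Areas are carried in km² and densities are reported per 100 km²;
the conversion lives in :func:`density_per_100km2` so that no other module
hard-codes unit factors.

The detection model is the classic two-parameter half-normal for binary
proximity detectors: an animal with activity centre at distance ``d`` from a
detector is detected there on any one occasion with probability
``g(d) = g0 * exp(-d² / (2 σ²))``, where ``g0`` is the detection probability
at distance zero and ``σ`` (metres) is the spatial scale of the decline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "DetectionParams",
    "Detector",
    "DetectorArray",
    "HabitatMask",
    "CaptureData",
    "half_normal_g",
    "p_dot",
    "build_mask",
    "density_per_100km2",
]


def density_per_100km2(n: float, area_km2: float) -> float:
    """Convert a count over an area in km² to a density per 100 km²."""
    return 100.0 * n / area_km2


@dataclass(frozen=True)
class DetectionParams:
    """Half-normal detection parameters.

    Attributes
    ----------
    g0 : float
        Per-occasion detection probability for a detector at the animal's
        activity centre, in (0, 1).
    sigma : float
        Spatial scale of the half-normal decline, in metres (> 0).
    """

    g0: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.g0 < 1.0):
            raise ValueError(f"g0 must be in (0, 1), got {self.g0}")
        if not (self.sigma > 0.0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")

    def to_link(self) -> np.ndarray:
        """Return ``[logit(g0), log(sigma)]``, the unconstrained link scale."""
        return np.array([logit(self.g0), math.log(self.sigma)])

    @classmethod
    def from_link(cls, theta: np.ndarray) -> "DetectionParams":
        """Inverse of :meth:`to_link`."""
        return cls(g0=float(expit(theta[0])), sigma=float(math.exp(theta[1])))


@dataclass(frozen=True)
class Detector:
    """One detector (trap) with planar coordinates in metres."""

    id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"detector {self.id}: coordinates must be finite")


@dataclass(frozen=True)
class DetectorArray:
    """A replicate array of proximity detectors: the sampling unit j.

    ``n_occasions`` is the number of sampling occasions S shared by all
    detectors of the array.
    """

    array_id: str
    detectors: tuple[Detector, ...]
    n_occasions: int

    def __post_init__(self) -> None:
        if len(self.detectors) < 2:
            raise ValueError("an array needs at least 2 detectors")
        ids = [d.id for d in self.detectors]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate detector ids in array {self.array_id}")
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be a positive integer")

    @property
    def n_detectors(self) -> int:
        return len(self.detectors)

    @property
    def coords(self) -> np.ndarray:
        """(K, 2) array of detector coordinates in metres."""
        return np.array([(d.x, d.y) for d in self.detectors])

    def spacing(self) -> float:
        """Minimum nearest-neighbour distance between detectors, metres."""
        xy = self.coords
        d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        return float(np.sqrt(d2.min()))


@dataclass(frozen=True)
class HabitatMask:
    """Discretised region of integration around one array.

    ``cell_centers`` are the centres of equal-sized square grid cells
    (metres); ``cell_area`` is the common cell area in km²; ``buffer_m``
    records the buffer width used to build the mask.
    """

    cell_centers: np.ndarray  # (n_cells, 2), metres
    cell_area: float  # km²
    buffer_m: float

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if len(self.cell_centers) == 0:
            raise ValueError("mask has no cells")

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    @property
    def total_area(self) -> float:
        """Total mask area in km²."""
        return self.n_cells * self.cell_area


@dataclass(frozen=True)
class CaptureData:
    """Binary detection histories ω for one array.

    ``omega`` has shape (n individuals, S occasions, K detectors) with
    entries in {0, 1}; a proximity detector records an individual at most
    once per occasion, so entries are binary by construction.
    """

    array_id: str
    individuals: tuple[str, ...]
    omega: np.ndarray

    def __post_init__(self) -> None:
        om = np.asarray(self.omega)
        if om.ndim != 3:
            raise ValueError("omega must be (individuals, occasions, detectors)")
        if om.shape[0] != len(self.individuals):
            raise ValueError("omega first axis must match individuals")
        if not np.isin(om, (0, 1)).all():
            raise ValueError("omega must be binary")
        if om.shape[0] and (om.sum(axis=(1, 2)) == 0).any():
            raise ValueError("every individual must have at least one detection")

    @property
    def n(self) -> int:
        """Number of detected individuals."""
        return len(self.individuals)

    @property
    def n_detections(self) -> int:
        """Total detection events."""
        return int(self.omega.sum())

    @property
    def n_recaptures(self) -> int:
        """Detection events beyond each individual's first."""
        return self.n_detections - self.n

    @property
    def n_spatial_recaptures(self) -> int:
        """Recaptures at a detector different from the preceding detection.

        Detection events are ordered by occasion (detector index within an
        occasion); each successive event whose detector differs from the
        previous one counts as a movement, i.e. a spatial recapture.
        """
        total = 0
        for i in range(self.n):
            occ, det = np.nonzero(self.omega[i])
            d_sorted = det[np.lexsort((det, occ))]
            total += int(np.sum(d_sorted[1:] != d_sorted[:-1]))
        return total

    def detector_counts(self) -> np.ndarray:
        """(n, K) matrix of per-detector detection counts over occasions."""
        return self.omega.sum(axis=1)


def half_normal_g(d, params: DetectionParams):
    """Half-normal detection probability at distance ``d`` (metres).

    Accepts scalars or arrays; raises on negative distances.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = params.g0 * np.exp(-(d**2) / (2.0 * params.sigma**2))
    return float(out) if out.ndim == 0 else out


def _distances(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """(n_points, K) Euclidean distance matrix in metres."""
    diff = points[:, None, :] - coords[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def p_dot(x, array: DetectorArray, params: DetectionParams):
    """Probability of at least one detection anywhere on the array.

    For occasion-constant parameters,
    ``p·(x) = 1 − ∏_k (1 − g(d_k(x)))^S``.  ``x`` may be one point
    ``(x, y)`` or an (n, 2) array of points.
    """
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    d = _distances(pts, array.coords)
    log_surv = np.log1p(-half_normal_g(d, params)).sum(axis=1)
    out = -np.expm1(array.n_occasions * log_surv)
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def build_mask(
    array: DetectorArray, buffer_m: float, cell_side_m: float
) -> HabitatMask:
    """Rasterise a union-of-discs buffer around the array's detectors.

    Cells are centres of a regular square grid of side ``cell_side_m``; a
    cell is included when its centre lies within ``buffer_m`` of any
    detector.  ``cell_area`` is reported in km².
    """
    if buffer_m <= 0 or cell_side_m <= 0:
        raise ValueError("buffer_m and cell_side_m must be positive")
    if buffer_m < cell_side_m:
        raise ValueError("buffer_m must be at least cell_side_m")
    xy = array.coords
    x0 = xy[:, 0].min() - buffer_m
    x1 = xy[:, 0].max() + buffer_m
    y0 = xy[:, 1].min() - buffer_m
    y1 = xy[:, 1].max() + buffer_m
    # Grid anchored at the lower-left corner; centres at half-cell offsets.
    nx = int(np.ceil((x1 - x0) / cell_side_m))
    ny = int(np.ceil((y1 - y0) / cell_side_m))
    gx = x0 + (np.arange(nx) + 0.5) * cell_side_m
    gy = y0 + (np.arange(ny) + 0.5) * cell_side_m
    xx, yy = np.meshgrid(gx, gy)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    d = _distances(centers, xy)
    keep = d.min(axis=1) <= buffer_m
    return HabitatMask(
        cell_centers=centers[keep],
        cell_area=(cell_side_m**2) / 1e6,
        buffer_m=buffer_m,
    )
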