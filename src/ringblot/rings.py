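"""Concentric-ring feature extraction for dot-blot spot photographs.

A spot crop is reduced to a short radial profile: the image is converted to
grayscale, a mask of concentric rings (square annuli under the Chebyshev
metric, circular under the Euclidean one) is centered on the spot, and the
mean pixel intensity of each ring is normalized to the outermost ring's
mean.  The mask center is refined around a nominal position by maximizing
the variance of the profile — a sharp, well-centered spot produces the
highest-contrast (least blurred) profile.

With the default 6 rings of 6 px thickness the mask spans 71 x 71 px;
at 45 um per pixel that is a 3.2 mm outer diameter with 270 um from ring
to ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateNormalizationError, MaskOutOfBoundsError

__all__ = [
    "RingMask",
    "RadialProfile",
    "CenterFit",
    "FeatureConfig",
    "to_grayscale",
    "build_ring_mask",
    "ring_profile",
    "refine_center",
    "extract_features",
    "physical_ring_pitch_um",
]

_METRICS = ("chebyshev", "euclidean")


@dataclass(frozen=True, eq=False)
class RingMask:
    """Pixel-offset -> ring-index assignment for concentric rings.

    ``ring_index`` is a square integer array over the window of half-width
    ``n_rings * thickness - 1``; entry -1 marks pixels outside the mask.
    A pixel at offset distance d belongs to ring floor(d / thickness) when
    that index is < n_rings.  Rings partition the masked region.
    """

    n_rings: int
    thickness: int
    metric: str
    ring_index: np.ndarray

    @property
    def half_width(self) -> int:
        return self.n_rings * self.thickness - 1

    @property
    def span(self) -> int:
        """Side length (px) of the window the mask occupies."""
        return 2 * self.half_width + 1

    def ring_pixels(self, k: int) -> np.ndarray:
        """Boolean window mask of ring ``k``."""
        return self.ring_index == k

    def flat_indices(self) -> tuple[np.ndarray, ...]:
        """Row-major flat indices of each ring within the window."""
        flat = self.ring_index.ravel()
        return tuple(np.flatnonzero(flat == k) for k in range(self.n_rings))


def build_ring_mask(
    n_rings: int = 6, thickness: int = 6, metric: str = "chebyshev"
) -> RingMask:
    """Construct the ring mask for the given geometry.

    Under the Chebyshev metric ring 0 is the central (2*thickness - 1)^2
    block; each further ring is a square frame of the same thickness.
    """
    if n_rings < 1:
        raise ValueError(f"n_rings must be >= 1, got {n_rings}")
    if thickness < 1:
        raise ValueError(f"thickness must be >= 1, got {thickness}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    half = n_rings * thickness - 1
    offs = np.arange(-half, half + 1)
    dy = np.abs(offs)[:, None]
    dx = np.abs(offs)[None, :]
    if metric == "chebyshev":
        d = np.maximum(dy, dx).astype(float)
    else:
        d = np.hypot(dy, dx)
    idx = np.floor(d / thickness).astype(int)
    idx[d >= n_rings * thickness] = -1
    return RingMask(n_rings=n_rings, thickness=thickness, metric=metric, ring_index=idx)


@dataclass(frozen=True, eq=False)
class RadialProfile:
    """Normalized per-ring mean intensities, indexed center (0) to edge.

    The outermost element is exactly 1 when normalized; ``variance_score``
    is the population variance of ``values`` and serves as the contrast
    objective for center refinement.
    """

    values: np.ndarray
    center: tuple[int, int]
    variance_score: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CenterFit:
    """Result of the variance-maximizing center search."""

    refined_center: tuple[int, int]
    nominal_center: tuple[int, int]
    offset: tuple[int, int]
    score: float
    search_radius: int
    search_step: int


def to_grayscale(image: np.ndarray, weights: tuple[float, ...] | None = None) -> np.ndarray:
    """Reduce an RGB image to one channel by a weighted channel mean.

    Weights default to the unweighted mean (1/3, 1/3, 1/3) and are
    normalized to sum to 1 so the output range matches the input range.
    Single-channel input is passed through unchanged.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] == 1:
        return arr[..., 0]
    if arr.ndim == 3 and arr.shape[-1] == 3:
        w = np.asarray(weights if weights is not None else (1.0, 1.0, 1.0), dtype=float)
        if w.shape != (3,) or w.sum() <= 0:
            raise ValueError("grayscale weights must be 3 non-negative values with positive sum")
        w = w / w.sum()
        return arr @ w
    raise ValueError(f"expected 1 or 3 channels, got array of shape {arr.shape}")


def _check_bounds(shape: tuple[int, ...], center: tuple[int, int], mask: RingMask) -> None:
    cy, cx = center
    h = mask.half_width
    if cy - h < 0 or cx - h < 0 or cy + h >= shape[0] or cx + h >= shape[1]:
        raise MaskOutOfBoundsError(
            f"outer ring {mask.n_rings - 1} of mask (half-width {h}) at center "
            f"({cy}, {cx}) leaves an image of shape {shape[:2]}"
        )


def ring_profile(
    gray: np.ndarray,
    center: tuple[int, int],
    mask: RingMask,
    normalize: bool = True,
) -> RadialProfile:
    """Mean intensity of each ring at ``center``, normalized to the outer ring.

    ``values[k]`` is the mean over ring k divided by the mean over ring
    n_rings - 1 (the outer edge of the mask); indexing runs by distance
    from the common center, 0 (innermost) to n_rings - 1 (edge).
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("ring_profile expects a single-channel image")
    cy, cx = int(center[0]), int(center[1])
    if (cy, cx) != (center[0], center[1]):
        raise ValueError(f"center must have integer coordinates, got {center}")
    _check_bounds(gray.shape, (cy, cx), mask)
    h = mask.half_width
    window = gray[cy - h : cy + h + 1, cx - h : cx + h + 1]
    means = np.array(
        [float(np.mean(window[mask.ring_index == k])) for k in range(mask.n_rings)]
    )
    if normalize:
        outer = means[-1]
        if outer == 0.0:
            raise DegenerateNormalizationError(
                "outer-ring mean is zero; profile cannot be normalized"
            )
        means = means / outer
    return RadialProfile(values=means, center=(cy, cx), variance_score=float(np.var(means)))


def refine_center(
    gray: np.ndarray,
    nominal_center: tuple[int, int],
    mask: RingMask,
    search_radius: int = 5,
    search_step: int = 1,
    objective: str = "normalized",
) -> CenterFit:
    """Exhaustive grid search for the mask center maximizing profile variance.

    Candidates are the offsets {k * step : |k * step| <= radius}^2 around
    the nominal center (always including the nominal position itself).
    Ties are broken by the smallest Euclidean offset from nominal, then by
    row-major scan order.  The variance is computed on the normalized
    profile by default; set ``objective='raw'`` to score raw ring means.
    """
    if search_radius < 0:
        raise ValueError(f"search_radius must be >= 0, got {search_radius}")
    if search_step < 1:
        raise ValueError(f"search_step must be >= 1, got {search_step}")
    if objective not in ("normalized", "raw"):
        raise ValueError(f"objective must be 'normalized' or 'raw', got {objective!r}")
    cy, cx = int(nominal_center[0]), int(nominal_center[1])
    n_steps = search_radius // search_step
    offsets = [k * search_step for k in range(-n_steps, n_steps + 1)]
    if not offsets:
        raise ValueError("empty center search grid")
    # fail fast if any candidate would put the mask out of bounds
    _check_bounds(gray.shape, (cy + offsets[0], cx + offsets[0]), mask)
    _check_bounds(gray.shape, (cy + offsets[-1], cx + offsets[-1]), mask)

    normalize = objective == "normalized"
    best: tuple[float, int, tuple[int, int]] | None = None  # (score, -d2, offset)
    for dy in offsets:
        for dx in offsets:
            prof = ring_profile(gray, (cy + dy, cx + dx), mask, normalize=normalize)
            score = prof.variance_score
            d2 = dy * dy + dx * dx
            if best is None or score > best[0] or (score == best[0] and d2 < -best[1]):
                best = (score, -d2, (dy, dx))
    assert best is not None
    dy, dx = best[2]
    return CenterFit(
        refined_center=(cy + dy, cx + dx),
        nominal_center=(cy, cx),
        offset=(dy, dx),
        score=best[0],
        search_radius=search_radius,
        search_step=search_step,
    )


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the grayscale -> mask -> profile reduction."""

    n_rings: int = 6
    thickness: int = 6
    metric: str = "chebyshev"
    grayscale_weights: tuple[float, float, float] | None = None
    search_radius: int = 5
    search_step: int = 1
    objective: str = "normalized"

    def build_mask(self) -> RingMask:
        return build_ring_mask(self.n_rings, self.thickness, self.metric)


def extract_features(
    crop: np.ndarray,
    nominal_center: tuple[int, int] | None = None,
    config: FeatureConfig | None = None,
    mask: RingMask | None = None,
) -> RadialProfile:
    """Full reduction of a spot crop to its normalized radial profile.

    Composes grayscale conversion, center refinement and ring averaging;
    an RGB crop of ~(70 x 70) x 3 values collapses to a length-n_rings
    vector.  ``nominal_center`` defaults to the crop's central pixel.
    """
    config = config or FeatureConfig()
    gray = to_grayscale(crop, config.grayscale_weights)
    if mask is None:
        mask = config.build_mask()
    if nominal_center is None:
        nominal_center = ((gray.shape[0] - 1) // 2, (gray.shape[1] - 1) // 2)
    fit = refine_center(
        gray,
        nominal_center,
        mask,
        search_radius=config.search_radius,
        search_step=config.search_step,
        objective=config.objective,
    )
    return ring_profile(gray, fit.refined_center, mask, normalize=True)


def physical_ring_pitch_um(outer_diameter_mm: float, n_rings: int) -> float:
    """Ring-to-ring distance (um) of a mask with the given outer diameter."""
    if outer_diameter_mm <= 0 or n_rings < 1:
        raise ValueError("need positive diameter and at least one ring")
    return outer_diameter_mm * 1000.0 / (2.0 * n_rings)
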