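"""Synthetic dot-blot membrane generator.

Renders membrane photographs with the statistical structure of a
standardized dot-blot acquisition: a serial dilution of target DNA spotted
on a rectangular grid, each spot darkened by accumulated nanoparticle label
with coffee-ring morphology, imaged under slightly non-uniform illumination
with pixel noise.  Every spot carries a ground-truth center and a
concentration label (ppm), so downstream feature extraction and regression
can be exercised and validated without real photographs.

Conventions: images are float arrays in [0, 1] with shape (rows, cols, 3),
pixel coordinates are 0-based (row, col) with the origin at the top left.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CropBoundsError

__all__ = [
    "DilutionSeries",
    "SpotModel",
    "MembraneLayout",
    "SpotRecord",
    "SyntheticMembrane",
    "SpotCrop",
    "SimulationConfig",
    "build_dilution_series",
    "render_spot",
    "render_membrane",
    "generate_dataset",
]


@dataclass(frozen=True)
class DilutionSeries:
    """An ordered list of spotting concentrations (ppm) plus replicate count.

    ``concentrations`` holds the distinct levels, highest first, with the
    blank (0 ppm) last when present.  Each level is spotted ``replicates``
    times; ``randomized_order`` controls whether instances are shuffled
    before being assigned to grid positions.
    """

    concentrations: tuple[float, ...]
    replicates: int = 1
    randomized_order: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        nonzero = [c for c in self.concentrations if c > 0]
        if any(b >= a for a, b in zip(nonzero, nonzero[1:])):
            raise ValueError("nonzero concentrations must be strictly decreasing")
        if sum(1 for c in self.concentrations if c == 0) > 1:
            raise ValueError("at most one blank (0 ppm) level is allowed")

    @property
    def n_levels(self) -> int:
        return len(self.concentrations)

    @property
    def n_instances(self) -> int:
        return self.n_levels * self.replicates

    def instances(self) -> list[tuple[float, int]]:
        """Level-major list of (concentration, replicate_id) spot instances."""
        return [(c, r) for c in self.concentrations for r in range(self.replicates)]


def build_dilution_series(
    c_max: float,
    c_min: float,
    factor: float,
    include_blank: bool = True,
    replicates: int = 1,
    randomized_order: bool = False,
    endpoint_tol: float = 1e-3,
) -> DilutionSeries:
    """Enumerate a geometric dilution series from ``c_max`` down to ``c_min``.

    Levels are c_max, c_max/factor, c_max/factor^2, ... down to the last
    value >= c_min * (1 - endpoint_tol); the tolerance keeps a printed
    endpoint such as 0.1 ppm inside a series that starts at 10 ppm with
    factor 4/3 despite floating-point drift.  A blank (0 ppm) level is
    appended when requested.
    """
    if c_min <= 0 or c_max < c_min:
        raise ValueError(f"need c_max >= c_min > 0, got c_max={c_max}, c_min={c_min}")
    if factor <= 1:
        raise ValueError(f"dilution factor must be > 1, got {factor}")
    levels: list[float] = []
    floor = c_min * (1.0 - endpoint_tol)
    k = 0
    while True:
        c = c_max / factor**k
        if c < floor:
            break
        levels.append(c)
        k += 1
    if include_blank:
        levels.append(0.0)
    return DilutionSeries(
        concentrations=tuple(levels),
        replicates=replicates,
        randomized_order=randomized_order,
    )


@dataclass(frozen=True)
class SpotModel:
    """Morphology and concentration response of a single spot.

    The darkness amplitude follows a saturating response
    ``A(c) = A_max * c / (c + K)`` — zero at blank, half-maximal at the
    ``response_halfsat`` concentration K, approaching ``response_amplitude``
    (A_max) at high concentration.  The spatial shape mixes a soft disc with
    one to three Gaussian annuli ("coffee rings") drawn per spot; radii,
    widths and ellipticity are perturbed by ``shape_jitter`` so spots come
    in irregular sizes and shapes.
    """

    disc_radius: float = 24.0
    ring_radii: tuple[float, ...] = (22.0, 17.0, 26.0)
    ring_widths: tuple[float, ...] = (2.5, 3.5, 2.0)
    ring_weight: float = 0.5
    response_amplitude: float = 0.35
    response_halfsat: float = 2.0
    shape_jitter: float = 0.08
    edge_softness: float = 1.5

    def __post_init__(self) -> None:
        if self.disc_radius <= 0 or any(r <= 0 for r in self.ring_radii):
            raise ValueError("all radii must be positive")
        if len(self.ring_radii) != len(self.ring_widths):
            raise ValueError("ring_radii and ring_widths must have equal length")
        if not 0.0 <= self.ring_weight <= 1.0:
            raise ValueError("ring_weight must lie in [0, 1]")
        if self.response_amplitude <= 0 or self.response_halfsat <= 0:
            raise ValueError("response parameters must be positive")

    def darkness_amplitude(self, concentration: float) -> float:
        """Saturating concentration -> darkness map, strictly increasing."""
        c = float(concentration)
        if c < 0:
            raise ValueError(f"concentration must be >= 0, got {c}")
        return self.response_amplitude * c / (c + self.response_halfsat)

    @property
    def max_extent(self) -> float:
        """Conservative radius (px) beyond which a spot's darkness is negligible."""
        ring_reach = max(
            (r + 3.0 * w for r, w in zip(self.ring_radii, self.ring_widths)),
            default=0.0,
        )
        disc_reach = self.disc_radius + 5.0 * self.edge_softness
        return (1.0 + 4.0 * self.shape_jitter) * max(ring_reach, disc_reach)


@dataclass(frozen=True)
class _SpotShape:
    """One concrete shape realization drawn from a SpotModel."""

    disc_radius: float
    ring_radii: tuple[float, ...]
    ring_widths: tuple[float, ...]
    ring_weight: float
    axis_a: float
    axis_b: float
    angle: float
    edge_softness: float


def _sample_shape(model: SpotModel, rng: np.random.Generator) -> _SpotShape:
    # Number of coffee rings per spot is drawn from {1, .., n_pool};
    # the jitter perturbs radii, widths and introduces mild ellipticity.
    n_pool = len(model.ring_radii)
    k = int(rng.integers(1, n_pool + 1)) if n_pool > 0 else 0
    j = model.shape_jitter

    def perturb(x: float) -> float:
        return max(x * (1.0 + j * rng.standard_normal()), 0.5)

    disc_r = perturb(model.disc_radius)
    radii = tuple(perturb(r) for r in model.ring_radii[:k])
    widths = tuple(perturb(w) for w in model.ring_widths[:k])
    ratio = math.exp(j * rng.standard_normal())  # area-preserving ellipticity
    angle = float(rng.uniform(0.0, math.pi))
    return _SpotShape(
        disc_radius=disc_r,
        ring_radii=radii,
        ring_widths=widths,
        ring_weight=model.ring_weight,
        axis_a=math.sqrt(ratio),
        axis_b=1.0 / math.sqrt(ratio),
        angle=angle,
        edge_softness=model.edge_softness,
    )


def _shape_field(shape: _SpotShape, size: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Evaluate the unit-peak spatial darkness profile on a pixel grid."""
    rows, cols = size
    cy, cx = center
    dy = np.arange(rows, dtype=float)[:, None] - cy
    dx = np.arange(cols, dtype=float)[None, :] - cx
    ca, sa = math.cos(shape.angle), math.sin(shape.angle)
    u = (ca * dx + sa * dy) / shape.axis_a
    v = (-sa * dx + ca * dy) / shape.axis_b
    r = np.hypot(u, v)
    disc = 1.0 / (1.0 + np.exp((r - shape.disc_radius) / shape.edge_softness))
    rings = np.zeros_like(r)
    for ri, wi in zip(shape.ring_radii, shape.ring_widths):
        rings += np.exp(-((r - ri) ** 2) / (2.0 * wi**2))
    s = (1.0 - shape.ring_weight) * disc + shape.ring_weight * rings
    peak = float(s.max())
    if peak > 0:
        s /= peak  # unit peak, so peak darkness equals A(c) exactly
    return s


def render_spot(
    concentration: float,
    model: SpotModel,
    rng: np.random.Generator,
    size: int = 81,
    background: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Render one noise-free spot patch: background minus darkness.

    The patch is ``background - A(c) * S`` clipped to [0, 1], where S is the
    unit-peak shape field drawn from ``rng``.  At c = 0 the patch equals the
    background exactly.  Shape draws are consumed from ``rng`` even at c = 0
    so that patches at different concentrations from identical generator
    states share the same shape.
    """
    amp = model.darkness_amplitude(concentration)
    shape = _sample_shape(model, rng)
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    s = _shape_field(shape, (size, size), center)
    patch = np.broadcast_to(np.asarray(background, dtype=float), s.shape) - amp * s
    return np.clip(patch, 0.0, 1.0)


@dataclass(frozen=True)
class MembraneLayout:
    """Physical geometry and imaging conditions of one membrane photograph.

    Defaults reflect a 3x3 dispenser grid at 0.9 cm pitch on a 3.6 cm
    square membrane, imaged at 45 um per pixel (so a 6 px ring thickness
    corresponds to 270 um on the substrate).  Illumination is a low-order
    polynomial field of configurable relative amplitude; pixel noise is
    i.i.d. Gaussian per channel.
    """

    grid_shape: tuple[int, int] = (3, 3)
    pitch_cm: float = 0.9
    pixel_scale_um: float = 45.0
    membrane_size_cm: float = 3.6
    placement_jitter: float = 2.0
    base_level: float = 0.9
    illumination_amplitude: float = 0.05
    noise_sd: float = 0.02
    channel_tint: tuple[float, float, float] = (0.90, 1.15, 0.95)

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid must have positive capacity")
        if self.pitch_cm <= 0 or self.pixel_scale_um <= 0 or self.membrane_size_cm <= 0:
            raise ValueError("physical dimensions must be positive")
        if self.placement_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise standard deviations must be >= 0")
        if not 0 < self.base_level <= 1:
            raise ValueError("base_level must lie in (0, 1]")

    @property
    def pitch_px(self) -> float:
        return self.pitch_cm * 1e4 / self.pixel_scale_um

    @property
    def size_px(self) -> int:
        return int(round(self.membrane_size_cm * 1e4 / self.pixel_scale_um))

    @property
    def capacity(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def nominal_centers(self) -> list[tuple[int, int]]:
        """Row-major integer grid node positions, centered on the membrane."""
        out: list[tuple[int, int]] = []
        n_r, n_c = self.grid_shape
        start_y = (self.size_px - (n_r - 1) * self.pitch_px) / 2.0
        start_x = (self.size_px - (n_c - 1) * self.pitch_px) / 2.0
        for r in range(n_r):
            for c in range(n_c):
                out.append(
                    (int(round(start_y + r * self.pitch_px)), int(round(start_x + c * self.pitch_px)))
                )
        return out


@dataclass(frozen=True)
class SpotRecord:
    """Ground-truth annotation for one rendered spot."""

    spot_id: int
    membrane_id: int
    grid_row: int
    grid_col: int
    nominal_center: tuple[int, int]
    true_center: tuple[float, float]
    concentration: float
    replicate: int


@dataclass(frozen=True, eq=False)
class SyntheticMembrane:
    """A rendered membrane image plus its ground-truth spot annotations."""

    image: np.ndarray
    spots: tuple[SpotRecord, ...]
    membrane_id: int

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        for s in self.spots:
            ty, tx = s.true_center
            if not (0 <= ty < h and 0 <= tx < w):
                raise ValueError(f"spot {s.spot_id} center {s.true_center} outside image")


def _illumination_field(layout: MembraneLayout, rng: np.random.Generator) -> np.ndarray:
    """Low-order polynomial illumination, dimmest-to-brightest span = amplitude.

    The brightest point sits at ``base_level`` (below full scale so pixel
    noise does not clip on white membrane regions).
    """
    n = layout.size_px
    u = np.linspace(-1.0, 1.0, n)[None, :]
    v = np.linspace(-1.0, 1.0, n)[:, None]
    coef = rng.uniform(-1.0, 1.0, size=5)
    poly = coef[0] * u + coef[1] * v + coef[2] * u * v + coef[3] * u**2 + coef[4] * v**2
    span = float(poly.max() - poly.min())
    if span > 0 and layout.illumination_amplitude > 0:
        poly = (poly - poly.min()) / span  # in [0, 1]
        return layout.base_level * (1.0 - layout.illumination_amplitude * poly)
    return np.full((n, n), layout.base_level)


def render_membrane(
    layout: MembraneLayout,
    series: DilutionSeries,
    model: SpotModel,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> list[SyntheticMembrane]:
    """Render the full series onto as many membranes as the grid requires.

    Instances beyond one membrane's grid capacity spill onto additional
    membranes (ceil(n_instances / capacity) in total).  Deterministic for a
    fixed seed.
    """
    if layout.capacity == 0:
        raise ValueError("membrane layout has zero grid capacity")
    if layout.pitch_px < 2.0 * model.max_extent:
        raise ValueError(
            f"grid pitch {layout.pitch_px:.1f} px < 2x max spot extent "
            f"{model.max_extent:.1f} px: spots would overlap"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    instances = series.instances()
    if series.randomized_order:
        order = rng.permutation(len(instances))
        instances = [instances[i] for i in order]

    centers = layout.nominal_centers()
    n = layout.size_px
    tint = np.asarray(layout.channel_tint, dtype=float)
    membranes: list[SyntheticMembrane] = []
    n_membranes = math.ceil(len(instances) / layout.capacity)
    spot_id = 0
    for m in range(n_membranes):
        chunk = instances[m * layout.capacity : (m + 1) * layout.capacity]
        illum = _illumination_field(layout, rng)
        darkness = np.zeros((n, n))
        records: list[SpotRecord] = []
        for k, (conc, rep) in enumerate(chunk):
            ny, nx = centers[k]
            jy, jx = layout.placement_jitter * rng.standard_normal(2)
            ty, tx = ny + jy, nx + jx
            shape = _sample_shape(model, rng)
            amp = model.darkness_amplitude(conc)
            # render only a local window around the spot
            half = int(math.ceil(model.max_extent)) + 4
            y0, y1 = max(ny - half, 0), min(ny + half + 1, n)
            x0, x1 = max(nx - half, 0), min(nx + half + 1, n)
            s = _shape_field(shape, (y1 - y0, x1 - x0), (ty - y0, tx - x0))
            darkness[y0:y1, x0:x1] += amp * s
            records.append(
                SpotRecord(
                    spot_id=spot_id,
                    membrane_id=m,
                    grid_row=k // layout.grid_shape[1],
                    grid_col=k % layout.grid_shape[1],
                    nominal_center=(ny, nx),
                    true_center=(ty, tx),
                    concentration=conc,
                    replicate=rep,
                )
            )
            spot_id += 1
        image = illum[:, :, None] - darkness[:, :, None] * tint[None, None, :]
        if layout.noise_sd > 0:
            image = image + layout.noise_sd * rng.standard_normal(image.shape)
        image = np.clip(image, 0.0, 1.0)
        membranes.append(SyntheticMembrane(image=image, spots=tuple(records), membrane_id=m))
    return membranes


@dataclass(frozen=True, eq=False)
class SpotCrop:
    """A single-spot crop with its label and ground truth, in crop coordinates."""

    image: np.ndarray
    concentration: float
    nominal_center: tuple[int, int]
    true_center: tuple[float, float]
    spot_id: int
    membrane_id: int
    replicate: int


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic dataset.

    The defaults reproduce the standardized acquisition this package
    emulates: dilutions from 10 down to 0.1 ppm with factor 4/3, plus a
    blank, each level spotted in duplicate in random order — 36 spot
    instances on four 3x3 membranes.
    """

    c_max: float = 10.0
    c_min: float = 0.1
    dilution_factor: float = 4.0 / 3.0
    include_blank: bool = True
    replicates: int = 2
    randomized_order: bool = True
    endpoint_tol: float = 1e-3
    layout: MembraneLayout = field(default_factory=MembraneLayout)
    spot_model: SpotModel = field(default_factory=SpotModel)
    crop_size: int = 81

    def series(self) -> DilutionSeries:
        return build_dilution_series(
            self.c_max,
            self.c_min,
            self.dilution_factor,
            include_blank=self.include_blank,
            replicates=self.replicates,
            randomized_order=self.randomized_order,
            endpoint_tol=self.endpoint_tol,
        )


def generate_dataset(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> list[SpotCrop]:
    """Render the configured series and cut one crop per spot.

    Crops are centered on the *nominal* grid node, not the jittered true
    center, so downstream center refinement has genuine work to do.  The
    crop size defaults to 81 px: the 71 px span of a 6-ring mask of 6 px
    thickness plus a 5 px search margin on each side.
    """
    series = config.series()
    membranes = render_membrane(config.layout, series, config.spot_model, seed)
    half = (config.crop_size - 1) // 2
    crops: list[SpotCrop] = []
    for mem in membranes:
        h, w = mem.image.shape[:2]
        for s in mem.spots:
            ny, nx = s.nominal_center
            if ny - half < 0 or nx - half < 0 or ny + half >= h or nx + half >= w:
                raise CropBoundsError(
                    f"crop for spot {s.spot_id} exceeds bounds of membrane {mem.membrane_id}"
                )
            img = mem.image[ny - half : ny + half + 1, nx - half : nx + half + 1].copy()
            crops.append(
                SpotCrop(
                    image=img,
                    concentration=s.concentration,
                    nominal_center=(half, half),
                    true_center=(s.true_center[0] - (ny - half), s.true_center[1] - (nx - half)),
                    spot_id=s.spot_id,
                    membrane_id=s.membrane_id,
                    replicate=s.replicate,
                )
            )
    return crops
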