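"""Forward model of the zinc biosensor: zinc → pigments → pellet RGB → photo.

The sensor cells carry a three-pigment circuit. When induced with IPTG,
violacein (purple) is expressed at low zinc and switched off by a
zinc-loaded repressor; the carotenoid branch always runs, and a
zinc-activated enzyme converts the red carotenoid lycopene into orange
β-carotene as zinc rises. Both switches are modelled phenomenologically as
Hill functions: violacein follows a repressive Hill curve with half-off
point ``k_vio``, and the lycopene→β-carotene conversion follows an
activating Hill curve with half-transition ``k_crty``. Without inducer no
pigment is made and pellets stay colorless.

Pellet colors are produced by subtractive (Beer–Lambert-style) mixing: each
pigment attenuates each RGB channel of a white-paper background by
``exp(-absorptivity * level)``. Rendering places a noisy pellet disc on a
clean background, emulating a tube photographed against white paper in a
light-controlled box. Everything is seeded, so rendered images are
bit-reproducible and serve as ground-truth oracles for the extraction,
scoring and quantification stages.

All RGB values are 8-bit sRGB as read from a camera JPEG/PNG; no gamma
linearization is applied anywhere in the pipeline (a deliberate convention:
the phone app this emulates reads raw sRGB bytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, GeometryError

__all__ = [
    "CircuitParams",
    "PigmentState",
    "OpticalModel",
    "DEFAULT_ABSORPTIVITY",
    "pigment_response",
    "rgb_from_pigments",
    "render_pellet_image",
    "simulate_assay_images",
    "DEFAULT_STANDARDS_ZINC",
]

#: Default zinc concentrations (µM in the assay well) of the five standards.
#: The well range 0–5 µM spans the physiologically relevant serum window
#: (2–20 µM serum at a 25% serum fraction).
DEFAULT_STANDARDS_ZINC = (0.0, 1.0, 2.0, 3.5, 5.0)


@dataclass(frozen=True)
class CircuitParams:
    """Phenomenological dose-response parameters of the pigment circuit.

    Defaults place the violacein half-off point at 1.5 µM (so the purple→red
    switch falls between 1 and 2 µM zinc) and the lycopene→β-carotene
    half-transition at 5 µM, with steep (n=4) switches. These are plausible
    placeholder dose-response parameters consistent with the qualitative
    transition windows of the sensor; they are configurable and not measured
    constants.
    """

    v_max: float = 0.5        # max OD-normalized violacein (dimensionless)
    c_tot: float = 1.0        # total carotenoid capacity (a.u.)
    k_vio: float = 1.5        # violacein half-off zinc (µM)
    n_vio: float = 4.0        # violacein Hill coefficient
    k_crty: float = 5.0       # lycopene→β-carotene half-transition zinc (µM)
    n_crty: float = 4.0       # carotenoid-switch Hill coefficient
    induced: bool = True      # IPTG present: pigment module active

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.c_tot <= 0:
            raise DomainError("v_max and c_tot must be positive")
        if self.k_vio <= 0 or self.k_crty <= 0:
            raise DomainError("Hill half-points k_vio and k_crty must be positive")
        if self.n_vio < 1 or self.n_crty < 1:
            raise DomainError("Hill coefficients must be >= 1")


@dataclass(frozen=True)
class PigmentState:
    """OD-normalized pigment levels of one sample."""

    violacein: float
    lycopene: float
    beta_carotene: float

    def __post_init__(self) -> None:
        levels = (self.violacein, self.lycopene, self.beta_carotene)
        if any(v is None or np.isnan(v) for v in levels):
            raise DomainError("pigment levels must be finite numbers")
        if any(v < 0 for v in levels):
            raise DomainError("pigment levels must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.violacein, self.lycopene, self.beta_carotene], dtype=float
        )


#: Per-pigment, per-channel effective extinction coefficients (a.u.^-1).
#: Rows: violacein, lycopene, β-carotene; columns: R, G, B. Chosen so that,
#: against the default background, pure violacein renders in the purple
#: band, pure lycopene red, and pure β-carotene orange. Artifact constants.
DEFAULT_ABSORPTIVITY = np.array(
    [
        [1.05, 0.95, 0.28],   # violacein: darkens R and G, spares B → purple cast
        [0.20, 1.40, 0.90],   # lycopene: kills G, partial B → red
        [0.08, 0.77, 2.38],   # β-carotene: kills B, partial G → orange
    ]
)


@dataclass(frozen=True)
class OpticalModel:
    """Imaging model: background paper color, illumination gain, sensor noise."""

    absorptivity: np.ndarray = field(
        default_factory=lambda: DEFAULT_ABSORPTIVITY.copy()
    )
    background_rgb: tuple[float, float, float] = (245.0, 245.0, 240.0)
    noise_sigma: float = 3.0
    illumination_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorptivity, dtype=float)
        if a.shape != (3, 3) or (a < 0).any():
            raise DomainError("absorptivity must be a 3x3 nonnegative matrix")
        object.__setattr__(self, "absorptivity", a)
        if any(not (0 <= c <= 255) for c in self.background_rgb):
            raise DomainError("background channels must lie in [0, 255]")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if any(g <= 0 for g in self.illumination_gain):
            raise DomainError("illumination gains must be positive")


def pigment_response(zinc: float, params: CircuitParams | None = None) -> PigmentState:
    """Pigment levels produced at a given zinc concentration.

    Parameters
    ----------
    zinc : float
        Zinc concentration in the assay well (µM). Must be >= 0.
    params : CircuitParams, optional
        Circuit dose-response parameters; defaults used when omitted.

    Returns
    -------
    PigmentState
        Violacein follows a repressive Hill curve, β-carotene an activating
        one, and lycopene is the carotenoid remainder, so
        ``lycopene + beta_carotene == c_tot`` whenever the circuit is
        induced. Without inducer all pigments are zero.
    """
    if params is None:
        params = CircuitParams()
    zinc = float(zinc)
    if not np.isfinite(zinc) or zinc < 0:
        raise DomainError(f"zinc concentration must be >= 0, got {zinc}")
    if not params.induced:
        return PigmentState(0.0, 0.0, 0.0)
    kv = params.k_vio ** params.n_vio
    violacein = params.v_max * kv / (kv + zinc ** params.n_vio)
    kc = params.k_crty ** params.n_crty
    zc = zinc ** params.n_crty
    beta = params.c_tot * zc / (kc + zc)
    return PigmentState(violacein, params.c_tot - beta, beta)


def rgb_from_pigments(
    pigments: PigmentState, optics: OpticalModel | None = None
) -> tuple[int, int, int]:
    """Noiseless 8-bit pellet color from pigment levels.

    Each channel c is ``clamp(round(background_c * gain_c *
    exp(-sum_p absorptivity[p, c] * level_p)), 0, 255)`` — subtractive
    mixing, monotone non-increasing in every pigment level.
    """
    if optics is None:
        optics = OpticalModel()
    levels = pigments.as_array()
    bg = np.asarray(optics.background_rgb, dtype=float)
    gain = np.asarray(optics.illumination_gain, dtype=float)
    attenuation = np.exp(-levels @ optics.absorptivity)
    channels = np.clip(np.rint(bg * gain * attenuation), 0, 255).astype(int)
    return (int(channels[0]), int(channels[1]), int(channels[2]))


def _disc_mask(height: int, width: int, center: tuple[int, int], radius: float) -> np.ndarray:
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius ** 2


def render_pellet_image(
    rgb: tuple[float, float, float],
    width: int,
    height: int,
    pellet_center: tuple[int, int],
    pellet_radius: float,
    optics: OpticalModel | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render one pellet disc of mean color ``rgb`` on the paper background.

    Pixels inside the disc (Euclidean distance <= radius from the 0-based
    (row, col) center) get the pellet color plus i.i.d. per-pixel,
    per-channel Gaussian noise of std ``optics.noise_sigma``, rounded and
    clamped to [0, 255]; pixels outside are the exact background color.
    The same seed always yields a bit-identical image.
    """
    if optics is None:
        optics = OpticalModel()
    row, col = pellet_center
    r = float(pellet_radius)
    if row - r < 0 or col - r < 0 or row + r > height - 1 or col + r > width - 1:
        raise GeometryError(
            f"pellet disc (center={pellet_center}, radius={r}) does not fit "
            f"inside a {height}x{width} image"
        )
    bg = np.clip(
        np.rint(
            np.asarray(optics.background_rgb, dtype=float)
            * np.asarray(optics.illumination_gain, dtype=float)
        ),
        0,
        255,
    ).astype(np.uint8)
    image = np.empty((height, width, 3), dtype=np.uint8)
    image[:, :] = bg
    mask = _disc_mask(height, width, (row, col), r)
    values = np.tile(np.asarray(rgb, dtype=float), (int(mask.sum()), 1))
    if optics.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, optics.noise_sigma, size=values.shape)
    image[mask] = np.clip(np.rint(values), 0, 255).astype(np.uint8)
    return image


def simulate_assay_images(
    standards_zinc=DEFAULT_STANDARDS_ZINC,
    test_zinc: float = 2.5,
    params: CircuitParams | None = None,
    optics: OpticalModel | None = None,
    seed: int = 0,
    pellet_radius: float = 16.0,
    spacing: int = 56,
    margin: int = 40,
    height: int = 80,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one six-tube assay photo: standards of known zinc plus a test.

    Pellets are laid out left to right on a single row at known centers, the
    standards first (ascending input order preserved) and the test reaction
    last. The returned table is both layout and ground truth: one row per
    tube with its role, true zinc, disc geometry, and noiseless RGB.

    Parameters
    ----------
    standards_zinc : sequence of float
        Assay-well zinc of the standard reactions (µM); at least two.
    test_zinc : float
        True assay-well zinc of the test reaction (µM).
    seed : int
        Master seed; per-pellet noise streams are derived from it.

    Returns
    -------
    (image, table)
        ``image`` is an (H, W, 3) uint8 array; ``table`` a DataFrame with
        columns tube_id, role, zinc_uM, center_row, center_col, radius,
        r, g, b.
    """
    if params is None:
        params = CircuitParams()
    if optics is None:
        optics = OpticalModel()
    standards_zinc = [float(z) for z in standards_zinc]
    if len(standards_zinc) < 2:
        raise DomainError("need at least 2 standards")
    if spacing <= 2 * pellet_radius:
        raise GeometryError(
            f"pellet spacing {spacing} px would overlap discs of radius {pellet_radius}"
        )
    zincs = standards_zinc + [float(test_zinc)]
    n = len(zincs)
    width = 2 * margin + (n - 1) * spacing
    center_row = height // 2
    bg = np.clip(
        np.rint(
            np.asarray(optics.background_rgb, dtype=float)
            * np.asarray(optics.illumination_gain, dtype=float)
        ),
        0,
        255,
    ).astype(np.uint8)
    image = np.empty((height, width, 3), dtype=np.uint8)
    image[:, :] = bg

    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(n)
    for i, zinc in enumerate(zincs):
        is_test = i == n - 1
        center = (center_row, margin + i * spacing)
        rgb = rgb_from_pigments(pigment_response(zinc, params), optics)
        pellet = render_pellet_image(
            rgb,
            width=width,
            height=height,
            pellet_center=center,
            pellet_radius=pellet_radius,
            optics=optics,
            seed=child_seeds[i],
        )
        mask = _disc_mask(height, width, center, pellet_radius)
        image[mask] = pellet[mask]
        rows.append(
            {
                "tube_id": "T1" if is_test else f"S{i + 1}",
                "role": "test" if is_test else "standard",
                "zinc_uM": zinc,
                "center_row": center[0],
                "center_col": center[1],
                "radius": pellet_radius,
                "r": rgb[0],
                "g": rgb[1],
                "b": rgb[2],
            }
        )
    return image, pd.DataFrame(rows)
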