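"""Calibration-curve fitting, inverse zinc prediction, and status calls.

The assay photographs five standard reactions of known zinc alongside one
test reaction. Because illumination, growth and lyophilization recovery
vary run to run, each image carries its own calibration: per-channel
piecewise-linear curves through the standards' (zinc, mean channel) points.
The test reaction's zinc is recovered by joint three-channel least squares
along the calibration locus — the zinc value whose predicted (R, G, B)
triple is nearest (Euclidean) to the observed pellet color. Joint inversion
is used rather than inverting each channel separately because individual
channels need not be monotone through the purple→red→orange sequence,
whereas the RGB locus parameterized by zinc is a well-defined curve.

Assay-well zinc converts to serum zinc through the serum fraction (the test
runs in 25% serum from a 1:4 dilution, so serum zinc = 4 × well zinc), and
the serum value is classified low / borderline / high against configurable
clinical thresholds. The default thresholds (10 and 13 µM serum) are
explicit placeholders that users must confirm against the clinical cutoffs
applicable to their population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .color_model import ClassThresholds, Palette, score_from_rgb
from .errors import CalibrationError, ConfigError, DomainError, LayoutError
from .pellet_extraction import DEFAULT_WINDOW_SIDE, PelletColor, load_image, mean_rgb

__all__ = [
    "Standard",
    "CalibrationModel",
    "AssayConfig",
    "AssayResult",
    "fit_calibration",
    "predict_zinc",
    "to_serum_zinc",
    "classify_serum",
    "quantify_image",
]

logger = logging.getLogger(__name__)

GRID_STEP_UM = 0.01  # zinc resolution of the inverse-prediction grid search


def _color_array(color) -> np.ndarray:
    if isinstance(color, PelletColor):
        return color.as_array()
    arr = np.asarray(color, dtype=float)
    if arr.shape != (3,):
        raise DomainError(f"expected an RGB triple or PelletColor, got {color!r}")
    return arr


@dataclass(frozen=True)
class Standard:
    """One calibration reaction: known assay-well zinc and its pellet color."""

    zinc: float
    color: PelletColor | tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.zinc < 0:
            raise DomainError(f"standard zinc must be >= 0, got {self.zinc}")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-channel monotone-in-zinc piecewise-linear maps zinc → channel mean.

    ``node_zinc`` is strictly increasing; ``node_rgb`` holds the matching
    (n, 3) mean colors. Duplicate standard zincs are averaged at fit time.
    """

    node_zinc: np.ndarray
    node_rgb: np.ndarray

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.node_zinc[0]), float(self.node_zinc[-1])

    def rgb_at(self, zinc) -> np.ndarray:
        """Interpolated (R, G, B) at one or many zinc values within the domain."""
        z = np.atleast_1d(np.asarray(zinc, dtype=float))
        out = np.column_stack(
            [np.interp(z, self.node_zinc, self.node_rgb[:, c]) for c in range(3)]
        )
        return out[0] if np.isscalar(zinc) or np.ndim(zinc) == 0 else out


def fit_calibration(standards) -> CalibrationModel:
    """Fit per-channel piecewise-linear calibration curves through standards.

    Input order is irrelevant; standards sharing a zinc value are averaged.
    At least two distinct zinc values are required.
    """
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standards to calibrate")
    zs = np.array([s.zinc for s in standards], dtype=float)
    colors = np.array([_color_array(s.color) for s in standards], dtype=float)
    uniq = np.unique(zs)
    if uniq.size < 2:
        raise CalibrationError("need at least 2 distinct standard zinc values")
    rgb = np.array([colors[zs == z].mean(axis=0) for z in uniq])
    return CalibrationModel(node_zinc=uniq, node_rgb=rgb)


def predict_zinc(
    model: CalibrationModel, color
) -> tuple[float, float, bool]:
    """Inverse-predict assay-well zinc from an observed pellet color.

    Minimizes the squared Euclidean RGB distance between the observed color
    and the calibration locus over the standards' zinc domain, by dense grid
    search (step 0.01 µM) refined with bounded local optimization; ties
    resolve to the smallest zinc. When the minimizer sits at a domain
    endpoint with the distance still decreasing outward, the estimate is
    clamped there and flagged ``extrapolated``.

    Returns
    -------
    (assay_zinc, fit_residual, extrapolated)
        Estimate in µM, Euclidean RGB distance at the estimate, and the
        out-of-range flag.
    """
    target = _color_array(color)
    z0, z1 = model.domain

    def dist2(z: float) -> float:
        diff = model.rgb_at(float(z)) - target
        return float(diff @ diff)

    n = int(np.ceil((z1 - z0) / GRID_STEP_UM)) + 1
    grid = np.linspace(z0, z1, max(n, 2))
    d2 = ((model.rgb_at(grid) - target) ** 2).sum(axis=1)
    i = int(np.argmin(d2))  # first minimum → smallest zinc on ties

    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(dist2, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        z_hat = float(res.x) if res.fun <= d2[i] + 1e-12 else float(grid[i])
    else:
        z_hat = float(grid[i])
    if dist2(grid[i]) < dist2(z_hat):
        z_hat = float(grid[i])

    residual = float(np.sqrt(dist2(z_hat)))
    extrapolated = False
    eps = GRID_STEP_UM
    if z_hat - z0 <= eps / 2 and residual > 1e-9:
        z_hat = z0
        extrapolated = dist2(z0) < dist2(z0 + eps)  # still decreasing leftward
    elif z1 - z_hat <= eps / 2 and residual > 1e-9:
        z_hat = z1
        extrapolated = dist2(z1) < dist2(z1 - eps)  # still decreasing rightward
    if extrapolated:
        logger.warning(
            "test color lies outside the calibration range [%.3g, %.3g] µM; "
            "estimate clamped to %.3g µM", z0, z1, z_hat,
        )
    return z_hat, residual, extrapolated


@dataclass(frozen=True)
class AssayConfig:
    """Assay geometry and clinical thresholds.

    The default reaction is 200 µL at a 25% serum fraction (50 µL serum via
    a 1:4 dilution). ``serum_thresholds`` are the (low_upper,
    borderline_upper) serum-zinc cutoffs in µM; the defaults are
    placeholders pending confirmed clinical values.
    """

    serum_fraction: float = 0.25
    reaction_volume_uL: float = 200.0
    serum_volume_uL: float = 50.0
    serum_thresholds: tuple[float, float] = (10.0, 13.0)

    def __post_init__(self) -> None:
        if not (0 < self.serum_fraction <= 1):
            raise ConfigError("serum_fraction must lie in (0, 1]")
        if not np.isclose(
            self.serum_volume_uL, self.serum_fraction * self.reaction_volume_uL
        ):
            raise ConfigError(
                "serum_volume_uL must equal serum_fraction * reaction_volume_uL "
                f"({self.serum_volume_uL} != "
                f"{self.serum_fraction * self.reaction_volume_uL})"
            )
        low, high = self.serum_thresholds
        if not (0 < low < high):
            raise ConfigError("need 0 < low_upper < borderline_upper")


@dataclass(frozen=True)
class AssayResult:
    """Outcome of one quantified assay image."""

    assay_zinc: float      # µM in the reaction well
    serum_zinc: float      # µM in undiluted serum
    status: str            # low | borderline | high
    extrapolated: bool
    fit_residual: float    # RGB distance to the calibration locus
    tubes: pd.DataFrame | None = field(default=None, compare=False)


def to_serum_zinc(assay_zinc: float, config: AssayConfig | None = None) -> float:
    """Convert assay-well zinc to serum zinc by undoing the serum dilution.

    At the default 25% serum fraction this is a ×4 mapping: a 0.5–5 µM well
    range corresponds to 2–20 µM serum.
    """
    if config is None:
        config = AssayConfig()
    assay_zinc = float(assay_zinc)
    if assay_zinc < 0:
        raise DomainError(f"assay zinc must be >= 0, got {assay_zinc}")
    return assay_zinc / config.serum_fraction


def classify_serum(serum_zinc: float, config: AssayConfig | None = None) -> str:
    """Classify serum zinc as low, borderline, or high.

    Boundary values assign upward: exactly low_upper is borderline, exactly
    borderline_upper is high.
    """
    if config is None:
        config = AssayConfig()
    serum_zinc = float(serum_zinc)
    if serum_zinc < 0:
        raise DomainError(f"serum zinc must be >= 0, got {serum_zinc}")
    low_upper, borderline_upper = config.serum_thresholds
    if serum_zinc < low_upper:
        return "low"
    if serum_zinc < borderline_upper:
        return "borderline"
    return "high"


REQUIRED_LAYOUT_COLUMNS = ("tube_id", "role", "zinc_uM", "center_row", "center_col")


def quantify_image(
    image,
    layout: pd.DataFrame,
    config: AssayConfig | None = None,
    palette: Palette | None = None,
    thresholds: ClassThresholds | None = None,
    window_side: int = DEFAULT_WINDOW_SIDE,
) -> AssayResult:
    """Run the full readout on one assay photo.

    Parameters
    ----------
    image : path or (H, W, 3) array
        The assay photograph.
    layout : DataFrame
        One row per tube with columns tube_id, role ("standard"/"test"),
        zinc_uM (standards only), center_row, center_col.
    window_side : int
        Side of the averaging window around each center (default 20 px).

    Returns
    -------
    AssayResult
        Estimated well and serum zinc, status call, extrapolation flag, and
        a per-tube table (extracted colors, scores, labels) in ``tubes``.
    """
    if config is None:
        config = AssayConfig()
    if palette is None:
        palette = Palette()
    if thresholds is None:
        thresholds = ClassThresholds()
    if isinstance(image, (str, Path)):
        image = load_image(image)

    missing = [c for c in REQUIRED_LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise LayoutError(f"layout is missing columns: {missing}")
    roles = layout["role"].astype(str).str.lower()
    n_test = int((roles == "test").sum())
    n_std = int((roles == "standard").sum())
    if n_test != 1:
        raise LayoutError(f"layout must name exactly 1 test tube, found {n_test}")
    if n_std < 2:
        raise LayoutError(f"layout must name at least 2 standards, found {n_std}")

    rows = []
    standards = []
    test_color = None
    for _, tube in layout.iterrows():
        role = str(tube["role"]).lower()
        center = (int(tube["center_row"]), int(tube["center_col"]))
        color = mean_rgb(image, center, window_side, source=str(tube["tube_id"]))
        cs = score_from_rgb(color.rgb, palette, thresholds)
        if role == "standard":
            zinc = float(tube["zinc_uM"])
            if np.isnan(zinc):
                raise LayoutError(f"standard {tube['tube_id']} lacks zinc_uM")
            standards.append(Standard(zinc=zinc, color=color))
        else:
            zinc = np.nan
            test_color = color
        rows.append(
            {
                "tube_id": tube["tube_id"],
                "role": role,
                "zinc_uM": zinc,
                "center_row": center[0],
                "center_col": center[1],
                "window_side": window_side,
                "n_pixels": color.n_pixels,
                "r_mean": color.rgb[0],
                "g_mean": color.rgb[1],
                "b_mean": color.rgb[2],
                "score": cs.score,
                "label": cs.label,
                "residual": cs.residual,
            }
        )

    model = fit_calibration(standards)
    assay_zinc, fit_residual, extrapolated = predict_zinc(model, test_color)
    serum_zinc = to_serum_zinc(assay_zinc, config)
    status = classify_serum(serum_zinc, config)
    return AssayResult(
        assay_zinc=assay_zinc,
        serum_zinc=serum_zinc,
        status=status,
        extrapolated=extrapolated,
        fit_residual=fit_residual,
        tubes=pd.DataFrame(rows),
    )
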