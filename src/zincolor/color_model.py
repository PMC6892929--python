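"""Color scoring and purple/red/orange classification.

A pellet's color is summarized as a scalar score on a 0–4 scale running
purple (0) → red (2) → orange (4). The score is obtained by orthogonally
projecting the pellet's RGB triple onto a piecewise-linear polyline through
a set of reference anchor colors (a "palette") and interpolating the anchor
scores along the projected segment. Class bands follow the survey-derived
convention for this assay: scores in [0, 1.5) are purple, [1.5, 2.5) red,
and [2.5, 4] orange.

Samples with direct pigment measurements are classified in pigment space
instead: OD-normalized violacein above 0.2 is purple; otherwise the
dominating carotenoid decides between red (lycopene) and orange
(β-carotene).

The default palette anchors are artifact constants chosen on the rendered
color locus of the default forward model (they are NOT survey color-bar
values, which are not published); users who have a measured color bar
should supply their own anchors to reproduce their instrument exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError
from .forward_model import PigmentState

__all__ = [
    "Palette",
    "ColorScore",
    "ClassThresholds",
    "DEFAULT_ANCHORS",
    "score_from_rgb",
    "classify_score",
    "classify_pigments",
]

logger = logging.getLogger(__name__)

#: Default (score, RGB) anchors. Scores 0, 1.5, 2, 2.5 and 4 sit at the
#: purple extreme, the purple/red boundary, the red reference, the
#: red/orange boundary, and the orange extreme of the default forward
#: model's rendered color locus.
DEFAULT_ANCHORS: tuple[tuple[float, tuple[float, float, float]], ...] = (
    (0.0, (119.0, 38.0, 85.0)),
    (1.5, (163.0, 50.0, 91.0)),
    (2.0, (197.0, 63.0, 82.0)),
    (2.5, (212.0, 82.0, 47.0)),
    (4.0, (226.0, 113.0, 22.0)),
)

#: Pellets farther than this (Euclidean RGB distance) from the palette
#: polyline are flagged as off-palette — e.g. a colorless pellet from a
#: failed (uninduced) reaction.
DEFAULT_RESIDUAL_GATE = 60.0


@dataclass(frozen=True)
class Palette:
    """Ordered (score, RGB) reference points spanning purple → red → orange."""

    anchors: tuple[tuple[float, tuple[float, float, float]], ...] = DEFAULT_ANCHORS
    residual_gate: float = DEFAULT_RESIDUAL_GATE

    def __post_init__(self) -> None:
        anchors = tuple(
            (float(s), (float(c[0]), float(c[1]), float(c[2])))
            for s, c in self.anchors
        )
        object.__setattr__(self, "anchors", anchors)
        if len(anchors) < 3:
            raise ConfigError("palette needs at least 3 anchors")
        scores = [s for s, _ in anchors]
        if scores[0] != 0.0 or scores[-1] != 4.0:
            raise ConfigError("palette scores must start at 0 and end at 4")
        if any(b <= a for a, b in zip(scores, scores[1:])):
            raise ConfigError("palette scores must be strictly increasing")
        colors = np.array([c for _, c in anchors], dtype=float)
        if (np.linalg.norm(np.diff(colors, axis=0), axis=1) < 1e-9).any():
            raise ConfigError("palette has repeated anchor colors (degenerate segment)")

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for s, _ in self.anchors], dtype=float)

    @property
    def colors(self) -> np.ndarray:
        return np.array([c for _, c in self.anchors], dtype=float)


@dataclass(frozen=True)
class ClassThresholds:
    """Class-band boundaries in score space and pigment space."""

    purple_red: float = 1.5          # score below → purple
    red_orange: float = 2.5          # score below (and >= purple_red) → red
    violacein_purple: float = 0.2    # OD-normalized violacein above → purple

    def __post_init__(self) -> None:
        if not (0 < self.purple_red < self.red_orange < 4):
            raise ConfigError("need 0 < purple_red < red_orange < 4")
        if self.violacein_purple <= 0:
            raise ConfigError("violacein_purple threshold must be positive")


@dataclass(frozen=True)
class ColorScore:
    """A scored pellet color: position on the 0–4 scale, class, and fit."""

    score: float
    label: str
    residual: float = field(default=0.0)


def score_from_rgb(
    rgb,
    palette: Palette | None = None,
    thresholds: ClassThresholds | None = None,
) -> ColorScore:
    """Project an RGB triple onto the palette polyline and read off its score.

    The returned score is the anchor-score interpolation of the orthogonal
    projection onto the nearest polyline segment (so every anchor maps
    exactly to its own score), clamped to [0, 4]. ``residual`` is the
    Euclidean RGB distance to the projection; values beyond the palette's
    ``residual_gate`` log a warning, flagging off-palette colors such as a
    colorless pellet from an incomplete test.
    """
    if palette is None:
        palette = Palette()
    if thresholds is None:
        thresholds = ClassThresholds()
    point = np.asarray(rgb, dtype=float)
    if point.shape != (3,) or not ((0 <= point) & (point <= 255)).all():
        raise DomainError(f"rgb must be three channels in [0, 255], got {rgb!r}")

    colors = palette.colors
    scores = palette.scores
    starts, ends = colors[:-1], colors[1:]
    seg = ends - starts
    seg_len2 = (seg ** 2).sum(axis=1)
    t = np.clip(((point - starts) * seg).sum(axis=1) / seg_len2, 0.0, 1.0)
    feet = starts + t[:, None] * seg
    dists = np.linalg.norm(feet - point, axis=1)
    best = int(np.argmin(dists))  # ties resolve to the lower-score segment
    score = float(
        np.clip(scores[best] + t[best] * (scores[best + 1] - scores[best]), 0.0, 4.0)
    )
    residual = float(dists[best])
    if residual > palette.residual_gate:
        logger.warning(
            "color %s is %.1f RGB units off the palette locus (gate %.1f); "
            "possible failed/colorless reaction",
            tuple(point),
            residual,
            palette.residual_gate,
        )
    return ColorScore(score=score, label=classify_score(score, thresholds), residual=residual)


def classify_score(score: float, thresholds: ClassThresholds | None = None) -> str:
    """Map a 0–4 color score to its class band.

    Boundary scores belong to the higher class: exactly 1.5 is red and
    exactly 2.5 is orange (purple is the strict class, mirroring the strict
    violacein rule in pigment space).
    """
    if thresholds is None:
        thresholds = ClassThresholds()
    score = float(score)
    if not (0.0 <= score <= 4.0):
        raise DomainError(f"score must lie in [0, 4], got {score}")
    if score < thresholds.purple_red:
        return "purple"
    if score < thresholds.red_orange:
        return "red"
    return "orange"


def classify_pigments(
    pigments: PigmentState, thresholds: ClassThresholds | None = None
) -> str:
    """Classify a sample from measured pigment levels.

    OD-normalized violacein strictly above the threshold (default 0.2) is
    purple; otherwise the dominating carotenoid decides: lycopene >=
    β-carotene is red, else orange.
    """
    if thresholds is None:
        thresholds = ClassThresholds()
    if pigments.violacein > thresholds.violacein_purple:
        return "purple"
    return "red" if pigments.lycopene >= pigments.beta_carotene else "orange"
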