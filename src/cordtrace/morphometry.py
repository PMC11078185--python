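"""Spinal-cord circularity morphometry.

The circularity index CI = 4*pi*area / perimeter^2 quantifies how close a
cord cross-section outline is to a circle (CI = 1) versus an elongated or
compressed shape (CI -> 0); it is used to assess mechanical deformation
after chronic device implantation.  Outlines are simple closed polygons
(vertices in micrometres); nine measurements per animal (three repeats on
each of three sections) are averaged, and the per-animal means are
compared against a control reference with a one-sample t test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GroupTestResult:
    """One-sample t test of per-animal means against a reference value."""

    n: int
    mean: float
    sd: float
    reference: float
    t_statistic: float
    p_value: float
    ci95: tuple[float, float]


def circularity(vertices: np.ndarray) -> float:
    """Circularity index 4*pi*area / perimeter^2 of a simple polygon.

    Area comes from the shoelace formula and the perimeter from the
    Euclidean vertex-to-vertex sum including the closing edge.  1.0 is a
    perfect circle; values near 0 indicate elongated shapes.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValidationError("outline needs at least 3 (x, y) vertices")
    poly = Polygon(v)
    if not poly.is_valid:
        raise ValidationError("outline polygon is self-intersecting or otherwise invalid")
    area = poly.area
    perimeter = poly.length
    if area <= 0 or perimeter <= 0:
        raise ValidationError("degenerate polygon: zero area or perimeter")
    return float(4.0 * np.pi * area / perimeter**2)


def animal_mean(measurements: np.ndarray) -> float:
    """Mean circularity over an animal's nine measurements.

    Three repeats on each of three cord sections give nine values; fewer
    are accepted with a logged warning, none is an error.
    """
    m = np.asarray(measurements, dtype=float)
    if m.size == 0:
        raise ValidationError("no circularity measurements for this animal")
    if m.size != 9:
        logger.warning("expected 9 measurements (3 sections x 3 repeats), got %d", m.size)
    return float(m.mean())


def group_test(animal_means: np.ndarray, reference_mean: float) -> GroupTestResult:
    """One-sample, two-tailed t test of animal means vs a control value.

    Also reports the 95% confidence interval of the group mean,
    ``mean +/- t_{0.975, n-1} * SD / sqrt(n)``.
    """
    x = np.asarray(animal_means, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 animal means for a group test")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        if mean == reference_mean:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.inf * np.sign(mean - reference_mean)), 0.0
        return GroupTestResult(n, mean, sd, reference_mean, t, p, (mean, mean))
    t, p = stats.ttest_1samp(x, reference_mean)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return GroupTestResult(
        n=n,
        mean=mean,
        sd=sd,
        reference=reference_mean,
        t_statistic=float(t),
        p_value=float(p),
        ci95=(mean - half, mean + half),
    )


def mask_to_outline(mask: np.ndarray, level: float = 0.5) -> np.ndarray:
    """Largest closed contour of a binary/float mask, as (x, y) vertices.

    Convenience marching-squares helper for rasterised section masks;
    coordinates are returned in pixel units (column = x, row = y).
    """
    from skimage import measure

    contours = measure.find_contours(np.asarray(mask, dtype=float), level)
    if not contours:
        raise ValidationError("no contour found at the requested level")
    best = max(contours, key=len)
    return np.column_stack([best[:, 1], best[:, 0]])
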