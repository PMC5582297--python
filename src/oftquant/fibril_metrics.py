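"""Myofibril bundle orientation and thickness metrics.

Bundle orientation is described by two in-plane angles measured in a fixed
sample frame (x = circumferential, y = longitudinal, z = radial):

* ``phi`` — angle of the bundle's xy-plane projection relative to the
  x-axis (circumferential plane).  ``phi = 0`` is circumferential
  alignment, ``phi = 90`` longitudinal.
* ``theta`` — angle of the bundle's xz-plane projection relative to the
  z-axis (radial plane).  ``theta = 0`` is radial alignment, ``theta = 90``
  circumferential or longitudinal.

Because a fibril axis has no preferred sign, raw planar angles of a and
180 - a degrees describe the same orientation; every angle is therefore
folded into [0, 90].  Orientation *distributions* within a sample are the
comparable quantity (absolute sample orientation is arbitrary), summarized
by the maximum fraction of bundles falling in a sliding angular window.

Bundle thickness is measured as the 3D Euclidean length of annotated
Z-lines, averaged over all bundles in a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: Relative projection magnitude below which a planar angle is undefined.
PROJECTION_TOL = 1e-6

#: Default sliding-window width for the orientation concentration statistic.
DEFAULT_WINDOW_DEG = 20.0

#: Window scan step in degrees.
WINDOW_STEP_DEG = 0.5


@dataclass(frozen=True)
class BundleAnnotation:
    """A myofibril bundle: its axis direction and Z-line endpoint pairs.

    ``axis_vector`` has arbitrary sign and magnitude.  ``zlines`` is a
    sequence of ``((x1, y1, z1), (x2, y2, z2))`` endpoint pairs in nm.
    """

    bundle_id: str
    axis_vector: tuple[float, float, float]
    zlines: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...]

    def __post_init__(self) -> None:
        if not any(c != 0.0 for c in self.axis_vector):
            raise ValueError(f"bundle {self.bundle_id}: axis vector is zero")
        if len(self.zlines) < 1:
            raise ValueError(f"bundle {self.bundle_id}: needs at least one Z-line")


@dataclass(frozen=True)
class OrientationAngles:
    """Folded orientation angles in degrees; ``None`` marks a degenerate
    (near-zero) projection for which the angle is undefined."""

    phi: float | None
    theta: float | None


@dataclass(frozen=True)
class OrientationSummary:
    angles: tuple[float, ...]
    bin_width: float
    histogram: tuple[int, ...]
    max_window_fraction: float
    window_width: float


@dataclass(frozen=True)
class ThicknessSummary:
    """Z-line lengths (nm) pooled over bundles, with summary statistics."""

    lengths_nm: tuple[float, ...]
    mean: float
    q1: float
    median: float
    q3: float
    min: float
    max: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample pooled-variance Student's t-test result."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float


def fold_angle(raw_deg: float) -> float:
    """Fold a raw planar angle into [0, 90] degrees.

    A fibril axis is unsigned, so raw angles ``a`` and ``180 - a`` are the
    same orientation; the folded angle is ``min(a, 180 - a)`` after
    reducing ``a`` modulo 180.  Idempotent: folding a folded angle is a
    no-op.

    >>> fold_angle(175.0)
    5.0
    """
    a = float(raw_deg) % 180.0
    return min(a, 180.0 - a)


def compute_orientation(axis_vector: Sequence[float]) -> OrientationAngles:
    """Folded phi/theta angles of a bundle axis vector.

    phi is the folded angle between the xy-projection and the x-axis;
    theta the folded angle between the xz-projection and the z-axis.
    A projection whose magnitude is below ``PROJECTION_TOL`` times the
    vector norm yields an undefined (``None``) angle.  Sign-invariant:
    ``v`` and ``-v`` give identical angles.
    """
    v = np.asarray(axis_vector, dtype=float)
    if v.shape != (3,):
        raise ValueError("axis vector must have three components")
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError("axis vector is zero")
    x, y, z = (float(c) for c in v)

    phi: float | None
    theta: float | None
    if math.hypot(x, y) < PROJECTION_TOL * norm:
        phi = None
    else:
        phi = fold_angle(math.degrees(math.atan2(y, x)))
    if math.hypot(x, z) < PROJECTION_TOL * norm:
        theta = None
    else:
        # angle of the xz projection measured from the z-axis
        theta = fold_angle(math.degrees(math.atan2(x, z)))
    return OrientationAngles(phi=phi, theta=theta)


def concentration_statistic(
    angles: Iterable[float],
    window_width: float = DEFAULT_WINDOW_DEG,
    step: float = WINDOW_STEP_DEG,
) -> float:
    """Maximum fraction of folded angles inside any ``window_width`` window.

    Windows ``[s, s + window_width]`` (closed) are scanned over
    ``s in [0, 90 - window_width]`` at ``step``-degree increments.  No
    wraparound is applied: folding already removes periodicity beyond 90.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size == 0:
        raise ValueError("concentration statistic requires at least one angle")
    if np.any((arr < 0) | (arr > 90)):
        raise ValueError("angles must be folded into [0, 90]")
    if not 0 < window_width <= 90:
        raise ValueError("window width must be in (0, 90]")
    starts = np.arange(0.0, 90.0 - window_width + step / 2, step)
    if starts.size == 0 or starts[-1] < 90.0 - window_width:
        starts = np.append(starts, 90.0 - window_width)
    counts = (
        (arr[None, :] >= starts[:, None])
        & (arr[None, :] <= (starts + window_width)[:, None])
    ).sum(axis=1)
    return float(counts.max() / arr.size)


def summarize_orientation(
    angles: Iterable[float],
    window_width: float = DEFAULT_WINDOW_DEG,
    bin_width: float = 10.0,
) -> OrientationSummary:
    """Histogram + concentration summary of a sample's folded angles."""
    arr = np.asarray([a for a in angles if a is not None], dtype=float)
    if arr.size == 0:
        raise ValueError("no defined angles to summarize")
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    edges[-1] = 90.0 + 1e-9  # right-close the last bin
    hist, _ = np.histogram(arr, bins=edges)
    return OrientationSummary(
        angles=tuple(float(a) for a in arr),
        bin_width=float(bin_width),
        histogram=tuple(int(c) for c in hist),
        max_window_fraction=concentration_statistic(arr, window_width),
        window_width=float(window_width),
    )


def zline_length_nm(
    endpoints: tuple[tuple[float, float, float], tuple[float, float, float]],
) -> float:
    """3D Euclidean distance between Z-line endpoints (nm)."""
    p1 = np.asarray(endpoints[0], dtype=float)
    p2 = np.asarray(endpoints[1], dtype=float)
    d = float(np.linalg.norm(p2 - p1))
    if d == 0.0:
        raise ValueError("Z-line endpoints coincide (zero length)")
    return d


def mean_bundle_thickness(annotations: Iterable[BundleAnnotation]) -> ThicknessSummary:
    """Bundle thickness proxy: pooled Z-line lengths over all bundles.

    Each Z-line length is the 3D distance between its annotated endpoints;
    the sample-level thickness is the mean over every Z-line of every
    bundle, with quartiles for box-plot style reporting.
    """
    lengths = [
        zline_length_nm(zl) for ann in annotations for zl in ann.zlines
    ]
    if not lengths:
        raise ValueError("no Z-lines to measure")
    arr = np.asarray(lengths, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return ThicknessSummary(
        lengths_nm=tuple(float(x) for x in arr),
        mean=float(arr.mean()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Two-sample pooled-variance (Student) t-test, two-tailed.

    Degenerate case: if both groups have zero variance and equal means the
    result is t = 0, p = 1 by convention; zero variance with unequal means
    is an error (the statistic is unbounded).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    if var_a == 0.0 and var_b == 0.0:
        if float(a.mean()) == float(b.mean()):
            return GroupComparison(
                mean_a=float(a.mean()), sd_a=0.0, n_a=int(a.size),
                mean_b=float(b.mean()), sd_b=0.0, n_b=int(b.size),
                t=0.0, p=1.0,
            )
        raise ValueError("zero pooled variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t=float(res.statistic), p=float(res.pvalue),
    )
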