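"""Per-signal intensity and inner/outer-disk signal-to-noise statistics.

Each retained signal is scored by the ratio r of the maximum intensity in
an inner disk (radius 3 px by default) centered on the signal to the
standard deviation of the pixels in the surrounding annulus out to the
outer radius (7 px by default); SNR in decibels is 20*log10(r). Signals
whose neighborhoods overlap another signal, another object, or the image
border are excluded first, so each annulus samples only local background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .detect import SignalObject

__all__ = [
    "DiskGeometry",
    "SNRMeasurement",
    "exclude_overlapping",
    "measure_snr",
    "summarize_intensity",
    "compare_groups",
]


@dataclass(frozen=True)
class DiskGeometry:
    """Inner (signal) and outer (local background) disk radii in pixels.
    The study default is (3, 7); (5, 12) is the robustness alternative."""

    inner_radius_px: float = 3.0
    outer_radius_px: float = 7.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_px < self.outer_radius_px:
            raise ValueError("require 0 < inner_radius < outer_radius")


@dataclass(frozen=True)
class SNRMeasurement:
    signal_id: int
    peak_intensity: float
    local_sd: float
    ratio_r: float
    snr_db: float


def _disk_pixels(
    center: tuple[float, float],
    radius: float,
    image_shape: tuple[int, int],
    inner_exclusive_radius: float = -1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates with inner_exclusive < dist(center) <= radius."""
    h, w = image_shape
    r0 = max(0, int(math.floor(center[0] - radius)))
    r1 = min(h - 1, int(math.ceil(center[0] + radius)))
    c0 = max(0, int(math.floor(center[1] - radius)))
    c1 = min(w - 1, int(math.ceil(center[1] + radius)))
    rows = np.arange(r0, r1 + 1)[:, None]
    cols = np.arange(c0, c1 + 1)[None, :]
    d = np.sqrt((rows - center[0]) ** 2 + (cols - center[1]) ** 2)
    sel = (d <= radius) & (d > inner_exclusive_radius)
    rr, cc = np.nonzero(sel)
    return rr + r0, cc + c0


def exclude_overlapping(
    centers: Sequence[tuple[float, float]],
    geometry: DiskGeometry,
    all_objects: Sequence[SignalObject],
    image_shape: tuple[int, int],
) -> list[int]:
    """Indices of signals whose neighborhood is unique to them.

    A signal is retained iff (a) its outer disk lies fully inside the
    image, (b) no other candidate center lies within twice the outer
    radius (both members of a too-close pair are dropped; the criterion is
    evaluated on all candidates simultaneously, not greedily), and (c) no
    pixel of any other object intersects its outer disk.
    """
    R = geometry.outer_radius_px
    h, w = image_shape
    centers = [np.asarray(c, dtype=float) for c in centers]
    n = len(centers)
    retained = []
    for i, c in enumerate(centers):
        if c[0] - R < 0 or c[0] + R > h - 1 or c[1] - R < 0 or c[1] + R > w - 1:
            continue
        too_close = any(
            j != i and float(np.hypot(*(centers[j] - c))) < 2 * R
            for j in range(n)
        )
        if too_close:
            continue
        # (c) pixels of any *other* object inside the outer disk; an
        # object owns this center if the center falls inside its pixel set
        rr, cc = _disk_pixels((c[0], c[1]), R, image_shape)
        disk = set(zip(rr.tolist(), cc.tolist()))
        center_px = (int(round(c[0])), int(round(c[1])))
        clash = any(
            center_px not in obj.pixels and not disk.isdisjoint(obj.pixels)
            for obj in all_objects
        )
        if not clash:
            retained.append(i)
    return retained


def measure_snr(
    corrected: np.ndarray,
    center: tuple[float, float],
    geometry: DiskGeometry,
    signal_id: int = 0,
) -> SNRMeasurement:
    """SNR of one signal: peak intensity within the inner disk over the
    sample SD of the annulus between inner and outer radius.

    Raises ValueError when the outer disk leaves the image or the local SD
    is zero (degenerate background).
    """
    corrected = np.asarray(corrected, dtype=float)
    h, w = corrected.shape
    R = geometry.outer_radius_px
    if center[0] - R < 0 or center[0] + R > h - 1 \
            or center[1] - R < 0 or center[1] + R > w - 1:
        raise ValueError("outer disk extends beyond the image")
    rr, cc = _disk_pixels(center, geometry.inner_radius_px, corrected.shape)
    peak = float(corrected[rr, cc].max())
    ar, ac = _disk_pixels(center, R, corrected.shape,
                          inner_exclusive_radius=geometry.inner_radius_px)
    annulus = corrected[ar, ac]
    sd = float(np.std(annulus, ddof=1))
    if sd == 0:
        raise ValueError("degenerate background: zero local SD")
    r = peak / sd
    return SNRMeasurement(signal_id, peak, sd, r, 20.0 * math.log10(r))


def summarize_intensity(measurements: Sequence[SNRMeasurement]) -> dict:
    """Mean, sample SD (n-1), SEM and n for peak intensity and dB SNR."""
    if len(measurements) == 0:
        raise ValueError("no measurements to summarize")
    out: dict = {"n": len(measurements)}
    for key, values in (
        ("peak_intensity", [m.peak_intensity for m in measurements]),
        ("snr_db", [m.snr_db for m in measurements]),
    ):
        v = np.asarray(values, dtype=float)
        mean = float(v.mean())
        if v.size > 1:
            sd = float(v.std(ddof=1))
            sem = sd / math.sqrt(v.size)
        else:
            sd = float("nan")
            sem = float("nan")
        out[key] = {"mean": mean, "sd": sd, "sem": sem}
    return out


def compare_groups(a: Sequence[float], b: Sequence[float],
                   alpha: float = 0.05) -> dict:
    """Two-group comparison with a normality gate.

    Each group is checked for normality with a one-sample
    Kolmogorov-Smirnov test against a normal law with the group's mean and
    SD (alpha = 0.05). If both groups pass, a two-tailed t-test is used;
    otherwise a two-sided Mann-Whitney U test. The report names the test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if np.std(np.concatenate([a, b])) == 0:
        return {"test": "degenerate", "p_value": 1.0,
                "normal": (False, False),
                "note": "all values identical in both groups"}

    def _normal(x: np.ndarray) -> bool:
        sd = x.std(ddof=1)
        if sd == 0:
            return False
        return stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue >= alpha

    na, nb = _normal(a), _normal(b)
    if na and nb:
        stat, p = stats.ttest_ind(a, b)
        test = "t-test"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann-whitney-u"
    return {"test": test, "statistic": float(stat), "p_value": float(p),
            "normal": (na, nb)}
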