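"""Two-channel signal overlap measures.

Two experimental readouts are covered:

* slide images: pixel-level intersection-over-union of the two binarized
  channels after Gaussian smoothing (``pixel_overlap``);
* solution-phase confocal line scans: object-level classification of each
  RCP as single- or dual-channel positive using a photomultiplier-tube
  (PMT) intensity threshold of 35 and a 2-30 px size gate
  (``classify_solution_rcps``), with a one-way ANOVA + Fisher's LSD dose
  response test across compaction-oligonucleotide concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "OverlapResult",
    "SolutionRCP",
    "pixel_overlap",
    "classify_solution_rcps",
    "dose_response_test",
]


@dataclass(frozen=True)
class OverlapResult:
    """Foreground intersection-over-union of two binarized channels."""

    n_intersection_px: int
    n_union_px: int
    overlap_fraction: float
    threshold: float
    empty_union: bool = False


@dataclass(frozen=True)
class SolutionRCP:
    """One solution-phase RCP entity merged across channels.

    ``class_label`` is ``ch1_only``, ``ch2_only`` or ``dual`` depending on
    which channels exceed the PMT threshold within the entity footprint.
    """

    object_id: int
    pixels: frozenset[tuple[int, int]]
    area_px: int
    ch1_value: float
    ch2_value: float
    class_label: str


def pixel_overlap(
    img1: np.ndarray,
    img2: np.ndarray,
    binarization_threshold: float,
    smoothing_sigma_px: float = 1.0,
) -> OverlapResult:
    """Gaussian-filter both channels, binarize at >= the same fixed
    threshold, and report intersection / union of foreground pixels.
    An empty union yields overlap 0 with ``empty_union=True``."""
    img1 = np.asarray(img1, dtype=float)
    img2 = np.asarray(img2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("channel images must share a shape")
    if binarization_threshold <= 0:
        raise ValueError("threshold must be positive")
    if smoothing_sigma_px > 0:
        img1 = ndimage.gaussian_filter(img1, smoothing_sigma_px)
        img2 = ndimage.gaussian_filter(img2, smoothing_sigma_px)
    m1 = img1 >= binarization_threshold
    m2 = img2 >= binarization_threshold
    inter = int(np.logical_and(m1, m2).sum())
    union = int(np.logical_or(m1, m2).sum())
    if union == 0:
        return OverlapResult(0, 0, 0.0, binarization_threshold, empty_union=True)
    return OverlapResult(inter, union, inter / union, binarization_threshold)


def classify_solution_rcps(
    ch1: np.ndarray,
    ch2: np.ndarray,
    pmt_threshold: float = 35.0,
    size_range: tuple[int, int] = (2, 30),
    positivity: str = "any",
) -> tuple[list[SolutionRCP], float]:
    """Detect and classify solution-phase RCPs in a two-channel image.

    Objects are detected per channel at >= ``pmt_threshold``, retained when
    their area lies in ``size_range`` (endpoints inclusive), and merged
    across channels into one RCP entity when their pixel sets intersect.
    An entity is positive in a channel when any of its pixels reaches the
    threshold there (``positivity="any"``); ``positivity="mean"`` uses the
    entity's mean channel intensity instead. Returns the entities and the
    dual fraction (dual / total); the fraction is 0 when nothing is found.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channel images must share a shape")
    if positivity not in ("any", "mean"):
        raise ValueError("positivity must be 'any' or 'mean'")
    lo, hi = size_range

    def _channel_objects(img: np.ndarray) -> list[frozenset[tuple[int, int]]]:
        labels = measure.label(img >= pmt_threshold, connectivity=2)
        out = []
        for lab in range(1, labels.max() + 1):
            rows, cols = np.nonzero(labels == lab)
            if lo <= rows.size <= hi:
                out.append(frozenset(zip(rows.tolist(), cols.tolist())))
        return out

    parts = _channel_objects(ch1) + _channel_objects(ch2)
    # merge parts whose pixel sets intersect into entities (union-find)
    parent = list(range(len(parts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(parts)), 2):
        if not parts[i].isdisjoint(parts[j]):
            parent[find(i)] = find(j)

    groups: dict[int, set[tuple[int, int]]] = {}
    for i, part in enumerate(parts):
        groups.setdefault(find(i), set()).update(part)

    entities: list[SolutionRCP] = []
    n_dual = 0
    for oid, pixels in enumerate(groups.values()):
        rows = np.array([p[0] for p in pixels])
        cols = np.array([p[1] for p in pixels])
        if positivity == "any":
            v1 = float(ch1[rows, cols].max())
            v2 = float(ch2[rows, cols].max())
        else:
            v1 = float(ch1[rows, cols].mean())
            v2 = float(ch2[rows, cols].mean())
        pos1 = v1 >= pmt_threshold
        pos2 = v2 >= pmt_threshold
        label = "dual" if (pos1 and pos2) else ("ch1_only" if pos1 else "ch2_only")
        n_dual += label == "dual"
        entities.append(SolutionRCP(
            object_id=oid,
            pixels=frozenset(pixels),
            area_px=len(pixels),
            ch1_value=v1,
            ch2_value=v2,
            class_label=label,
        ))
    dual_fraction = n_dual / len(entities) if entities else 0.0
    return entities, dual_fraction


def dose_response_test(groups: dict[str, list[float]]) -> dict:
    """One-way ANOVA across condition groups with Fisher's LSD post hoc.

    LSD pairwise comparisons are unadjusted two-sided t-tests using the
    pooled within-group mean square error from the ANOVA. Groups with zero
    variance and n = 2 are reported and excluded from the post hoc with a
    warning flag.
    """
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) < 2 for g in names):
        raise ValueError("need >= 2 groups with n >= 2 each")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    f_stat, p = stats.f_oneway(*arrays.values())

    n_total = sum(len(a) for a in arrays.values())
    k = len(names)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / (n_total - k)
    df = n_total - k

    warnings = [g for g in names
                if len(arrays[g]) == 2 and arrays[g].std() == 0]
    post_hoc = {}
    for g1, g2 in combinations(names, 2):
        if g1 in warnings or g2 in warnings:
            continue
        a, b = arrays[g1], arrays[g2]
        se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        t = (a.mean() - b.mean()) / se
        p_pair = 2 * stats.t.sf(abs(t), df)
        post_hoc[f"{g1} vs {g2}"] = {"t": float(t), "p_value": float(p_pair)}
    return {
        "anova_F": float(f_stat),
        "anova_p": float(p),
        "mse": float(mse),
        "df_within": df,
        "post_hoc": post_hoc,
        "excluded_from_post_hoc": warnings,
    }
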