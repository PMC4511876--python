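import numpy as np
import pytest

import rcpquant as rq


@pytest.fixture(scope="session")
def compact_scene():
    """Default compact scene: 100 RCPs per color, 512x512, 16 z-levels."""
    cfg = rq.SceneConfig(mode="compact", seed=42)
    stacks, truth = rq.generate_scene(cfg)
    return cfg, stacks, truth


@pytest.fixture(scope="session")
def dispersed_scene():
    """Dispersed scene paired with compact_scene (same seed -> same parents)."""
    cfg = rq.SceneConfig(mode="dispersed", seed=42)
    stacks, truth = rq.generate_scene(cfg)
    return cfg, stacks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_same_color_frequency(points: np.ndarray) -> float:
    """O(n^2) oracle: directed nearest neighbor by exhaustive all-pairs
    distances, ties toward the smallest (row, col)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    same = 0
    for i in range(n):
        best = None
        best_d = np.inf
        for j in range(n):
            if j == i:
                continue
            d = np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
            key = (d, pts[j, 0], pts[j, 1])
            if best is None or key < (best_d, pts[best, 0], pts[best, 1]):
                best = j
                best_d = d
        if pts[best, 2] == pts[i, 2]:
            same += 1
    return same / n


def flood_fill_objects(mask: np.ndarray) -> list[dict]:
    """Naive 8-connected flood-fill oracle returning per-object pixel sets,
    areas and 4-neighbor boundary edge counts."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    objects = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                pix = []
                while stack:
                    r, c = stack.pop()
                    pix.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and \
                                    mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                perim = 0
                for r, c in pix:
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                        if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                            perim += 1
                objects.append({
                    "pixels": set(pix), "area": len(pix), "perimeter": perim,
                })
    return objects
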