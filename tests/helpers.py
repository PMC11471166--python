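"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: connected
components by BFS flood fill instead of scipy labeling, AUC by O(n^2)
pairwise ranking instead of the trapezoid rule, and the Wilson interval
from its closed form instead of statsmodels.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.stats import norm


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """All 3D connected components of a binary array via BFS flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(v[i] + off[i] for i in range(3))
                if any(c < 0 or c >= mask.shape[i] for i, c in enumerate(w)):
                    continue
                if mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        components.append(comp)
    return components


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random positive outranks random negative), ties counted half."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def wilson_closed_form(k: int, n: int, confidence: float = 0.95):
    """Wilson score interval from its closed-form expression."""
    z = norm.ppf(0.5 + confidence / 2.0)
    phat = k / n
    denom = 1.0 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)
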