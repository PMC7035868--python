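"""Independent brute-force oracles used to cross-check the library.

Everything here is deliberately written from first principles, sharing no
code with the package: quadratic-time rank computation, the textbook
tie-corrected normal approximation to the Mann-Whitney U null, the
threshold form of Benjamini-Hochberg, and a winding-number point-in-polygon
test.
"""

from __future__ import annotations

import math


def midranks(values) -> list[float]:
    """Average ranks (1-based) computed by pairwise comparison, O(n^2)."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def mwu_normal_p(x, y) -> tuple[float, float]:
    """Tie-corrected normal-approximation Mann-Whitney test, no continuity
    correction. Returns (U of x, two-sided p)."""
    x, y = list(map(float, x)), list(map(float, y))
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = x + y
    ranks = midranks(pooled)
    u = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    mean = n1 * n2 / 2.0
    tie_term = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie_term += t**3 - t
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    z = (u - mean) / math.sqrt(var)
    return u, min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))


def brute_bh(p_values) -> list[float]:
    """Benjamini-Hochberg via its threshold characterization:
    q_i = min over thresholds t >= p_i of m * t / #{j: p_j <= t}, capped at 1."""
    p = list(map(float, p_values))
    m = len(p)
    out = []
    for pi in p:
        candidates = [
            m * t / sum(1 for q in p if q <= t) for t in p if t >= pi
        ]
        out.append(min(1.0, min(candidates)))
    return out


def winding_number_inside(point, polygon) -> bool:
    """Nonzero winding number test for a point against a closed polygon."""
    px, py = point
    wn = 0
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        is_left = (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)
        if y1 <= py:
            if y2 > py and is_left > 0:
                wn += 1
        else:
            if y2 <= py and is_left < 0:
                wn -= 1
    return wn != 0


def random_convex_polygon(rng, n_vertices: int):
    """Convex polygon as the ordered hull of points on a random ellipse."""
    angles = sorted(rng.uniform(0, 2 * math.pi, size=n_vertices))
    a, b = rng.uniform(0.5, 3.0, size=2)
    cx, cy = rng.uniform(-2, 2, size=2)
    return [
        (cx + a * math.cos(t), cy + b * math.sin(t)) for t in angles
    ]
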