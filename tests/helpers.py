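"""Naive loop-based oracles used only by the tests.

These re-derive each statistic with plain Python loops so the vectorised
implementations are checked against an independent route.
"""

from __future__ import annotations

import math


def nearest_cell_oracle(georef, shape, lon, lat):
    """Nearest-cell lookup by scanning every cell center."""
    rows, cols = shape
    best = None
    best_d2 = math.inf
    for r in range(rows):
        for c in range(cols):
            clon = georef.west + (c + 0.5) * georef.dx
            clat = georef.north - (r + 0.5) * georef.dy
            d2 = (clon - lon) ** 2 + (clat - lat) ** 2
            if d2 < best_d2:
                best_d2, best = d2, (r, c)
    return best


def partition_oracle(values, classes, areas, mask, total_scale=1e-6):
    """Per-cell accumulation of zonal statistics. Returns dict per class code."""
    acc: dict[int, dict] = {}
    total_area = 0.0
    grand_total = 0.0
    rows, cols = values.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                continue
            total_area += areas[r, c]
            grand_total += values[r, c] * areas[r, c]
            code = int(classes[r, c])
            a = acc.setdefault(code, {"area": 0.0, "wsum": 0.0, "max": -math.inf})
            a["area"] += areas[r, c]
            a["wsum"] += values[r, c] * areas[r, c]
            a["max"] = max(a["max"], values[r, c])
    out = {}
    for code, a in acc.items():
        out[code] = {
            "area_km2": a["area"],
            "area_pct": 100.0 * a["area"] / total_area,
            "mean_value": a["wsum"] / a["area"],
            "max_value": a["max"],
            "total": a["wsum"] * total_scale,
            "total_pct": 100.0 * a["wsum"] / grand_total,
        }
    return out


def histogram_oracle(values, mask, edges):
    """Naive counting with [lo, hi) bins, last bin closed."""
    counts = [0] * (len(edges) - 1)
    rows, cols = values.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c]:
                continue
            v = values[r, c]
            for i in range(len(edges) - 1):
                hi_ok = v < edges[i + 1] or (i == len(edges) - 2 and v == edges[i + 1])
                if edges[i] <= v and hi_ok:
                    counts[i] += 1
                    break
    return counts
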