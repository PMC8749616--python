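"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain Python loops over pixels and
matrix cells, deliberately sharing no code with the package: histogram
statistics from a pixel tally, Haralick features from a dict-based
co-occurrence table, and an even-odd point-in-polygon test.
"""

from __future__ import annotations

import math
from collections import Counter


def naive_hs(plane, mask, levels=256, radii=(1, 10)):
    values = [int(plane[i][j]) for i in range(len(plane)) for j in range(len(plane[0])) if mask[i][j]]
    n = len(values)
    tally = Counter(values)
    h = [tally.get(k, 0) / n for k in range(levels)]

    mean = sum(k * h[k] for k in range(levels))
    var = sum((k - mean) ** 2 * h[k] for k in range(levels))
    m3 = sum((k - mean) ** 3 * h[k] for k in range(levels))
    m4 = sum((k - mean) ** 4 * h[k] for k in range(levels))
    skew = m3 / var**1.5 if var > 0 else 0.0
    kurt = m4 / var**2 - 3.0 if var > 0 else 0.0

    out = {"Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt}
    for qq in (1, 10, 50, 90, 99):
        acc = 0.0
        for k in range(levels):
            acc += h[k]
            if acc >= qq / 100 - 1e-12:
                out[f"Perc{qq:02d}"] = float(k)
                break
    for r in radii:
        r_eff = min(r, levels)
        best_k, best_count = 0, -1
        for k in range(levels - r_eff + 1):
            count = sum(tally.get(k + j, 0) for j in range(r_eff))
            if count > best_count:
                best_k, best_count = k, count
        out[f"Domn{r:02d}"] = float(best_k)
        out[f"Maxm{r:02d}"] = best_count / n
    return out


def naive_cooccurrence(plane, mask, offset=(0, 1), symmetric=False):
    """Dict of (k, l) -> probability over in-ROI ordered pairs."""
    nrow, ncol = len(plane), len(plane[0])
    dr, dc = offset
    counts: Counter = Counter()
    for i in range(nrow):
        for j in range(ncol):
            i2, j2 = i + dr, j + dc
            if mask[i][j] and 0 <= i2 < nrow and 0 <= j2 < ncol and mask[i2][j2]:
                counts[(int(plane[i][j]), int(plane[i2][j2]))] += 1
                if symmetric:
                    counts[(int(plane[i2][j2]), int(plane[i][j]))] += 1
    total = sum(counts.values())
    return {kl: c / total for kl, c in counts.items()}


def naive_glcm_features(p: dict):
    mu_k = sum(k * v for (k, _), v in p.items())
    mu_l = sum(l * v for (_, l), v in p.items())
    var_k = sum((k - mu_k) ** 2 * v for (k, _), v in p.items())
    var_l = sum((l - mu_l) ** 2 * v for (_, l), v in p.items())
    sd_k, sd_l = math.sqrt(var_k), math.sqrt(var_l)

    p_sum: Counter = Counter()
    p_diff: Counter = Counter()
    for (k, l), v in p.items():
        p_sum[k + l] += v
        p_diff[abs(k - l)] += v

    if sd_k * sd_l > 0:
        correlat = (sum(k * l * v for (k, l), v in p.items()) - mu_k * mu_l) / (sd_k * sd_l)
    else:
        correlat = 0.0
    sum_averg = sum(m * v for m, v in p_sum.items())
    diff_mean = sum(m * v for m, v in p_diff.items())
    return {
        "AngScMom": sum(v * v for v in p.values()),
        "Contrast": sum(m * m * v for m, v in p_diff.items()),
        "Correlat": correlat,
        "SumOfSqs": var_k,
        "InvDefMom": sum(v / (1 + m * m) for m, v in p_diff.items()),
        "SumAverg": sum_averg,
        "SumVarnc": sum((m - sum_averg) ** 2 * v for m, v in p_sum.items()),
        "SumEntrp": -sum(v * math.log(v) for v in p_sum.values() if v > 0),
        "Entropy": -sum(v * math.log(v) for v in p.values() if v > 0),
        "DifVarnc": sum((m - diff_mean) ** 2 * v for m, v in p_diff.items()),
        "DifEntrp": -sum(v * math.log(v) for v in p_diff.values() if v > 0),
    }


def point_in_polygon_evenodd(r, c, vertices):
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            if c < c1 + (r - r1) / (r2 - r1) * (c2 - c1):
                inside = not inside
    return inside
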