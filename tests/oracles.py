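"""Independent brute-force oracles used by the test suite.

Everything here is written as plain python loops over pixels/values, kept
deliberately independent of the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_otsu(values) -> float | None:
    """Exhaustive Otsu threshold: maximize between-class variance over every
    candidate split of the sorted unique values.  Returns a threshold t such
    that the foreground is ``v > t``, or None when no split separates two
    non-empty classes."""
    vals = sorted(float(v) for v in values)
    uniq = sorted(set(vals))
    if len(uniq) < 2:
        return None
    best_t, best_score = None, -1.0
    n = len(vals)
    for t in uniq[:-1]:  # threshold between t and the next unique value
        lo = [v for v in vals if v <= t]
        hi = [v for v in vals if v > t]
        w0, w1 = len(lo) / n, len(hi) / n
        m0 = sum(lo) / len(lo)
        m1 = sum(hi) / len(hi)
        score = w0 * w1 * (m0 - m1) ** 2
        if score > best_score:
            best_score, best_t = score, t
    return best_t


def oracle_far(
    dapi,
    actin,
    roi_mask,
    background=(0.0, 0.0),
    dapi_threshold=None,
    actin_threshold=None,
    denominator="actin_positive",
):
    """Pixel-loop FAR computation.

    Thresholds of None mean "brute-force Otsu on the in-ROI values".
    Returns ``(far_percent, nuclear_sum, total_sum)``; far is NaN when the
    denominator is zero.  Matches the pipeline's definitions: background
    subtraction clipped at zero, strict ``>`` thresholds, numerator over the
    nucleus/actin-positive intersection.
    """
    dapi = np.asarray(dapi, dtype=float)
    actin = np.asarray(actin, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    h, w = dapi.shape
    dsub = [[max(dapi[r][c] - background[0], 0.0) for c in range(w)] for r in range(h)]
    asub = [[max(actin[r][c] - background[1], 0.0) for c in range(w)] for r in range(h)]

    in_roi = [(r, c) for r in range(h) for c in range(w) if roi_mask[r][c]]
    dthr = dapi_threshold
    if dthr is None:
        dthr = brute_otsu([dsub[r][c] for r, c in in_roi])
    athr = actin_threshold
    if athr is None:
        athr = brute_otsu([asub[r][c] for r, c in in_roi])

    nuclear_px = set()
    if dthr is not None:
        nuclear_px = {(r, c) for r, c in in_roi if dsub[r][c] > dthr}
    actin_px = set()
    if athr is not None:
        actin_px = {(r, c) for r, c in in_roi if asub[r][c] > athr}

    if denominator == "actin_positive":
        total = sum(asub[r][c] for r, c in actin_px)
        nuclear = sum(asub[r][c] for r, c in actin_px & nuclear_px)
    else:
        total = sum(asub[r][c] for r, c in in_roi)
        nuclear = sum(asub[r][c] for r, c in nuclear_px)
    far = 100.0 * nuclear / total if total > 0 else float("nan")
    return far, nuclear, total


def raycast_mask(vertices, shape):
    """Reference polygon rasterization: per-pixel ray casting with an
    explicit on-boundary check, pixel centers at (r+0.5, c+0.5)."""
    v = [(float(a), float(b)) for a, b in vertices]
    n = len(v)
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            py, px = r + 0.5, c + 0.5
            inside = False
            on_edge = False
            for i in range(n):
                y1, x1 = v[i]
                y2, x2 = v[(i + 1) % n]
                cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
                if (
                    abs(cross) < 1e-9
                    and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
                    and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9
                ):
                    on_edge = True
                    break
                if (y1 > py) != (y2 > py):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xint:
                        inside = not inside
            mask[r, c] = inside or on_edge
    return mask


def student_t_p(group, control):
    """Textbook equal-variance two-sample t-test (two-sided p)."""
    from scipy.stats import t as tdist

    g = [float(x) for x in group]
    c = [float(x) for x in control]
    ng, nc = len(g), len(c)
    mg = sum(g) / ng
    mc = sum(c) / nc
    ssg = sum((x - mg) ** 2 for x in g)
    ssc = sum((x - mc) ** 2 for x in c)
    df = ng + nc - 2
    sp2 = (ssg + ssc) / df
    t = (mg - mc) / (sp2 * (1.0 / ng + 1.0 / nc)) ** 0.5
    return 2.0 * float(tdist.sf(abs(t), df))
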