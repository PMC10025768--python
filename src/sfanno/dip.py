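"""Hartigan's dip statistic and a bootstrap unimodality test.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and the class of unimodal distribution functions (convex below the mode,
concave above it).  It is computed with the classical iterative greatest
convex minorant / least concave majorant scheme of Hartigan & Hartigan
(1985): repeatedly fit the two envelopes on the current interval, find the
largest envelope gap, record the one-sided deviations outside the candidate
modal interval, and shrink the interval until the gap no longer exceeds the
recorded dip.  The returned value is floored at 1/(2n), the lower bound
attained by an equally spaced sample; a constant sample reports exactly
1/(2n) and p-value 1.

Significance is calibrated by parametric bootstrap against Uniform(0, 1)
samples of the same size (the asymptotically least favorable unimodal null).
Null dip tables are memoized per (n, n_boot, seed).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Tuple

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _gcm_pointers(x: np.ndarray) -> np.ndarray:
    """mn[j]: previous vertex of the greatest convex minorant through j (1-based)."""
    n = len(x) - 1
    mn = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    return mn


def _lcm_pointers(x: np.ndarray) -> np.ndarray:
    """mj[k]: next vertex of the least concave majorant through k (1-based)."""
    n = len(x) - 1
    mj = np.zeros(n + 2, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk
    return mj


def dip_statistic(samples) -> float:
    """Dip statistic of a 1-D sample (>= 1/(2n) by convention)."""
    xs = np.sort(np.asarray(samples, dtype=np.float64))
    n = len(xs)
    if n < 2:
        raise ValueError("dip statistic needs at least 2 observations")
    floor = 1.0 / (2.0 * n)
    if xs[0] == xs[-1]:
        return floor
    x = np.concatenate(([np.nan], xs))  # 1-based indexing

    mn = _gcm_pointers(x)
    mj = _lcm_pointers(x)

    low, high = 1, n
    dip = 1.0  # in count units; divided by 2n at the end

    while True:
        # gcm vertex chain from high down to low, lcm chain from low up to high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        gcm = np.array([0] + gcm)  # 1-based

        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)
        lcm = np.array([0] + lcm)  # 1-based

        ig, ih = l_gcm, l_lcm
        ix, iv = l_gcm - 1, 2

        if l_gcm != 2 or l_lcm != 2:
            # largest gap between the two envelopes, in count units
            d = 0.0
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next vertex comes from the LCM: gap at lcm[iv]
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    # next vertex comes from the GCM: gap at gcm[ix]
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # one-sided ECDF deviations outside the candidate modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                jj = np.arange(jb, je + 1)
                t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                dip_l = max(dip_l, 1.0, float(t.max()))
            else:
                dip_l = max(dip_l, 1.0)
        dip_u = 0.0
        for j in range(ih, l_lcm):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                jj = np.arange(jb, je + 1)
                t = (x[jj] - x[jb]) * C - (jj - jb - 1)
                dip_u = max(dip_u, 1.0, float(t.max()))
            else:
                dip_u = max(dip_u, 1.0)

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = int(gcm[ig]), int(lcm[ih])
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return max(dip / (2.0 * n), floor)


@lru_cache(maxsize=32)
def _null_dips(n: int, n_boot: int, seed: int) -> Tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.random(n)) for _ in range(n_boot))


def dip_test(samples, n_boot: int = 200, seed: int = 0) -> Tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    Deterministic given ``seed``; the p-value uses the add-one rule
    ``(1 + #{null dips >= dip}) / (1 + n_boot)`` so it is never exactly zero.
    """
    x = np.asarray(samples, dtype=np.float64)
    n = len(x)
    if n < 10:
        raise ValueError("dip test needs at least 10 observations")
    d = dip_statistic(x)
    if x.min() == x.max():
        return d, 1.0
    null = np.array(_null_dips(n, n_boot, int(seed)))
    p = (1.0 + float((null >= d).sum())) / (1.0 + n_boot)
    return d, p
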