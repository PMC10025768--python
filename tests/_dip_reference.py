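"""Independent brute-force dip oracle for small samples.

Minimizes sup|F_n - G| exactly over piecewise-linear unimodal CDFs (convex
then concave, with an atom allowed at the mode) by solving one LP per
candidate mode position.  Completely independent of the package's
envelope-based dip computation; assumes distinct sample values; small n only.
"""
import numpy as np
from scipy.optimize import linprog


def dip_lp(xs):
    xs = np.sort(np.asarray(xs, float))
    n = len(xs)
    assert len(set(xs)) == n, "oracle assumes distinct values"
    best = np.inf
    # variables: g_1..g_n, (optional gL), d  -> minimize d
    # bounds for non-mode knot i (1-based): i/n - d <= g_i <= (i-1)/n + d

    def solve(A_ub, b_ub, nvar):
        c = np.zeros(nvar); c[-1] = 1.0
        r = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * (nvar - 1) + [(0, None)],
                    method="highs")
        return r.fun if r.status == 0 else np.inf

    def band_rows(rows, i_knot, var, nvar, lo_cnt, hi_cnt):
        # lo_cnt/n - d <= g_var  and  g_var <= hi_cnt/n + d
        r = np.zeros(nvar); r[var] = -1.0; r[-1] = -1.0
        rows.append((r, -lo_cnt / n))
        r = np.zeros(nvar); r[var] = 1.0; r[-1] = -1.0
        rows.append((r, hi_cnt / n))

    def mono(rows, a, b, nvar):  # g_a <= g_b
        r = np.zeros(nvar); r[a] = 1.0; r[b] = -1.0
        rows.append((r, 0.0))

    def chord(rows, i, j, k, nvar, xi, xj, xk, convex=True):
        # convex: (g_j-g_i)/(xj-xi) <= (g_k-g_j)/(xk-xj)
        dij, djk = xj - xi, xk - xj
        r = np.zeros(nvar)
        r[i] = -djk; r[j] = djk + dij; r[k] = -dij
        if not convex:
            r = -r
        rows.append((r, 0.0))

    # mode at knot m (1-based), atom allowed: left chain g_0..g_{m-2}, gL; right chain g_{m-1}..g_{n-1}
    for m in range(1, n + 1):
        nvar = n + 2  # g_0..g_{n-1}, gL, d
        gL = n
        rows = []
        for i in range(1, n + 1):
            if i != m:
                band_rows(rows, i, i - 1, nvar, i, i - 1)
        # mode knot: m/n - d <= g_m <= m/n + d ; gL <= (m-1)/n + d
        band_rows(rows, m, m - 1, nvar, m, m)
        r = np.zeros(nvar); r[gL] = 1.0; r[-1] = -1.0
        rows.append((r, (m - 1) / n))
        # monotone: g_1<=...<=g_{m-1}<=gL<=g_m<=...<=g_n ; g_1 >= 0, g_n <= 1, gL >= 0
        chain_left = [i - 1 for i in range(1, m)] + [gL]
        chain_right = [i - 1 for i in range(m, n + 1)]
        full = chain_left + chain_right
        for a, b in zip(full[:-1], full[1:]):
            mono(rows, a, b, nvar)
        r = np.zeros(nvar); r[full[0]] = -1.0; rows.append((r, 0.0))
        r = np.zeros(nvar); r[full[-1]] = 1.0; rows.append((r, 1.0))
        # convex chords on left chain (positions x_1..x_{m-1}, x_m for gL)
        xs_left = list(xs[: m - 1]) + [xs[m - 1]]
        for a in range(len(chain_left) - 2):
            chord(rows, chain_left[a], chain_left[a + 1], chain_left[a + 2], nvar,
                  xs_left[a], xs_left[a + 1], xs_left[a + 2], convex=True)
        xs_right = list(xs[m - 1:])
        for a in range(len(chain_right) - 2):
            chord(rows, chain_right[a], chain_right[a + 1], chain_right[a + 2], nvar,
                  xs_right[a], xs_right[a + 1], xs_right[a + 2], convex=False)
        A = np.array([r for r, _ in rows]); b = np.array([v for _, v in rows])
        best = min(best, solve(A, b, nvar))

    # mode inside segment k (between knots k, k+1), sub-cases sA: s_k>=s_{k-1}, sB: s_k>=s_{k+1}
    for k in range(1, n):
        for case in ("A", "B"):
            nvar = n + 1
            rows = []
            for i in range(1, n + 1):
                band_rows(rows, i, i - 1, nvar, i, i - 1)
            for a in range(n - 1):
                mono(rows, a, a + 1, nvar)
            r = np.zeros(nvar); r[0] = -1.0; rows.append((r, 0.0))
            r = np.zeros(nvar); r[n - 1] = 1.0; rows.append((r, 1.0))
            # convex chords among segments 1..k-1, concave among k+1..n-1 (1-based segs)
            for s in range(1, k - 1):  # segments s, s+1 share knot s+1
                chord(rows, s - 1, s, s + 1, nvar, xs[s - 1], xs[s], xs[s + 1], convex=True)
            for s in range(k + 1, n - 1):
                chord(rows, s - 1, s, s + 1, nvar, xs[s - 1], xs[s], xs[s + 1], convex=False)
            if case == "A" and k >= 2:
                chord(rows, k - 2, k - 1, k, nvar, xs[k - 2], xs[k - 1], xs[k], convex=True)
            if case == "B" and k <= n - 2:
                chord(rows, k - 1, k, k + 1, nvar, xs[k - 1], xs[k], xs[k + 1], convex=False)
            A = np.array([r for r, _ in rows]); b = np.array([v for _, v in rows])
            best = min(best, solve(A, b, nvar))
    return best
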