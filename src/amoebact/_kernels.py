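"""Numba inner loops for per-window kernel shaping and aggregation.

Everything here works on one sliding window at a time (at most 81 pixels for
the default 9x9 window), so all scratch arrays are small and preallocated by
the callers in :mod:`amoebact.amoeba`.

Multilevel Otsu is solved by dynamic programming over a fixed 64-bin
quantization of the window's own intensity range.  The DP maximizes
``sum_k S_k^2 / C_k`` (class count ``C_k``, class value-sum ``S_k``), which is
equivalent to maximizing the between-class variance; it returns the same
optimum as exhaustive threshold search (asserted in the test suite) at
``O(N * 64^2)`` cost per window.
"""

import numpy as np
from numba import njit

NBINS = 64

__all__ = ["NBINS", "quantize_window", "otsu_dp", "pick_n_classes",
           "flood_fill", "rbs_filter", "classical_filter"]


@njit(cache=False)
def quantize_window(w, n, wmin, span, bins, cnt, s1):
    """Fill bin index array and histogram (count, value-sum) in place."""
    for b in range(NBINS):
        cnt[b] = 0
        s1[b] = 0.0
    for i in range(n):
        b = int((w[i] - wmin) / span * NBINS)
        if b > NBINS - 1:
            b = NBINS - 1
        if b < 0:
            b = 0
        bins[i] = b
        cnt[b] += 1
        s1[b] += w[i]


@njit(cache=False)
def otsu_dp(cnt, s1, n_max, f, arg):
    """DP table for optimal 1..n_max-class splits of the histogram.

    ``f[k, j]`` is the best value of ``sum S^2/C`` when bins ``0..j`` are split
    into ``k+1`` classes; ``arg[k, j]`` records the first bin of the last
    class.  Ties are broken toward the earliest split (smallest thresholds).
    """
    csum = np.empty(NBINS + 1, dtype=np.int64)
    vsum = np.empty(NBINS + 1, dtype=np.float64)
    csum[0] = 0
    vsum[0] = 0.0
    for b in range(NBINS):
        csum[b + 1] = csum[b] + cnt[b]
        vsum[b + 1] = vsum[b] + s1[b]
    for j in range(NBINS):
        c = csum[j + 1]
        v = vsum[j + 1]
        f[0, j] = (v * v / c) if c > 0 else 0.0
        arg[0, j] = 0
    for k in range(1, n_max):
        for j in range(NBINS):
            best = -1.0
            besti = 0
            # last class spans bins i..j
            for i in range(j + 1):
                c = csum[j + 1] - csum[i]
                v = vsum[j + 1] - vsum[i]
                sc = (v * v / c) if c > 0 else 0.0
                tot = (f[k - 1, i - 1] if i > 0 else 0.0) + sc
                if tot > best:
                    best = tot
                    besti = i
            f[k, j] = best
            arg[k, j] = besti


@njit(cache=False)
def recover_cuts(arg, n_classes, cuts):
    """Backtrack the DP: ``cuts[k]`` = last bin index of class ``k``."""
    j = NBINS - 1
    for k in range(n_classes - 1, 0, -1):
        i = arg[k, j]
        cuts[k - 1] = i - 1
        j = i - 1


@njit(cache=False)
def pick_n_classes(cnt, s1, n, n_max, f, arg, rel_gain):
    """Smallest class count whose between-class-variance gain saturates.

    Walks N = 2, 3, ... and stops as soon as the relative gain in
    between-class variance drops below ``rel_gain`` (returning the previous
    N), or at ``n_max``.
    """
    total = 0.0
    mu = 0.0
    for b in range(NBINS):
        mu += s1[b]
    mu /= n
    otsu_dp(cnt, s1, n_max, f, arg)
    prev = f[1, NBINS - 1] / n - mu * mu
    chosen = 2
    for k in range(2, n_max):
        cur = f[k, NBINS - 1] / n - mu * mu
        if prev <= 0.0 or (cur - prev) / prev < rel_gain:
            break
        prev = cur
        chosen = k + 1
    return chosen


@njit(cache=False)
def flood_fill(mask, wh, ww, cr, cc, conn8, stack, out):
    """Connected component of True pixels containing (cr, cc), into ``out``."""
    for i in range(wh * ww):
        out[i] = False
    top = 0
    stack[top] = cr * ww + cc
    top += 1
    out[cr * ww + cc] = True
    while top > 0:
        top -= 1
        idx = stack[top]
        r = idx // ww
        c = idx % ww
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                if not conn8 and dr != 0 and dc != 0:
                    continue
                rr = r + dr
                cc2 = c + dc
                if rr < 0 or rr >= wh or cc2 < 0 or cc2 >= ww:
                    continue
                j = rr * ww + cc2
                if mask[j] and not out[j]:
                    out[j] = True
                    stack[top] = j
                    top += 1


@njit(cache=False)
def rbs_filter(image, pilot, U, V, max_classes, tol, conn8, rel_gain, out):
    """Region-shaped amoeba mean filter over the whole image (in place)."""
    H, W = image.shape
    hu = U // 2
    hv = V // 2
    nmax_px = U * V
    w = np.empty(nmax_px, dtype=np.float64)
    bins = np.empty(nmax_px, dtype=np.int64)
    cnt = np.empty(NBINS, dtype=np.int64)
    s1 = np.empty(NBINS, dtype=np.float64)
    f = np.empty((max_classes, NBINS), dtype=np.float64)
    arg = np.empty((max_classes, NBINS), dtype=np.int64)
    cuts = np.empty(max_classes, dtype=np.int64)
    mask = np.empty(nmax_px, dtype=np.bool_)
    comp = np.empty(nmax_px, dtype=np.bool_)
    stack = np.empty(nmax_px, dtype=np.int64)

    for r in range(H):
        r0 = r - hu if r - hu > 0 else 0
        r1 = r + hu + 1 if r + hu + 1 < H else H
        for c in range(W):
            c0 = c - hv if c - hv > 0 else 0
            c1 = c + hv + 1 if c + hv + 1 < W else W
            wh = r1 - r0
            ww = c1 - c0
            n = wh * ww
            wmin = pilot[r0, c0]
            wmax = wmin
            k = 0
            for i in range(r0, r1):
                for j in range(c0, c1):
                    v = pilot[i, j]
                    w[k] = v
                    k += 1
                    if v < wmin:
                        wmin = v
                    if v > wmax:
                        wmax = v
            span = wmax - wmin
            if span <= tol:
                # flat window: the kernel stays the full square
                acc = 0.0
                for i in range(r0, r1):
                    for j in range(c0, c1):
                        acc += image[i, j]
                out[r, c] = acc / n
                continue
            quantize_window(w, n, wmin, span, bins, cnt, s1)
            distinct = 0
            for b in range(NBINS):
                if cnt[b] > 0:
                    distinct += 1
            n_cl = max_classes if max_classes < distinct else distinct
            if n_cl < 2:
                n_cl = 2
            n_cl = pick_n_classes(cnt, s1, n, n_cl, f, arg, rel_gain)
            recover_cuts(arg, n_cl, cuts)
            cr = r - r0
            cc = c - c0
            bc = bins[cr * ww + cc]
            lo = -1
            hi = NBINS - 1
            for kk in range(n_cl - 1):
                if bc <= cuts[kk]:
                    hi = cuts[kk]
                    break
                lo = cuts[kk]
            for i in range(n):
                mask[i] = (bins[i] > lo) and (bins[i] <= hi)
            flood_fill(mask, wh, ww, cr, cc, conn8, stack, comp)
            acc = 0.0
            m = 0
            for i in range(wh):
                for j in range(ww):
                    if comp[i * ww + j]:
                        acc += image[r0 + i, c0 + j]
                        m += 1
            out[r, c] = acc / m


@njit(cache=False)
def amoeba_distances(pw, wh, ww, cr, cc, lam, conn8, dist):
    """Geodesic 'amoeba' distances from the center within one window.

    Path cost per step is ``1 + lam * |pilot step difference|``; distances are
    relaxed to convergence (Bellman-Ford sweeps on the tiny window graph).
    """
    big = 1e30
    for i in range(wh * ww):
        dist[i] = big
    dist[cr * ww + cc] = 0.0
    changed = True
    while changed:
        changed = False
        for r in range(wh):
            for c in range(ww):
                d0 = dist[r * ww + c]
                if d0 >= big:
                    continue
                for dr in range(-1, 2):
                    for dc in range(-1, 2):
                        if dr == 0 and dc == 0:
                            continue
                        if not conn8 and dr != 0 and dc != 0:
                            continue
                        rr = r + dr
                        cc2 = c + dc
                        if rr < 0 or rr >= wh or cc2 < 0 or cc2 >= ww:
                            continue
                        step = 1.0 + lam * abs(pw[rr * ww + cc2] - pw[r * ww + c])
                        j = rr * ww + cc2
                        if d0 + step < dist[j] - 1e-12:
                            dist[j] = d0 + step
                            changed = True


@njit(cache=False)
def classical_filter(image, pilot, U, V, lam, radius, conn8, out):
    """Classical amoeba-distance mean filter over the whole image."""
    H, W = image.shape
    hu = U // 2
    hv = V // 2
    nmax_px = U * V
    pw = np.empty(nmax_px, dtype=np.float64)
    dist = np.empty(nmax_px, dtype=np.float64)
    for r in range(H):
        r0 = r - hu if r - hu > 0 else 0
        r1 = r + hu + 1 if r + hu + 1 < H else H
        for c in range(W):
            c0 = c - hv if c - hv > 0 else 0
            c1 = c + hv + 1 if c + hv + 1 < W else W
            wh = r1 - r0
            ww = c1 - c0
            k = 0
            for i in range(r0, r1):
                for j in range(c0, c1):
                    pw[k] = pilot[i, j]
                    k += 1
            amoeba_distances(pw, wh, ww, r - r0, c - c0, lam, conn8, dist)
            acc = 0.0
            m = 0
            for i in range(wh):
                for j in range(ww):
                    if dist[i * ww + j] <= radius:
                        acc += image[r0 + i, c0 + j]
                        m += 1
            out[r, c] = acc / m
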