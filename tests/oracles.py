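"""Independent straight-line oracle implementations of the thresholding rules.

Each function re-implements the published rule of one thresholding method in
the plainest possible form (explicit loops over cuts, no shared code with
the package) so the suite can check the production implementations against
genuinely separate code paths.  Conventions match the package: cut t means
bins 0..t are the low class, reported threshold is edges[t+1]; objective
exact objective ties resolve at the median tied cut.
"""

import math

import numpy as np

TINY = np.finfo(float).tiny


def _probs_centers(counts, edges):
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    centers = [(edges[i] + edges[i + 1]) / 2.0 for i in range(len(counts))]
    return p, centers




def _best_mid(vals, maximize):
    """Median index among exactly tied optima (mirrors the package rule)."""
    finite = [v for v in vals if v is not None and math.isfinite(v)]
    opt = max(finite) if maximize else min(finite)
    tied = [i for i, v in enumerate(vals) if v == opt]
    return tied[len(tied) // 2]


def oracle_otsu(counts, edges):
    """Exhaustive scan minimizing within-class weighted variance."""
    p, c = _probs_centers(counts, edges)
    B = len(p)
    vals = []
    for t in range(B - 1):
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            vals.append(math.inf)
            continue
        mu0 = sum(p[i] * c[i] for i in range(t + 1)) / w0
        mu1 = sum(p[i] * c[i] for i in range(t + 1, B)) / w1
        var0 = sum(p[i] * (c[i] - mu0) ** 2 for i in range(t + 1)) / w0
        var1 = sum(p[i] * (c[i] - mu1) ** 2 for i in range(t + 1, B)) / w1
        vals.append(w0 * var0 + w1 * var1)
    return edges[_best_mid(vals, maximize=False) + 1]


def oracle_isodata(counts, edges, max_iter=1000):
    """Ridler–Calvard fixed point of t = (mean_low + mean_high) / 2."""
    p, c = _probs_centers(counts, edges)
    B = len(p)
    cum = np.cumsum(p)
    t = min(max(int(np.searchsorted(cum, 0.5)), 0), B - 2)
    for _ in range(max_iter):
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        if w0 <= 0:
            t += 1
            continue
        if w1 <= 0:
            t -= 1
            continue
        mu0 = sum(p[i] * c[i] for i in range(t + 1)) / w0
        mu1 = sum(p[i] * c[i] for i in range(t + 1, B)) / w1
        mid = 0.5 * (mu0 + mu1)
        t_new = min(max(int(np.searchsorted(c, mid)) - 1, 0), B - 2)
        if t_new == t:
            return edges[t + 1]
        t = t_new
    raise RuntimeError("oracle isodata did not converge")


def oracle_intermodes(counts, edges, max_iter=10000):
    """Iterative 3-point smoothing until bimodal, then peak midpoint."""
    h = list(map(float, counts))
    _, c = _probs_centers(counts, edges)
    B = len(h)
    for _ in range(max_iter):
        peaks = []
        for i in range(B):
            left = h[i - 1] if i > 0 else -math.inf
            right = h[i + 1] if i < B - 1 else -math.inf
            if h[i] > left and h[i] >= right and h[i] > 0:
                peaks.append(i)
        if len(peaks) == 2:
            mid = 0.5 * (c[peaks[0]] + c[peaks[1]])
            t = min(max(int(np.searchsorted(edges, mid)) - 1, 0), B - 2)
            return edges[t + 1]
        # same boundary handling as numpy convolve 'same' with kernel [1/3]*3
        h = [(0.0 if i == 0 else h[i - 1]) / 3.0 + h[i] / 3.0
             + (0.0 if i == B - 1 else h[i + 1]) / 3.0 for i in range(B)]
    raise RuntimeError("oracle intermodes never bimodal")


def oracle_renyi(counts, edges, alpha=2.0):
    """Maximize H_alpha(low) + H_alpha(high), Renyi entropy of order alpha."""
    p, _ = _probs_centers(counts, edges)
    B = len(p)
    vals = []
    for t in range(B - 1):
        P0 = sum(p[: t + 1])
        P1 = 1.0 - P0
        if P0 <= 0 or P1 <= 0:
            vals.append(-math.inf)
            continue
        if abs(alpha - 1.0) < 1e-12:
            h0 = -sum((q / P0) * math.log(q / P0) for q in p[: t + 1] if q > 0)
            h1 = -sum((q / P1) * math.log(q / P1) for q in p[t + 1:] if q > 0)
        else:
            h0 = math.log(sum((q / P0) ** alpha for q in p[: t + 1]) + TINY) / (1 - alpha)
            h1 = math.log(sum((q / P1) ** alpha for q in p[t + 1:]) + TINY) / (1 - alpha)
        vals.append(h0 + h1)
    return edges[_best_mid(vals, maximize=True) + 1]


def oracle_li(counts, edges, max_iter=1000, tol=1e-8):
    """Li & Tam minimum-cross-entropy fixed point on positively shifted centers."""
    p, c = _probs_centers(counts, edges)
    B = len(p)
    width = edges[1] - edges[0]
    offset = c[0] - width
    cs = [ci - offset for ci in c]
    t_val = sum(p[i] * cs[i] for i in range(B))
    for _ in range(max_iter):
        low = [i for i in range(B) if cs[i] <= t_val]
        high = [i for i in range(B) if cs[i] > t_val]
        w0 = sum(p[i] for i in low)
        w1 = sum(p[i] for i in high)
        if w0 <= 0 or w1 <= 0:
            break
        mu0 = sum(p[i] * cs[i] for i in low) / w0
        mu1 = sum(p[i] * cs[i] for i in high) / w1
        if abs(mu0 - mu1) < tol:
            break
        t_new = (mu0 - mu1) / (math.log(mu0) - math.log(mu1))
        if abs(t_new - t_val) < tol:
            t_val = t_new
            break
        t_val = t_new
    shifted_edges = [e - offset for e in edges]
    t = min(max(int(np.searchsorted(shifted_edges, t_val)) - 1, 0), B - 2)
    return edges[t + 1]


def oracle_shanbhag(counts, edges):
    """Minimize |I_low - I_high| of the fuzzy membership information."""
    p, _ = _probs_centers(counts, edges)
    B = len(p)
    P0 = np.cumsum(p)
    vals = []
    for t in range(B - 1):
        if P0[t] <= TINY or (1.0 - P0[t]) <= TINY:
            vals.append(math.inf)
            continue
        term0 = 0.5 / P0[t]
        ent0 = 0.0
        for i in range(t + 1):
            cum_below = P0[i - 1] if i > 0 else 0.0
            arg = 1.0 - term0 * cum_below
            ent0 -= p[i] * math.log(max(arg, TINY))
        ent0 *= term0
        P1t = 1.0 - P0[t]
        term1 = 0.5 / P1t
        ent1 = 0.0
        for i in range(t + 1, B):
            cum_above = (1.0 - P0[i]) if i < B - 1 else 0.0
            arg = 1.0 - term1 * cum_above
            ent1 -= p[i] * math.log(max(arg, TINY))
        ent1 *= term1
        vals.append(abs(ent0 - ent1))
    return edges[_best_mid(vals, maximize=False) + 1]


def oracle_huang(counts, edges):
    """Minimize total Shannon fuzziness with u = 1/(1 + |c - mu_class|/range)."""
    p, c = _probs_centers(counts, edges)
    B = len(p)
    C = edges[-1] - edges[0]
    vals = []
    for t in range(B - 1):
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            vals.append(math.inf)
            continue
        mu0 = sum(p[i] * c[i] for i in range(t + 1)) / w0
        mu1 = sum(p[i] * c[i] for i in range(t + 1, B)) / w1
        val = 0.0
        for i in range(B):
            mu = mu0 if i <= t else mu1
            u = 1.0 / (1.0 + abs(c[i] - mu) / C)
            u = min(max(u, TINY), 1.0 - 1e-15)
            val += p[i] * (-u * math.log(u) - (1 - u) * math.log(1 - u))
        vals.append(val)
    return edges[_best_mid(vals, maximize=False) + 1]


def oracle_mean(values):
    values = list(map(float, values))
    return sum(values) / len(values)


def oracle_triangle(counts, edges):
    """Max distance below the chord from the peak to the far end of the
    longer tail (histogram mirrored so the tail is on the right)."""
    h = list(map(float, counts))
    B = len(h)
    peak = max(range(B), key=lambda i: h[i])
    nonzero = [i for i in range(B) if h[i] > 0]
    left_end, right_end = nonzero[0], nonzero[-1]
    flipped = (peak - left_end) > (right_end - peak)
    if flipped:
        h = h[::-1]
        peak = B - 1 - peak
        tail_end = B - 1 - left_end
    else:
        tail_end = right_end
    best_i, best_d = peak, -math.inf
    for i in range(peak, tail_end + 1):
        x = (i - peak) / (tail_end - peak)
        y = h[i] / h[peak]
        d = (1.0 - x) - y
        if d > best_d + 1e-15:
            best_d, best_i = d, i
    split = (B - 1 - best_i) if flipped else best_i
    t = min(max(split, 0), B - 2)
    return edges[t + 1]


def oracle_kmeans2(values, n_starts=5, max_iter=300):
    """Lloyd's algorithm, k=2, best of several deterministic quantile inits;
    threshold is the midpoint of the two final centers."""
    v = np.sort(np.asarray(values, dtype=float))
    inits = [(np.quantile(v, a), np.quantile(v, b))
             for a, b in [(0.25, 0.75), (0.1, 0.9), (0.0, 1.0), (0.4, 0.6), (0.05, 0.5),
                          (0.005, 0.5), (0.5, 0.995), (0.01, 0.99), (0.001, 0.6),
                          (0.4, 0.999)]]
    best = None
    for c1, c2 in inits:
        if c1 == c2:
            continue
        for _ in range(max_iter):
            mid = 0.5 * (c1 + c2)
            low = v[v <= mid]
            high = v[v > mid]
            if len(low) == 0 or len(high) == 0:
                break
            n1, n2 = low.mean(), high.mean()
            if n1 == c1 and n2 == c2:
                break
            c1, c2 = n1, n2
        inertia = np.sum((v[v <= 0.5 * (c1 + c2)] - c1) ** 2) \
            + np.sum((v[v > 0.5 * (c1 + c2)] - c2) ** 2)
        if best is None or inertia < best[0]:
            best = (inertia, c1, c2)
    _, c1, c2 = best
    return 0.5 * (c1 + c2)


def oracle_gmm(values, n_starts=8, max_iter=500, tol=1e-10, seed=0):
    """Plain EM for a 2-component 1-D Gaussian mixture, best likelihood of
    several starts; threshold is the weighted-density crossing between the
    two means (found by dense scan)."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        if s == 0:
            m = np.array([np.quantile(v, 0.25), np.quantile(v, 0.75)])
        else:
            m = rng.choice(v, 2, replace=False).astype(float)
        if m[0] == m[1]:
            continue
        sd = np.array([v.std(), v.std()]) + 1e-6
        w = np.array([0.5, 0.5])
        ll_old = -np.inf
        for _ in range(max_iter):
            log_pdf = (-0.5 * ((v[:, None] - m) / sd) ** 2
                       - np.log(sd) - 0.5 * np.log(2 * np.pi) + np.log(w))
            mx = log_pdf.max(axis=1, keepdims=True)
            post = np.exp(log_pdf - mx)
            norm = post.sum(axis=1, keepdims=True)
            ll = float(np.sum(np.log(norm) + mx))
            post /= norm
            nk = post.sum(axis=0)
            w = nk / len(v)
            m = (post * v[:, None]).sum(axis=0) / nk
            sd = np.sqrt((post * (v[:, None] - m) ** 2).sum(axis=0) / nk) + 1e-10
            if abs(ll - ll_old) < tol:
                break
            ll_old = ll
        if best is None or ll > best[0]:
            best = (ll, m.copy(), sd.copy(), w.copy())
    _, m, sd, w = best
    order = np.argsort(m)
    m, sd, w = m[order], sd[order], w[order]
    if m[1] - m[0] < 1e-12:
        return float(m[0])
    xs = np.linspace(m[0], m[1], 20001)
    diff = (np.log(w[0]) - np.log(sd[0]) - 0.5 * ((xs - m[0]) / sd[0]) ** 2) \
        - (np.log(w[1]) - np.log(sd[1]) - 0.5 * ((xs - m[1]) / sd[1]) ** 2)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if len(sign_change):
        return float(xs[sign_change[0]])
    return float((m[0] * sd[1] + m[1] * sd[0]) / (sd[0] + sd[1]))
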