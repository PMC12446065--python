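"""Histogram-thresholding suite for splitting the FSC-ratio distribution.

The FSC ratio of a mixed singlet/multiplet event stream is bimodal-ish:
a dominant mode near the instrument's pulse-shape floor (singlets) and a
heavier-tailed mode above it (coincident or conjugated cells).  Every method
here reduces to a 1-D cut of that distribution.  Histogram-based methods
(Otsu, IsoData, Intermodes, Rényi entropy, Li, Shanbhag, Huang, Triangle)
operate on an equal-width histogram with >= 1000 bins; Mean uses the raw
data mean, and k-means (k=2) / two-component Gaussian-mixture cuts operate
on the raw values directly.

Conventions shared by the histogram methods: a cut index ``t`` means bins
``0..t`` form the low class and ``t+1..B-1`` the high class; the reported
threshold is the bin edge ``edges[t+1]`` (in data units).  Exactly tied
objective values form contiguous plateaus whenever the histogram has a run
of empty bins between modes (every cut inside the gap yields the identical
partition); the median tied cut is returned, which lands such thresholds in
the middle of the data gap and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Histogram",
    "ThresholdResult",
    "DegenerateDistributionError",
    "ConvergenceError",
    "build_histogram",
    "threshold_otsu",
    "compute_threshold",
    "THRESHOLD_METHODS",
]

THRESHOLD_METHODS = (
    "otsu", "isodata", "intermodes", "renyi_entropy", "li", "shanbhag",
    "huang", "mean", "triangle", "kmeans2", "gmm",
)

_EPS = np.finfo(float).tiny


class DegenerateDistributionError(ValueError):
    """The input distribution admits no threshold (e.g. constant data)."""


class ConvergenceError(RuntimeError):
    """An iterative method failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class Histogram:
    """Equal-width histogram: ``B+1`` strictly increasing edges, ``B`` counts."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


@dataclass
class ThresholdResult:
    threshold: float
    method: str
    diagnostics: dict = field(default_factory=dict)


def build_histogram(values, n_bins: int = 1000) -> Histogram:
    """Equal-width histogram over [min, max] with the rightmost bin closed."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise DegenerateDistributionError("constant input: no threshold exists")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return Histogram(edges, counts)


def _check_mass(hist: Histogram) -> None:
    if np.count_nonzero(hist.counts) < 2:
        raise DegenerateDistributionError("histogram mass concentrated in one bin")


def _cut_to_threshold(hist: Histogram, t: int) -> float:
    return float(hist.bin_edges[t + 1])


def _argbest(objective: np.ndarray, maximize: bool) -> int:
    """Index of the optimal objective; exact ties resolved at the median
    tied index (plateaus arise from empty-bin gaps, see module docstring)."""
    opt = np.nanmax(objective) if maximize else np.nanmin(objective)
    tied = np.flatnonzero(objective == opt)
    return int(tied[len(tied) // 2])


def _class_stats(hist: Histogram):
    """Cumulative weight and mean for every cut t (low class = bins 0..t)."""
    p = hist.probabilities
    c = hist.centers
    w0 = np.cumsum(p)
    mu_cum = np.cumsum(p * c)
    mu_total = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
    return p, c, w0, w1, mu0, mu1


# --------------------------------------------------------------------------
# histogram-based criteria

def threshold_otsu(hist: Histogram) -> ThresholdResult:
    """Otsu's cut: minimize within-class (intragroup) weighted variance.

    Equivalently maximizes the between-class variance
    ``w0*w1*(mu0-mu1)^2`` over all B-1 cuts; exact ties resolve mid-plateau.
    """
    _check_mass(hist)
    p, c, w0, w1, mu0, mu1 = _class_stats(hist)
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    between = np.full(hist.n_bins - 1, -np.inf)
    between[valid] = (w0[:-1] * w1[:-1] * (mu0[:-1] - mu1[:-1]) ** 2)[valid]
    t = _argbest(between, maximize=True)
    total_var = float(np.sum(p * (c - np.sum(p * c)) ** 2))
    return ThresholdResult(
        _cut_to_threshold(hist, t), "otsu",
        {"cut_index": t, "between_class_variance": float(between[t]),
         "within_class_variance": total_var - float(between[t])},
    )


def _threshold_isodata(hist: Histogram, max_iter: int = 1000) -> ThresholdResult:
    """Ridler–Calvard fixed point: t = (mean below t + mean above t) / 2."""
    _check_mass(hist)
    p, c, w0, w1, mu0, mu1 = _class_stats(hist)
    t = int(np.searchsorted(np.cumsum(p), 0.5))  # start near the median bin
    t = min(max(t, 0), hist.n_bins - 2)
    for _ in range(max_iter):
        if w0[t] <= 0:
            t += 1
            continue
        if w1[t] <= 0:
            t -= 1
            continue
        midpoint = 0.5 * (mu0[t] + mu1[t])
        t_new = int(np.searchsorted(hist.centers, midpoint))
        t_new = min(max(t_new - 1, 0), hist.n_bins - 2)
        if t_new == t:
            return ThresholdResult(_cut_to_threshold(hist, t), "isodata",
                                   {"cut_index": t, "class_mean_low": float(mu0[t]),
                                    "class_mean_high": float(mu1[t])})
        t = t_new
    raise ConvergenceError("isodata did not converge", _cut_to_threshold(hist, t))


def _threshold_intermodes(hist: Histogram, max_iter: int = 10000) -> ThresholdResult:
    """Smooth the histogram (3-point mean) until bimodal; cut midway between the modes."""
    _check_mass(hist)
    h = hist.counts.astype(float)

    def peak_indices(a):
        left = np.r_[-np.inf, a[:-1]]
        right = np.r_[a[1:], -np.inf]
        return np.flatnonzero((a > left) & (a >= right) & (a > 0))

    for it in range(max_iter):
        peaks = peak_indices(h)
        if len(peaks) == 2:
            mid = 0.5 * (hist.centers[peaks[0]] + hist.centers[peaks[1]])
            t = int(np.clip(np.searchsorted(hist.bin_edges, mid) - 1, 0, hist.n_bins - 2))
            return ThresholdResult(_cut_to_threshold(hist, t), "intermodes",
                                   {"cut_index": t, "iterations_smoothed": it,
                                    "peaks": [int(peaks[0]), int(peaks[1])]})
        h = np.convolve(h, np.ones(3) / 3.0, mode="same")
    raise ConvergenceError("intermodes: histogram never became bimodal",
                           float(hist.centers[int(np.argmax(h))]))


def _threshold_renyi(hist: Histogram, alpha: float = 2.0) -> ThresholdResult:
    """Maximize the sum of Rényi entropies of the two classes.

    ``H_a(class) = log(sum((p_i/P)^a)) / (1-a)`` for order ``a != 1``;
    ``a -> 1`` recovers the Kapur maximum-Shannon-entropy criterion.
    """
    _check_mass(hist)
    p = hist.probabilities
    B = hist.n_bins
    P0 = np.cumsum(p)
    P1 = 1.0 - P0
    crit = np.full(B - 1, -np.inf)
    for t in range(B - 1):
        if P0[t] <= 0 or P1[t] <= 0:
            continue
        q0 = p[: t + 1] / P0[t]
        q1 = p[t + 1:] / P1[t]
        if abs(alpha - 1.0) < 1e-12:
            h0 = -np.sum(q0[q0 > 0] * np.log(q0[q0 > 0]))
            h1 = -np.sum(q1[q1 > 0] * np.log(q1[q1 > 0]))
        else:
            h0 = np.log(np.sum(q0 ** alpha) + _EPS) / (1.0 - alpha)
            h1 = np.log(np.sum(q1 ** alpha) + _EPS) / (1.0 - alpha)
        crit[t] = h0 + h1
    t = _argbest(crit, maximize=True)
    return ThresholdResult(_cut_to_threshold(hist, t), "renyi_entropy",
                           {"cut_index": t, "alpha": alpha, "entropy_sum": float(crit[t])})


def _threshold_li(hist: Histogram, max_iter: int = 1000, tol: float = 1e-8) -> ThresholdResult:
    """Li & Tam minimum cross-entropy iteration.

    ``t_{k+1} = (mu_low - mu_high) / (ln mu_low - ln mu_high)`` with class
    means taken below/above ``t_k``.  The iteration requires positive support,
    so data are shifted so the lowest bin center sits at one bin width; the
    returned threshold is shifted back.
    """
    _check_mass(hist)
    c = hist.centers
    p = hist.probabilities
    width = hist.bin_edges[1] - hist.bin_edges[0]
    offset = c[0] - width  # shift so min center -> width > 0
    cs = c - offset
    t_val = float(np.sum(p * cs))  # start at the (shifted) mean
    for _ in range(max_iter):
        low = cs <= t_val
        w_low, w_high = p[low].sum(), p[~low].sum()
        if w_low <= 0 or w_high <= 0:
            break
        mu_low = np.sum(p[low] * cs[low]) / w_low
        mu_high = np.sum(p[~low] * cs[~low]) / w_high
        if abs(mu_low - mu_high) < tol:
            break
        t_new = (mu_low - mu_high) / (np.log(mu_low) - np.log(mu_high))
        if abs(t_new - t_val) < tol:
            t_val = t_new
            break
        t_val = t_new
    else:
        raise ConvergenceError("li iteration did not converge", t_val + offset)
    t = int(np.clip(np.searchsorted(hist.bin_edges - offset, t_val) - 1, 0, hist.n_bins - 2))
    return ThresholdResult(_cut_to_threshold(hist, t), "li",
                           {"cut_index": t, "fixed_point": float(t_val + offset)})


def _threshold_shanbhag(hist: Histogram) -> ThresholdResult:
    """Shanbhag's fuzzy-information criterion.

    Each class's information is a membership-weighted sum where a bin's
    membership fades with its cumulative distance from the cut; the cut
    balancing the two class informations (minimum |I_low - I_high|) wins.
    """
    _check_mass(hist)
    p = hist.probabilities
    B = hist.n_bins
    P0 = np.cumsum(p)
    P1 = 1.0 - P0
    vals = np.full(B - 1, np.inf)
    for t in range(B - 1):
        if P0[t] <= _EPS or P1[t] <= _EPS:
            continue
        term0 = 0.5 / P0[t]
        # low class: membership of bin i (i <= t) uses cumulative mass below i
        cum_below = np.r_[0.0, P0[:t]]  # P0[i-1] for i = 0..t
        args0 = 1.0 - term0 * cum_below
        ent0 = -np.sum(p[: t + 1] * np.log(np.clip(args0, _EPS, None))) * term0
        term1 = 0.5 / P1[t]
        cum_above = P1[t + 1:]  # mass strictly above bin i, i = t+1..B-1
        args1 = 1.0 - term1 * cum_above
        ent1 = -np.sum(p[t + 1:] * np.log(np.clip(args1, _EPS, None))) * term1
        vals[t] = abs(ent0 - ent1)
    if not np.isfinite(vals).any():
        raise DegenerateDistributionError("shanbhag: no admissible cut")
    t = _argbest(vals, maximize=False)
    return ThresholdResult(_cut_to_threshold(hist, t), "shanbhag",
                           {"cut_index": t, "information_imbalance": float(vals[t])})


def _threshold_huang(hist: Histogram) -> ThresholdResult:
    """Huang & Wang fuzzy-entropy minimization.

    For a cut t, bin i gets membership ``u_i = 1 / (1 + |c_i - mu_class| / C)``
    (C = data range), and the cut minimizing the total Shannon fuzziness
    ``sum p_i * S(u_i)`` with ``S(u) = -u ln u - (1-u) ln(1-u)`` is returned.
    """
    _check_mass(hist)
    p, c, w0, w1, mu0, mu1 = _class_stats(hist)
    C = hist.bin_edges[-1] - hist.bin_edges[0]
    B = hist.n_bins
    vals = np.full(B - 1, np.inf)
    for t in range(B - 1):
        if w0[t] <= 0 or w1[t] <= 0:
            continue
        u_low = 1.0 / (1.0 + np.abs(c[: t + 1] - mu0[t]) / C)
        u_high = 1.0 / (1.0 + np.abs(c[t + 1:] - mu1[t]) / C)
        u = np.r_[u_low, u_high]
        u = np.clip(u, _EPS, 1.0 - 1e-15)
        s = -(u * np.log(u) + (1.0 - u) * np.log(1.0 - u))
        vals[t] = float(np.sum(p * s))
    if not np.isfinite(vals).any():
        raise DegenerateDistributionError("huang: no admissible cut")
    t = _argbest(vals, maximize=False)
    return ThresholdResult(_cut_to_threshold(hist, t), "huang",
                           {"cut_index": t, "fuzziness": float(vals[t])})


def _threshold_triangle(hist: Histogram) -> ThresholdResult:
    """Triangle geometry: maximal perpendicular distance to the peak-tail chord.

    The chord runs from the histogram peak to the far end of the longer tail;
    the bin whose (normalized) count lies furthest below that chord is the cut.
    """
    _check_mass(hist)
    h = hist.counts.astype(float)
    peak = int(np.argmax(h))
    nonzero = np.flatnonzero(h > 0)
    left_end, right_end = int(nonzero[0]), int(nonzero[-1])
    # operate on the longer tail; mirror so the tail is to the right of the peak
    if (peak - left_end) > (right_end - peak):
        h = h[::-1]
        peak = len(h) - 1 - peak
        tail_end = len(h) - 1 - left_end
        flipped = True
    else:
        tail_end = right_end
        flipped = False
    if tail_end <= peak:
        raise DegenerateDistributionError("triangle: no tail to the side of the peak")
    # normalized chord from (peak, h[peak]) to (tail_end, 0)
    xs = np.arange(peak, tail_end + 1, dtype=float)
    ys = h[peak: tail_end + 1] / h[peak]
    x_norm = (xs - peak) / (tail_end - peak)
    # chord height at x_norm is 1 - x_norm; distance below the chord ∝ (1 - x_norm) - y
    d = (1.0 - x_norm) - ys
    split = int(xs[int(np.argmax(d))])
    if flipped:
        split = len(h) - 1 - split
    t = int(np.clip(split, 0, hist.n_bins - 2))
    return ThresholdResult(_cut_to_threshold(hist, t), "triangle",
                           {"cut_index": t, "peak_bin": int(np.argmax(hist.counts))})


# --------------------------------------------------------------------------
# value-based methods

def _threshold_mean(values: np.ndarray) -> ThresholdResult:
    return ThresholdResult(float(np.mean(values)), "mean", {})


def _threshold_kmeans2(values: np.ndarray, seed: int | None) -> ThresholdResult:
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    km.fit(values.reshape(-1, 1))
    lo, hi = sorted(float(c) for c in km.cluster_centers_.ravel())
    return ThresholdResult(0.5 * (lo + hi), "kmeans2",
                           {"center_low": lo, "center_high": hi})


def _threshold_gmm(values: np.ndarray, seed: int | None) -> ThresholdResult:
    """Two-component Gaussian mixture; cut at the posterior crossing point.

    The crossing of the two weighted component densities between the means is
    the root of a quadratic in x; if no root falls between the means (extreme
    variance imbalance) the variance-weighted midpoint is used instead.
    """
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, n_init=10, random_state=seed)
    gm.fit(values.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    (m1, m2), (s1, s2), (w1, w2) = means[order], sds[order], weights[order]
    # log w1 - log s1 - (x-m1)^2/(2 s1^2) = log w2 - log s2 - (x-m2)^2/(2 s2^2)
    a = 1.0 / (2 * s2 ** 2) - 1.0 / (2 * s1 ** 2)
    b = m1 / s1 ** 2 - m2 / s2 ** 2
    cc = m2 ** 2 / (2 * s2 ** 2) - m1 ** 2 / (2 * s1 ** 2) + np.log((w1 * s2) / (w2 * s1))
    crossing = None
    if abs(a) < 1e-300:
        if abs(b) > 0:
            crossing = -cc / b
    else:
        disc = b ** 2 - 4 * a * cc
        if disc >= 0:
            roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
            inside = roots[(roots > m1) & (roots < m2)]
            if inside.size:
                crossing = float(inside[0])
    if crossing is None or not (m1 < crossing < m2):
        crossing = float((m1 * s2 + m2 * s1) / (s1 + s2))
    return ThresholdResult(float(crossing), "gmm",
                           {"means": [float(m1), float(m2)], "sds": [float(s1), float(s2)],
                            "weights": [float(w1), float(w2)]})


_HISTOGRAM_METHODS = {
    "otsu": threshold_otsu,
    "isodata": _threshold_isodata,
    "intermodes": _threshold_intermodes,
    "renyi_entropy": _threshold_renyi,
    "li": _threshold_li,
    "shanbhag": _threshold_shanbhag,
    "huang": _threshold_huang,
    "triangle": _threshold_triangle,
}


def compute_threshold(values, method: str = "otsu", n_bins: int = 1000,
                      seed: int | None = 0, **kwargs) -> ThresholdResult:
    """Compute a singlet/multiplet cut of 1-D values by the named method.

    Histogram methods build an equal-width histogram with ``n_bins`` bins
    first; ``mean``, ``kmeans2`` and ``gmm`` operate on the raw values
    (the latter two seeded for reproducibility).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2 or values.min() == values.max():
        raise DegenerateDistributionError("need at least two distinct finite values")
    if method in _HISTOGRAM_METHODS:
        hist = build_histogram(values, n_bins)
        result = _HISTOGRAM_METHODS[method](hist, **kwargs)
    elif method == "mean":
        result = _threshold_mean(values)
    elif method == "kmeans2":
        result = _threshold_kmeans2(values, seed)
    elif method == "gmm":
        result = _threshold_gmm(values, seed)
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    assert values.min() <= result.threshold <= values.max()
    return result
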