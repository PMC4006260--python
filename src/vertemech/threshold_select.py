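"""Bone/background threshold selection from greyscale histograms.

The trabecular greyscale histogram of a vertebral micro-CT region of interest
is modelled as the sum of two normal components: component 1 is the fluid in
the trabecular space (background), component 2 is mineralized bone.  The model
curve at a bin of centre ``c`` and width ``w`` is

    f(c) = w * [ A1 * N(c; mu1, s1^2) + A2 * N(c; mu2, s2^2) ]

with masses ``A1, A2`` in voxel counts, fitted to the binned counts by
least squares with a bounded quasi-Newton optimizer (multi-start).

Two threshold rules are implemented:

* *clear minimum* — when the mixture density has a clear interior local
  minimum between the two means, that minimum is the threshold (typical for
  well-separated, highly mineralized distributions);
* *equal misclassification* — otherwise, the threshold ``t`` solves
  ``A1 * (1 - Phi((t - mu1)/s1)) = A2 * Phi((t - mu2)/s2)``, i.e. the
  expected count of background voxels misclassified as bone equals the
  expected count of bone voxels misclassified as background (typical for
  overlapping distributions).

A global threshold across two groups is the mean of the two group-specific
values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .core_io import GreyscaleVolume

__all__ = [
    "Histogram",
    "BimodalFit",
    "ThresholdResult",
    "compute_histogram",
    "average_histogram",
    "fit_bimodal",
    "threshold_equal_misclassification",
    "threshold_clear_minimum",
    "select_species_threshold",
    "global_threshold",
]


@dataclass
class Histogram:
    """Binned greyscale distribution: ``len(counts) == len(edges) - 1``."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.edges.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("edges and counts must be 1D")
        if len(self.counts) != len(self.edges) - 1:
            raise ValueError("need len(counts) == len(edges) - 1")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class BimodalFit:
    """Fitted two-normal mixture.  By convention ``mu1 < mu2``: component 1 is
    the trabecular-space background, component 2 is bone.  ``A1, A2`` are
    component masses in voxel counts."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    A1: float
    A2: float
    residual: float
    converged: bool
    message: str = ""

    def __post_init__(self):
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("component SDs must be positive")
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("component masses must be non-negative")
        if not self.mu1 < self.mu2:
            raise ValueError("component means must satisfy mu1 < mu2")

    def density(self, x) -> np.ndarray:
        """Mixture density in counts per intensity unit."""
        x = np.asarray(x, dtype=float)
        return (self.A1 * norm.pdf(x, self.mu1, self.sigma1)
                + self.A2 * norm.pdf(x, self.mu2, self.sigma2))


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    rule: str  # "clear_minimum" | "equal_misclassification"
    fit: BimodalFit

    def __post_init__(self):
        if not (self.fit.mu1 <= self.threshold <= self.fit.mu2):
            raise ValueError("threshold must lie within [mu1, mu2]")


def compute_histogram(volume: GreyscaleVolume, roi=None, n_bins: int = 256,
                      range_=None) -> Histogram:
    """Histogram of voxel intensities whose centres fall inside an axis-aligned
    box ``roi = ((x0, x1), (y0, y1), (z0, z1))`` in mm (physical coordinates).

    ``roi=None`` uses the whole volume.  The sum of counts equals the number
    of voxel centres inside the box.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    data = volume.data
    if roi is not None:
        roi = np.asarray(roi, dtype=float)
        if roi.shape != (3, 2):
            raise ValueError("roi must be ((x0,x1),(y0,y1),(z0,z1)) in mm")
        if np.any(roi[:, 1] <= roi[:, 0]):
            raise ValueError("roi is degenerate (zero or negative extent)")
        sel = []
        for ax in range(3):
            c = volume.voxel_centres(ax)
            idx = np.nonzero((c >= roi[ax, 0]) & (c <= roi[ax, 1]))[0]
            if idx.size == 0:
                raise ValueError(f"roi contains no voxel centres on axis {ax}")
            lo, hi = c[idx[0]], c[idx[-1]]
            if roi[ax, 0] < volume.origin[ax] - 1e-9 or \
               roi[ax, 1] > volume.origin[ax] + data.shape[ax] * volume.spacing[ax] + 1e-9:
                raise ValueError(f"roi exceeds volume bounds on axis {ax}")
            sel.append(slice(idx[0], idx[-1] + 1))
        data = data[tuple(sel)]
    values = data.ravel()
    if range_ is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:  # constant region: make a non-degenerate bin around it
            lo, hi = lo - 0.5, hi + 0.5
        range_ = (lo, hi)
    counts, edges = np.histogram(values, bins=n_bins, range=range_)
    return Histogram(edges=edges, counts=counts.astype(float))


def average_histogram(histograms) -> Histogram:
    """Arithmetic per-bin mean of histograms sharing identical bin edges."""
    histograms = list(histograms)
    if not histograms:
        raise ValueError("need at least one histogram")
    edges = histograms[0].edges
    for h in histograms[1:]:
        if len(h.edges) != len(edges) or not np.allclose(h.edges, edges, rtol=0, atol=0):
            raise ValueError("histograms must share identical bin edges")
    counts = np.mean([h.counts for h in histograms], axis=0)
    return Histogram(edges=edges.copy(), counts=counts)


def _model_curve(params, centres, widths):
    mu1, mu2, s1, s2, a1, a2 = params
    return widths * (a1 * norm.pdf(centres, mu1, s1) + a2 * norm.pdf(centres, mu2, s2))


def _objective(params, centres, widths, counts):
    r = _model_curve(params, centres, widths) - counts
    return float(r @ r)


def fit_bimodal(hist: Histogram, init=None) -> BimodalFit:
    """Least-squares fit of the two-normal mixture curve to binned counts.

    Uses L-BFGS-B (quasi-Newton, numerical gradients) with sigma bounded below
    by one bin width, started from three deterministic quantile-based
    initializations (plus ``init`` when supplied); the best final objective
    wins.  Components are relabelled so that ``mu1 < mu2``.
    """
    nonempty = int(np.count_nonzero(hist.counts))
    if nonempty < 6:
        raise ValueError(f"need >= 6 non-empty bins to fit 6 parameters, got {nonempty}")
    centres, widths, counts = hist.centres, hist.widths, hist.counts
    total = counts.sum()
    if counts.max() >= total:  # all mass in one bin
        raise ValueError("all histogram mass in a single bin; mixture fit is undefined")

    # empirical quantiles of the binned distribution
    cdf = np.cumsum(counts) / total
    def q(p):
        return float(np.interp(p, cdf, centres))

    w_min = float(widths.min())
    span = hist.edges[-1] - hist.edges[0]
    sd_all = max(np.sqrt(np.average((centres - np.average(centres, weights=counts)) ** 2,
                                    weights=counts)), w_min)

    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    # quantile-based deterministic multi-start: split at 3 candidate masses
    for p_split in (0.5, 0.3, 0.7):
        mu1, mu2 = q(p_split / 2), q(p_split + (1 - p_split) / 2)
        if mu2 - mu1 < w_min:
            mu1, mu2 = q(0.25), q(0.75)
            if mu2 - mu1 < w_min:
                mu1, mu2 = mu1 - w_min, mu1 + w_min
        s_guess = max(sd_all / 2, w_min)
        starts.append(np.array([mu1, mu2, s_guess, s_guess,
                                p_split * total, (1 - p_split) * total]))

    lo, hi = hist.edges[0] - span, hist.edges[-1] + span
    bounds = [(lo, hi), (lo, hi), (w_min, 10 * span), (w_min, 10 * span),
              (0.0, 10 * total), (0.0, 10 * total)]

    best = None
    any_converged = False
    message = ""
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(_objective, x0, args=(centres, widths, counts),
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 20000, "maxfun": 100000,
                                         "ftol": 1e-15, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
            message = str(res.message)
        any_converged = any_converged or bool(res.success)

    mu1, mu2, s1, s2, a1, a2 = best.x
    if mu1 > mu2:
        mu1, mu2, s1, s2, a1, a2 = mu2, mu1, s2, s1, a2, a1
    elif mu1 == mu2:
        mu2 = mu1 + max(w_min * 1e-6, 1e-12)
    return BimodalFit(mu1=float(mu1), mu2=float(mu2), sigma1=float(s1),
                      sigma2=float(s2), A1=float(a1), A2=float(a2),
                      residual=float(best.fun), converged=any_converged,
                      message=message)


def threshold_equal_misclassification(fit: BimodalFit, tol: float = 1e-6) -> float:
    """Threshold where expected misclassified counts balance.

    Solves ``A1 * (1 - Phi((t - mu1)/s1)) - A2 * Phi((t - mu2)/s2) = 0`` by
    bracketed root finding on ``(mu1, mu2)`` to ``tol`` intensity units.
    """
    def g(t):
        return (fit.A1 * norm.sf(t, fit.mu1, fit.sigma1)
                - fit.A2 * norm.cdf(t, fit.mu2, fit.sigma2))

    a, b = fit.mu1, fit.mu2
    ga, gb = g(a), g(b)
    if ga == 0:
        return float(a)
    if gb == 0:
        return float(b)
    if np.sign(ga) == np.sign(gb):
        raise ValueError(
            f"no equal-misclassification crossing in (mu1, mu2) for fit {fit}: "
            f"g({a})={ga:.3g}, g({b})={gb:.3g}"
        )
    return float(optimize.brentq(g, a, b, xtol=tol))


def threshold_clear_minimum(fit: BimodalFit, depth_factor: float = 0.8,
                            n_grid: int = 4096) -> float | None:
    """Interior local minimum of the mixture density on ``(mu1, mu2)``, if clear.

    A minimum ``t*`` qualifies when ``density(t*) <= depth_factor *
    min(density(mu1), density(mu2))``; otherwise ``None`` (the overlapped,
    effectively unimodal case).  When two interior minima exist the deeper one
    wins; exact ties go to the one nearer ``(mu1 + mu2) / 2``.
    """
    a, b = fit.mu1, fit.mu2
    if b - a <= 0:
        return None
    ts = np.linspace(a, b, n_grid)
    d = fit.density(ts)
    interior = np.arange(1, n_grid - 1)
    is_min = (d[interior] <= d[interior - 1]) & (d[interior] <= d[interior + 1])
    cand_idx = interior[is_min]
    if cand_idx.size == 0:
        return None
    # refine each candidate by bounded scalar minimization on its grid bracket
    refined = []
    for i in cand_idx:
        res = optimize.minimize_scalar(lambda t: float(fit.density(t)),
                                       bounds=(ts[i - 1], ts[i + 1]),
                                       method="bounded",
                                       options={"xatol": 1e-9 * (b - a)})
        refined.append((float(res.fun), float(res.x)))
    d_min = min(r[0] for r in refined)
    mid = 0.5 * (a + b)
    # deepest first; ties by distance to midpoint
    best = min(refined, key=lambda r: (r[0] - d_min > 1e-12 * max(d_min, 1e-300),
                                       abs(r[1] - mid)))
    d_star, t_star = best
    edge = min(float(fit.density(a)), float(fit.density(b)))
    if d_star <= depth_factor * edge:
        return t_star
    return None


def select_species_threshold(fit: BimodalFit, depth_factor: float = 0.8) -> ThresholdResult:
    """Clear-minimum threshold when one exists, else equal misclassification."""
    t = threshold_clear_minimum(fit, depth_factor=depth_factor)
    if t is not None:
        return ThresholdResult(threshold=t, rule="clear_minimum", fit=fit)
    t = threshold_equal_misclassification(fit)
    return ThresholdResult(threshold=t, rule="equal_misclassification", fit=fit)


def global_threshold(t_a: float, t_b: float) -> float:
    """Mean of two group-specific thresholds."""
    if not (np.isfinite(t_a) and np.isfinite(t_b)):
        raise ValueError("thresholds must be finite")
    return 0.5 * (float(t_a) + float(t_b))
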