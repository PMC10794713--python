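"""Filament length-distribution morphometry.

Filament lengths traced from negative-stain electron micrographs are
summarized the way they are conventionally plotted (median with the
25th/75th-percentile range), and modelled as a K-component Gaussian
mixture fitted by expectation-maximization on the raw length values.
Self-assembled filaments frequently fuse end to end, so fitted peak means
are additionally checked for sitting at integer multiples of the first
(shortest) peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LengthSample",
    "MixtureFit",
    "length_summary",
    "fit_gaussian_mixture",
    "fit_histogram_gaussians",
    "check_peak_multiples",
]

_MIN_SD = 0.1  # nm; a component collapsing below this is degenerate


@dataclass(frozen=True)
class LengthSample:
    """Filament length measurements (nm) from one sample."""

    lengths: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths, dtype=float)
        if arr.ndim != 1:
            raise ValueError("lengths must be one-dimensional")
        if arr.size and arr.min() <= 0:
            raise ValueError("all lengths must be > 0")
        object.__setattr__(self, "lengths", arr)

    @property
    def n(self) -> int:
        return int(self.lengths.size)


@dataclass(frozen=True)
class MixtureFit:
    """A fitted K-component 1-D Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool
    ll_trace: np.ndarray = field(repr=False, default=None)

    @property
    def K(self) -> int:
        return int(len(self.means))

    def bic(self, n: int) -> float:
        """Bayesian information criterion (optional model-selection report)."""
        n_params = 3 * self.K - 1
        return n_params * np.log(n) - 2 * self.log_likelihood

    def components(self) -> pd.DataFrame:
        return pd.DataFrame({"weight": self.weights, "mean": self.means, "sd": self.sds})


def length_summary(s: LengthSample) -> dict:
    """Median and quartiles, as drawn on violin plots.

    Percentile method: linear interpolation between order statistics (the
    numpy default).  Returns dict with median, q25, q75, n.
    """
    if s.n == 0:
        raise ValueError("empty length sample")
    q25, med, q75 = np.percentile(s.lengths, [25, 50, 75])
    return {"median": float(med), "q25": float(q25), "q75": float(q75), "n": s.n}


def _log_gauss(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def _em_once(
    x: np.ndarray, K: int, rng: np.random.Generator, max_iter: int, tol: float
) -> MixtureFit | None:
    """One EM run from a random initialization; None if it degenerates."""
    n = x.size
    means = rng.choice(x, size=K, replace=False).astype(float)
    sds = np.full(K, max(x.std(), _MIN_SD))
    weights = np.full(K, 1.0 / K)
    ll_prev = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities via log-sum-exp
        log_comp = np.stack(
            [np.log(w) + _log_gauss(x, m, s) for w, m, s in zip(weights, means, sds)]
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=0)
        resp = np.exp(log_comp - log_norm)
        ll = float(log_norm.sum())
        trace.append(ll)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M-step
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-12):
            return None
        weights = nk / n
        means = resp @ x / nk
        sds = np.array(
            [np.sqrt(np.sum(resp[k] * (x - means[k]) ** 2) / nk[k]) for k in range(K)]
        )
        if np.any(sds < _MIN_SD):
            return None
    order = np.argsort(means)
    return MixtureFit(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        log_likelihood=trace[-1],
        n_iter=it,
        converged=converged,
        ll_trace=np.asarray(trace),
    )


def fit_gaussian_mixture(
    s: LengthSample,
    K: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit a K-component Gaussian mixture to raw lengths by EM.

    Best of ``n_restarts`` random initializations by log-likelihood;
    convergence when the log-likelihood improvement drops below ``tol`` or
    after ``max_iter`` iterations.  A restart whose component standard
    deviation collapses below 0.1 nm is discarded as degenerate; if every
    restart degenerates the fit errors out.

    Truncation of the length distribution at zero is ignored (lengths sit
    far from zero in practice).
    """
    if K <= 0:
        raise ValueError("K must be >= 1")
    if s.n < 10 * K:
        raise ValueError(f"need at least {10 * K} observations for K={K}, got {s.n}")
    rng = np.random.default_rng(seed)
    best: MixtureFit | None = None
    for _ in range(max(1, n_restarts)):
        fit = _em_once(s.lengths, K, rng, max_iter, tol)
        if fit is not None and (best is None or fit.log_likelihood > best.log_likelihood):
            best = fit
    if best is None:
        raise ValueError("all EM restarts degenerate (component sd collapsed below 0.1 nm)")
    return best


def fit_histogram_gaussians(
    s: LengthSample, K: int, bin_width: float, seed: int = 0
) -> MixtureFit:
    """Histogram-based Gaussian fit for comparability with GUI curve fitting.

    Bins the lengths at ``bin_width`` (nm) and least-squares fits a sum of K
    Gaussians to the bin counts.  Bin-width dependent; the EM fit on raw
    values (:func:`fit_gaussian_mixture`) is the preferred route.
    """
    from scipy.optimize import curve_fit

    if K <= 0 or bin_width <= 0:
        raise ValueError("K and bin_width must be positive")
    lo, hi = s.lengths.min(), s.lengths.max()
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(s.lengths, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(x, *params):
        out = np.zeros_like(x)
        for k in range(K):
            a, m, sd = params[3 * k : 3 * k + 3]
            out = out + a * np.exp(-0.5 * ((x - m) / sd) ** 2)
        return out

    em = fit_gaussian_mixture(s, K, seed=seed)  # seeds the curve fit sensibly
    p0 = []
    for w, m, sd in zip(em.weights, em.means, em.sds):
        p0 += [w * s.n * bin_width / (sd * np.sqrt(2 * np.pi)), m, sd]
    popt, _ = curve_fit(model, centers, counts, p0=p0, maxfev=20000)
    amps = np.abs(popt[0::3])
    means = popt[1::3]
    sds = np.abs(popt[2::3])
    areas = amps * sds * np.sqrt(2 * np.pi)
    order = np.argsort(means)
    resid = counts - model(centers, *popt)
    return MixtureFit(
        weights=(areas / areas.sum())[order],
        means=means[order],
        sds=sds[order],
        log_likelihood=-0.5 * float(np.sum(resid**2)),  # pseudo-LL: -SSE/2
        n_iter=1,
        converged=True,
    )


def check_peak_multiples(fit: MixtureFit, rel_tol: float = 0.12) -> pd.DataFrame:
    """Do fitted peak means sit at integer multiples of the first peak?

    End-to-end fusion of filaments produces length peaks near 2x, 3x, ... the
    unit-filament length.  For each component beyond the first, reports the
    ratio mean_k/mean_1, its nearest integer, and whether
    |ratio - round(ratio)| <= rel_tol * round(ratio).
    """
    if fit.K < 2:
        raise ValueError("peak-multiple check needs at least two components")
    base = fit.means[0]
    rows = []
    for k in range(1, fit.K):
        ratio = fit.means[k] / base
        nearest = int(round(ratio))
        rows.append(
            {
                "component": k + 1,
                "mean": fit.means[k],
                "ratio": ratio,
                "nearest_integer": nearest,
                "within_tol": nearest >= 1 and abs(ratio - nearest) <= rel_tol * nearest,
            }
        )
    return pd.DataFrame(rows)


def sample_from_tsv(path, label: str = "") -> LengthSample:
    """Read a one-column TSV of lengths (nm) into a LengthSample."""
    values = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].to_numpy(float)
    return LengthSample(lengths=values, label=label)
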