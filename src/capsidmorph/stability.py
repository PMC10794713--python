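"""Melt-curve Tm extraction and assembly-mass bookkeeping.

Differential scanning fluorimetry (DSF) melt curves are reduced to a
melting temperature Tm taken at the extremum of the first derivative of
fluorescence with respect to temperature — by the convention adopted
here, the derivative *minimum* (mode configurable; instrument sign
conventions vary).  Mass arithmetic covers expected oligomer masses
(n subunits x monomer mass), inferred cargo mass from a measured
particle mass, and peak calling on single-particle mass-photometry
histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "MeltCurve",
    "TmResult",
    "MassObservation",
    "MassPeak",
    "compute_tm",
    "replicate_tm",
    "expected_assembly_mass",
    "infer_cargo_mass",
    "call_mass_peak",
    "mda_to_kda",
]


def mda_to_kda(mass_mda: float) -> float:
    """Convert MDa to the canonical kDa unit (1 MDa = 1000 kDa)."""
    return mass_mda * 1000.0


@dataclass(frozen=True)
class MeltCurve:
    """Temperature-ordered fluorescence series on a uniform grid (deg C)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size != f.size:
            raise ValueError("temperature and fluorescence lengths differ")
        if t.size < 5:
            raise ValueError("melt curve needs at least 5 points")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.ptp(steps) > 1e-6:
            raise ValueError("temperature grid must be uniform (step varies)")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class TmResult:
    tm: float
    mode: str
    at_boundary: bool  # extremum sits on the grid edge: treat with caution


def _moving_mean(y: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return np.convolve(y, kernel, mode="same") / counts


def compute_tm(
    curve: MeltCurve,
    mode: str = "min",
    smooth_window: int | None = None,
    noise_floor: float = 0.0,
) -> TmResult:
    """Melting temperature from the first derivative of a melt curve.

    The derivative is taken by central differences on the uniform grid
    (one-sided at the ends).  Tm is the temperature of the derivative
    minimum (``mode='min'``, the default), maximum (``'max'``), or the
    larger-magnitude extremum (``'auto'``).  Optional moving-mean smoothing
    (``smooth_window`` points) is applied before differentiation.

    A curve with no discernible transition — derivative range below
    ``noise_floor`` (plus a relative floor that catches flat and purely
    linear curves) — raises ``ValueError``.
    """
    if mode not in ("min", "max", "auto"):
        raise ValueError(f"mode must be min, max or auto, got {mode!r}")
    f = curve.fluorescence
    if smooth_window is not None:
        if smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        f = _moving_mean(f, smooth_window)
    deriv = np.gradient(f, curve.step)
    drange = float(np.ptp(deriv))
    scale = max(float(np.abs(deriv).max()), 1e-30)
    if drange <= max(noise_floor, 1e-9 * scale):
        raise ValueError("no transition: first derivative has no extremum above the noise floor")
    i_min = int(np.argmin(deriv))
    i_max = int(np.argmax(deriv))
    if mode == "min":
        idx = i_min
    elif mode == "max":
        idx = i_max
    else:
        median = float(np.median(deriv))
        idx = i_min if abs(deriv[i_min] - median) >= abs(deriv[i_max] - median) else i_max
    return TmResult(
        tm=float(curve.temperatures[idx]),
        mode=mode,
        at_boundary=idx in (0, len(deriv) - 1),
    )


def replicate_tm(curves: Sequence[MeltCurve], mode: str = "min", **kwargs) -> dict:
    """Per-replicate Tm plus mean +/- SD across replicate curves."""
    tms = [compute_tm(c, mode=mode, **kwargs).tm for c in curves]
    return {
        "tm_per_replicate": tms,
        "mean": float(np.mean(tms)),
        "sd": float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0,
        "n": len(tms),
    }


@dataclass(frozen=True)
class MassObservation:
    """A measured particle mass against an expected oligomer stoichiometry."""

    measured_mass: float  # kDa
    n_subunits: int
    monomer_mass: float  # kDa

    def __post_init__(self) -> None:
        if min(self.measured_mass, self.n_subunits, self.monomer_mass) <= 0:
            raise ValueError("measured_mass, n_subunits and monomer_mass must all be > 0")


def expected_assembly_mass(n_subunits: int, monomer_mass: float) -> float:
    """Expected oligomer mass in kDa: n_subunits x monomer_mass."""
    if n_subunits <= 0 or monomer_mass <= 0:
        raise ValueError("n_subunits and monomer_mass must be > 0")
    return n_subunits * monomer_mass


def infer_cargo_mass(obs: MassObservation) -> float:
    """Cargo mass (kDa) = measured particle mass - expected shell mass."""
    expected = expected_assembly_mass(obs.n_subunits, obs.monomer_mass)
    cargo = obs.measured_mass - expected
    if cargo < 0:
        raise ValueError(
            f"measured below expected assembly mass ({obs.measured_mass} < {expected:.1f} kDa)"
        )
    return cargo


@dataclass(frozen=True)
class MassPeak:
    peak_mass: float  # fitted Gaussian center, kDa
    sd: float
    n_in_peak: int
    multimodal: bool


def call_mass_peak(masses: Sequence[float], bin_width: float = 25.0) -> MassPeak:
    """Call the dominant peak of a particle-mass histogram.

    Histograms the masses at ``bin_width`` (kDa), locates the modal bin, and
    fits a Gaussian over a +/-3-bin window around the mode.  If another local
    maximum of comparable height (>= 50% of the mode) lies outside that
    window the result is flagged multimodal; the tallest peak is returned.
    """
    from scipy.optimize import curve_fit

    m = np.asarray(masses, dtype=float)
    if m.size < 50:
        raise ValueError(f"need at least 50 mass observations, got {m.size}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if np.ptp(m) == 0:  # all identical: center is that value
        return MassPeak(peak_mass=float(m[0]), sd=0.0, n_in_peak=int(m.size), multimodal=False)
    edges = np.arange(m.min() - bin_width, m.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(m, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode_idx = int(np.argmax(counts))

    lo, hi = max(0, mode_idx - 3), min(len(counts), mode_idx + 4)
    window_counts = counts[lo:hi].astype(float)
    window_centers = centers[lo:hi]

    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    p0 = (float(counts[mode_idx]), float(centers[mode_idx]), max(bin_width, float(m.std() / 2)))
    try:
        popt, _ = curve_fit(gauss, window_centers, window_counts, p0=p0, maxfev=10000)
        center, sd = float(popt[1]), abs(float(popt[2]))
    except RuntimeError:  # fit failure on a pathological window: fall back to moments
        center = float(np.average(window_centers, weights=np.maximum(window_counts, 0)))
        sd = float(m.std())

    # secondary local maxima outside the fit window
    multimodal = False
    for i in range(1, len(counts) - 1):
        if lo <= i < hi:
            continue
        if counts[i] >= counts[i - 1] and counts[i] >= counts[i + 1]:
            if counts[i] >= 0.5 * counts[mode_idx] and counts[i] > 0:
                multimodal = True
                break
    n_in_peak = int(np.sum((m >= edges[lo]) & (m < edges[hi])))
    return MassPeak(peak_mass=center, sd=sd, n_in_peak=n_in_peak, multimodal=multimodal)
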