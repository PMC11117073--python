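"""Frequency-distribution construction and model fitting for pause durations.

Pausing conditions produce unimodal duration distributions well described
by a Gaussian ``A·exp(−0.5·((x − x̄)/SD)²)``; non-pausing conditions (where
apparent "pauses" are detection noise) are right-skewed and better modelled
by an exponential decay ``(Y0 − Dmax)·exp(−k·x) + Dmax``. Both models are
fit to binned counts by nonlinear least squares and compared by R²; the
parameters of interest (x̄, SD, k) are invariant to the overall count scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError


@dataclass
class FrequencyHistogram:
    """Counts per uniform bin; bins are centred on multiples of ``bin_width``."""

    bin_centers: np.ndarray
    frequencies: np.ndarray
    bin_width: float

    @property
    def n_events(self) -> int:
        return int(self.frequencies.sum())


@dataclass(frozen=True)
class DistributionFit:
    """Result of one nonlinear least-squares model fit to a histogram."""

    model: str  # "gaussian" or "exp_decay"
    params: dict[str, float]
    r2: float
    n_events: int


@dataclass(frozen=True)
class ModelSelection:
    model: str | None  # None on a tie
    delta_r2: float
    tie: bool


def build_histogram(durations, bin_width: float = 5.0) -> FrequencyHistogram:
    """Bin durations into uniform bins starting at 0: [0, w), [w, 2w), ...

    ``bin_centers`` are the bin midpoints (w/2, 3w/2, ...); the total
    count equals the number of durations for any width. Starting the first
    full-width bin at zero keeps a decaying sample monotone in its counts
    (a half-width first bin would fake a peak).
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise InsufficientDataError("no durations to bin")
    if np.any(durations < 0):
        raise InsufficientDataError("durations must be non-negative")
    if bin_width <= 0:
        raise InsufficientDataError("bin_width must be positive")
    idx = np.floor(durations / bin_width).astype(int)
    counts = np.bincount(idx)
    centers = (np.arange(counts.size) + 0.5) * bin_width
    return FrequencyHistogram(
        bin_centers=centers, frequencies=counts.astype(float), bin_width=bin_width
    )


def _gaussian(x, amp, mean, sd):
    return amp * np.exp(-0.5 * ((x - mean) / sd) ** 2)


def _exp_decay(x, y0, dmax, k):
    return (y0 - dmax) * np.exp(-k * x) + dmax


def _check_bins(hist: FrequencyHistogram) -> None:
    if int(np.count_nonzero(hist.frequencies)) < 4:
        raise InsufficientDataError("need >= 4 bins with nonzero counts to fit")


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_gaussian(hist: FrequencyHistogram) -> DistributionFit:
    """Least-squares Gaussian fit (amplitude, mean, SD) to bin frequencies.

    Initialisation is data-driven and deterministic: the count-weighted bin
    mean and SD, and the maximum frequency for the amplitude.
    """
    _check_bins(hist)
    x, y = hist.bin_centers, hist.frequencies
    w = y / y.sum()
    mean0 = float(np.sum(w * x))
    sd0 = float(np.sqrt(np.sum(w * (x - mean0) ** 2))) or hist.bin_width
    p0 = [float(y.max()), mean0, sd0]
    # the fitted mean is reported as the mean pause duration, so it is
    # constrained to be non-negative; without the bound a monotone-
    # decaying histogram drives the mean to -inf (a half-Gaussian that
    # mimics exponential decay) and the fit never converges
    span = float(x.max() - x.min()) + hist.bin_width
    try:
        popt, _ = curve_fit(
            _gaussian, x, y, p0=p0,
            bounds=([0.0, 0.0, 1e-9], [np.inf, float(x.max()) + span, 10.0 * span]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError("Gaussian fit did not converge", {"p0": p0}) from exc
    amp, mean, sd = map(float, popt)
    return DistributionFit(
        model="gaussian",
        params={"A": amp, "mean": mean, "sd": sd},
        r2=_r2(y, _gaussian(x, *popt)),
        n_events=hist.n_events,
    )


def fit_exp_decay(hist: FrequencyHistogram) -> DistributionFit:
    """Least-squares exponential-decay fit (Y0, Dmax, k) to bin frequencies.

    The rate constant is initialised from a log-linear fit over the first
    half of the (positive-count) bins; the plateau from the smallest
    frequency.
    """
    _check_bins(hist)
    x, y = hist.bin_centers, hist.frequencies
    dmax0 = float(y.min())
    y0_0 = float(y[0]) if y[0] > 0 else float(y.max())
    pos = y > dmax0
    k0 = 0.1
    if pos.sum() >= 2:
        half = max(2, int(np.ceil(pos.sum() / 2)))
        xs, ys = x[pos][:half], y[pos][:half]
        if xs.size >= 2 and np.ptp(xs) > 0:
            slope = np.polyfit(xs, np.log(ys - dmax0 + 1e-12), 1)[0]
            if slope < 0:
                k0 = float(-slope)
    try:
        popt, _ = curve_fit(
            _exp_decay, x, y, p0=[y0_0, dmax0, k0],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitError("exponential-decay fit did not converge", {"k0": k0}) from exc
    y0, dmax, k = map(float, popt)
    return DistributionFit(
        model="exp_decay",
        params={"Y0": y0, "Dmax": dmax, "k": k},
        r2=_r2(y, _exp_decay(x, *popt)),
        n_events=hist.n_events,
    )


def select_model(
    gauss: DistributionFit, decay: DistributionFit, tie_tolerance: float = 0.0
) -> ModelSelection:
    """Pick the model with the higher R²; equal R² is flagged as a tie."""
    delta = gauss.r2 - decay.r2
    if abs(delta) <= tie_tolerance:
        return ModelSelection(model=None, delta_r2=abs(delta), tie=True)
    winner = gauss if delta > 0 else decay
    return ModelSelection(model=winner.model, delta_r2=abs(delta), tie=False)
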