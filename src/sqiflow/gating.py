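"""Mixture-model gating of single-stain controls and the order statistics
used by the spread metrics.

A single-stain control acquisition contains two bead populations: blank
(unstained) beads and beads saturated with one antibody-fluorochrome
conjugate.  The two populations are separated on the primary-detector axis
by an expectation-maximisation (EM) fit of a two-component univariate
normal mixture, fitted by default to the absolute value of the compensated
intensities.  The gate for each population is the interquartile interval of
its fitted normal, [mean - z*sd, mean + z*sd] with z = Phi^-1(0.75), so a
well-fitted gate retains the central 50% of its component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import logsumexp
from scipy.stats import median_abs_deviation

from .fcs_io import EventTable

__all__ = [
    "MixtureFit",
    "PopulationPair",
    "DegenerateDataError",
    "GatingError",
    "em_two_component",
    "gate_single_stain",
    "percentile",
    "robust_sd",
    "QUARTILE_Z",
    "RECOMMENDED_MIN_EVENTS",
]

#: First/third quartile of a standard normal: Phi^-1(0.75).
QUARTILE_Z = 0.6744897501960817

#: Minimum recommended single-bead count for stable 99th percentiles.
RECOMMENDED_MIN_EVENTS = 35_000


class DegenerateDataError(ValueError):
    """Raised when the input carries no variance to fit a mixture on."""


class GatingError(RuntimeError):
    """Raised when the two bead populations cannot be separated."""


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate normal mixture, components in ascending mean order."""

    weight_low: float
    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float
    log_likelihood: float
    iterations: int
    converged: bool
    ll_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.mean_low <= self.mean_high):
            raise ValueError("components must be ordered by ascending mean")
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ValueError("component standard deviations must be positive")
        if not (0.0 < self.weight_low < 1.0):
            raise ValueError("weight_low must lie in (0, 1)")

    @property
    def weight_high(self) -> float:
        return 1.0 - self.weight_low


@dataclass
class PopulationPair:
    """Gated unstained/stained event indices for one single-stain control."""

    primary_channel: str
    unstained_index: np.ndarray
    stained_index: np.ndarray
    fit: MixtureFit
    unstained_gate: tuple[float, float] = (np.nan, np.nan)
    stained_gate: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        self.unstained_index = np.asarray(self.unstained_index, dtype=np.intp)
        self.stained_index = np.asarray(self.stained_index, dtype=np.intp)
        if self.unstained_index.size == 0 or self.stained_index.size == 0:
            raise GatingError("each gated population must be non-empty")
        if np.intersect1d(self.unstained_index, self.stained_index).size:
            raise ValueError("gated index sets must be disjoint")


# --------------------------------------------------------------------------
# order statistics
# --------------------------------------------------------------------------


def percentile(values: np.ndarray, q: float) -> float:
    """Order statistic with linear interpolation between closest ranks.

    This is the type-7 convention (numpy's default); q = 50 is the median.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("percentile of an empty vector is undefined")
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"q must be in [0, 100], got {q}")
    return float(np.percentile(values, q, method="linear"))


def robust_sd(
    values: np.ndarray, method: Literal["mad", "percentile"] = "mad"
) -> float:
    """Robust standard deviation of a gated population.

    ``mad``: 1.4826 x median absolute deviation from the median, the
    consistent estimator of sigma for normal data.  ``percentile``: half the
    central ~68.3% spread, (P84.13 - P15.87)/2, an alternative convention
    used by some analysis tools.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("robust_sd requires at least 2 values")
    if method == "mad":
        return float(median_abs_deviation(values, scale="normal"))
    if method == "percentile":
        return (percentile(values, 84.13) - percentile(values, 15.87)) / 2.0
    raise ValueError(f"unknown robust_sd method {method!r}")


# --------------------------------------------------------------------------
# EM mixture fit
# --------------------------------------------------------------------------


def _em_once(
    x: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    max_iter: int,
    tol: float,
    sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = x.size
    ll_prev = -np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step in log space
        log_comp = (
            np.log(weights)[:, None]
            - 0.5 * np.log(2.0 * np.pi)
            - np.log(sds)[:, None]
            - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        history.append(ll)
        resp = np.exp(log_comp - log_norm[None, :])
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - means**2
        sds = np.sqrt(np.maximum(var, sd_floor**2))
        weights = np.clip(weights, 1e-12, 1.0 - 1e-12)
        weights = weights / weights.sum()
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    return means, sds, weights, history[-1], it, converged, history


def em_two_component(
    values: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 3,
    random_state: int = 0,
) -> MixtureFit:
    """Fit a two-component univariate normal mixture by EM.

    Initialised by splitting at the overall median (each half seeds one
    component), plus ``n_restarts`` runs with perturbed means; the fit with
    the best log-likelihood wins.  Convergence: successive log-likelihoods
    differ by less than ``tol``.  Components are reported in ascending mean
    order.  A fit that exhausts ``max_iter`` is returned with
    ``converged=False`` and a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 50:
        raise ValueError(f"need at least 50 values for a mixture fit, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("all values identical: mixture fit is degenerate")

    overall_sd = float(np.std(x))
    sd_floor = max(1e-6 * np.ptp(x), 1e-12)
    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # median equals the maximum
        lo, hi = x[x < med], x[x >= med]
    base_means = np.array([lo.mean(), hi.mean()])
    base_sds = np.maximum(np.array([lo.std(), hi.std()]), sd_floor)
    base_weights = np.array([0.5, 0.5])

    rng = np.random.default_rng(random_state)
    inits = [(base_means, base_sds)]
    for _ in range(n_restarts):
        inits.append(
            (base_means + rng.normal(0.0, 0.5 * overall_sd, size=2), base_sds)
        )

    best = None
    for means0, sds0 in inits:
        means0 = np.sort(means0.astype(float))
        result = _em_once(
            x, means0.copy(), sds0.copy(), base_weights.copy(), max_iter, tol, sd_floor
        )
        if best is None or result[3] > best[3]:
            best = result
    means, sds, weights, ll, iters, converged, history = best

    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations "
            f"(last |delta log-likelihood| >= {tol})",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1 = float(weights[order][0])
    return MixtureFit(
        weight_low=w1,
        mean_low=float(m1),
        sd_low=float(s1),
        mean_high=float(m2),
        sd_high=float(s2),
        log_likelihood=float(ll),
        iterations=iters,
        converged=converged,
        ll_history=tuple(history),
    )


# --------------------------------------------------------------------------
# gating
# --------------------------------------------------------------------------


def _mixture_pdf(fit: MixtureFit, x: np.ndarray) -> np.ndarray:
    def comp(w, m, s):
        return w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))

    return comp(fit.weight_low, fit.mean_low, fit.sd_low) + comp(
        fit.weight_high, fit.mean_high, fit.sd_high
    )


def _trough_to_peak_ratio(fit: MixtureFit) -> float:
    """Minimum mixture density between the component means, relative to the
    smaller of the densities at the means; ~0 for separated populations."""
    if fit.mean_high == fit.mean_low:
        return 1.0
    grid = np.linspace(fit.mean_low, fit.mean_high, 201)
    dens = _mixture_pdf(fit, grid)
    peak = min(dens[0], dens[-1])
    if peak <= 0:
        return 0.0
    return float(dens.min() / peak)


def gate_single_stain(
    table: EventTable,
    primary_channel: str,
    use_abs: bool = True,
    min_events: int = 1000,
    max_iter: int = 500,
    tol: float = 1e-6,
    random_state: int = 0,
    singlet_ratio: tuple[str, str, float] | None = None,
) -> PopulationPair:
    """Gate the unstained and stained bead populations of one control.

    The EM mixture is fitted to the absolute values of the primary-channel
    intensities (``use_abs=False`` fits the signed values instead); each
    population's gate is the first-to-third-quartile interval of its fitted
    normal, and events are assigned by membership in those intervals on the
    same axis.  An event eligible for both gates goes to the component with
    the smaller standardised distance |x - mean| / sd.

    ``singlet_ratio=(height_channel, area_channel, threshold)`` optionally
    drops events whose height/area ratio falls below the threshold before
    fitting (a crude doublet filter).
    """
    if not table.compensated:
        raise ValueError("gate_single_stain requires a compensated event table")
    keep = np.ones(table.n_events, dtype=bool)
    if singlet_ratio is not None:
        h_name, a_name, threshold = singlet_ratio
        area = table.column(a_name)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = table.column(h_name) / area
        keep = np.isfinite(ratio) & (ratio > threshold)
    kept_idx = np.nonzero(keep)[0]
    if kept_idx.size < min_events:
        raise ValueError(
            f"only {kept_idx.size} events available; at least {min_events} required"
        )
    if kept_idx.size < RECOMMENDED_MIN_EVENTS:
        warnings.warn(
            f"{kept_idx.size} events is below the recommended minimum of "
            f"{RECOMMENDED_MIN_EVENTS} single beads; 99th-percentile statistics "
            "may be unstable",
            UserWarning,
            stacklevel=2,
        )

    raw = table.column(primary_channel)[kept_idx]
    axis = np.abs(raw) if use_abs else raw
    fit = em_two_component(
        axis, max_iter=max_iter, tol=tol, random_state=random_state
    )

    lo_gate = (fit.mean_low - QUARTILE_Z * fit.sd_low, fit.mean_low + QUARTILE_Z * fit.sd_low)
    hi_gate = (fit.mean_high - QUARTILE_Z * fit.sd_high, fit.mean_high + QUARTILE_Z * fit.sd_high)

    # A genuine single-stain control is bimodal: the fitted mixture density
    # must dip between the component means.  A unimodal sample split by EM
    # into two overlapping half-populations shows no such trough.
    if _trough_to_peak_ratio(fit) > 0.5:
        raise GatingError(
            "fitted mixture shows no density trough between components: "
            "input looks like a single population"
        )

    overlap = min(lo_gate[1], hi_gate[1]) - max(lo_gate[0], hi_gate[0])
    narrower = min(lo_gate[1] - lo_gate[0], hi_gate[1] - hi_gate[0])
    if overlap > 0.5 * narrower:
        raise GatingError(
            "unstained and stained gates overlap by more than half the narrower "
            f"gate (overlap {overlap:.3g} scale units): populations not separated"
        )

    in_lo = (axis >= lo_gate[0]) & (axis <= lo_gate[1])
    in_hi = (axis >= hi_gate[0]) & (axis <= hi_gate[1])
    both = in_lo & in_hi
    if both.any():
        d_lo = np.abs(axis[both] - fit.mean_low) / fit.sd_low
        d_hi = np.abs(axis[both] - fit.mean_high) / fit.sd_high
        to_hi = d_hi < d_lo
        idx_both = np.nonzero(both)[0]
        in_lo[idx_both[to_hi]] = False
        in_hi[idx_both[~to_hi]] = False

    unstained = kept_idx[in_lo]
    stained = kept_idx[in_hi]
    if unstained.size == 0 or stained.size == 0:
        raise GatingError("one of the gated populations is empty")
    return PopulationPair(
        primary_channel=primary_channel,
        unstained_index=unstained,
        stained_index=stained,
        fit=fit,
        unstained_gate=lo_gate,
        stained_gate=hi_gate,
    )
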