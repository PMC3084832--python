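"""Limiting-dilution analysis: frequency of reactive antibody-producing B cells.

The single-hit model assumes one reactive B cell is sufficient to make a
culture well reactive, so with per-cell frequency ``f`` and ``n`` cells plated
per well the number of reactive clones in a well is approximately
Poisson(f*n) and

    P(well non-reactive at dose n) = exp(-f * n).

Two estimators of ``f`` are provided:

``crossing37``
    The graphical criterion: the dose at which 37 % (e^-1) of wells are
    non-reactive equals 1/f.  Implemented reproducibly by linear interpolation
    of ln(fraction non-reactive) against dose — exact under the model, where
    ln F0(n) = -f*n is a straight line through the origin.

``mle``
    Maximum likelihood under the binomial dose-response
    k_nonreactive ~ Binomial(m, exp(-f*n)) per dose, with a profile-likelihood
    (default) or percentile-bootstrap confidence interval.  The log-likelihood
    is concave in f, so the score equation has a unique root.

A cohort-level shortcut, :func:`aggregate_frequency`, divides the number of
reactive cultures by the total B cells screened, valid only under the
assumption that each reactive culture arises from a single B cell; it
underestimates f when f * cells_per_well is not small (multi-clone wells
collapse to one positive culture).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

E_MINUS_1 = float(np.exp(-1.0))

__all__ = [
    "DilutionSeries",
    "FrequencyEstimate",
    "GofResult",
    "LimitingDilutionEstimator",
    "NoCrossingError",
    "UndefinedFrequencyError",
    "aggregate_frequency",
    "estimate_frequency_crossing37",
    "estimate_frequency_mle",
    "nonreactive_fractions",
    "single_hit_gof",
    "plot_dilution",
]


class NoCrossingError(ValueError):
    """Non-reactive fractions never bracket e^-1; the graphical criterion is
    undefined.  Use the MLE estimator instead."""


class UndefinedFrequencyError(ValueError):
    """Zero positive cultures: the aggregate frequency is undefined."""


class BoundaryEstimateWarning(UserWarning):
    """The MLE sits on the parameter boundary (all wells reactive, or none)."""


@dataclass(frozen=True)
class DilutionSeries:
    """Dose-response table for limiting-dilution analysis.

    One row per plating density: cells/well, wells tested, wells non-reactive.
    Rows are sorted by dose and duplicate doses are pooled on construction, so
    estimates are invariant to row order and duplicate-dose splits.
    """

    dose: np.ndarray          # cells per well
    tested: np.ndarray        # wells tested at that dose
    nonreactive: np.ndarray   # wells with no reactive culture

    @classmethod
    def from_arrays(cls, dose, tested, nonreactive) -> "DilutionSeries":
        dose = np.atleast_1d(np.asarray(dose, dtype=float))
        tested = np.atleast_1d(np.asarray(tested, dtype=float))
        nonreactive = np.atleast_1d(np.asarray(nonreactive, dtype=float))
        if not (len(dose) == len(tested) == len(nonreactive)):
            raise ValueError("dose, tested and nonreactive must have equal length")
        if len(dose) == 0:
            raise ValueError("empty dilution series")
        if (dose <= 0).any():
            raise ValueError("doses (cells/well) must be positive")
        if (tested < 1).any():
            raise ValueError("each dose needs at least one tested well")
        if ((nonreactive < 0) | (nonreactive > tested)).any():
            raise ValueError("need 0 <= nonreactive <= tested at every dose")
        df = (
            pd.DataFrame({"dose": dose, "tested": tested, "nonreactive": nonreactive})
            .groupby("dose", as_index=False)
            .sum()
            .sort_values("dose")
        )
        return cls(
            dose=df["dose"].to_numpy(float),
            tested=df["tested"].to_numpy(float),
            nonreactive=df["nonreactive"].to_numpy(float),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DilutionSeries":
        """Build from a table with columns dose_cells, n_wells, n_nonreactive."""
        for col in ("dose_cells", "n_wells", "n_nonreactive"):
            if col not in df.columns:
                raise ValueError(f"dilution table is missing column {col!r}")
        return cls.from_arrays(df["dose_cells"], df["n_wells"], df["n_nonreactive"])

    @classmethod
    def read_csv(cls, path) -> "DilutionSeries":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_cells": self.dose.astype(int),
             "n_wells": self.tested.astype(int),
             "n_nonreactive": self.nonreactive.astype(int)}
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.dose)


@dataclass
class FrequencyEstimate:
    """A per-cell reactive frequency with provenance.

    ``frequency`` is the per-cell probability f; ``one_in`` is 1/f rounded to
    the nearest 10 for reporting (the raw value is recoverable from
    ``frequency``).  ``ci_low``/``ci_high`` are on the frequency scale and may
    be NaN when undefined (boundary estimates carry a one-sided interval).
    """

    frequency: float
    method: str                      # crossing37 | mle | aggregate
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_level: float = float("nan")
    log_likelihood: float = float("nan")
    gof_p: float = float("nan")
    extra: dict = field(default_factory=dict)

    @property
    def one_in(self) -> float:
        """1/f rounded to the nearest 10 ("1 in 1,790" reporting style)."""
        if self.frequency <= 0:
            return float("inf")
        return float(round((1.0 / self.frequency) / 10.0) * 10)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        n = self.one_in
        label = "undefined" if not np.isfinite(n) else f"1 in {n:,.0f}"
        return f"FrequencyEstimate({label}, f={self.frequency:.3e}, method={self.method})"

    def to_dict(self) -> dict:
        d = {
            "frequency": self.frequency,
            "one_in": self.one_in,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "method": self.method,
            "log_likelihood": self.log_likelihood,
            "gof_p": self.gof_p,
        }
        d.update(self.extra)
        return d


@dataclass
class GofResult:
    """Single-hit goodness of fit (residual deviance against chi-square)."""

    applicable: bool
    deviance: float = float("nan")
    df: int = 0
    p_value: float = float("nan")


def nonreactive_fractions(series: DilutionSeries) -> np.ndarray:
    """Fraction of non-reactive wells per dose, in dose order."""
    return series.nonreactive / series.tested


def expected_nonreactive_percent(frequency: float, dose: float) -> float:
    """Model prediction 100 * exp(-f*n): percent of wells with zero reactive
    clones at the given plating density.  At n = 1/f this is 100*e^-1 (the 37 %
    criterion)."""
    if not 0 < frequency < 1:
        raise ValueError(f"frequency must be in (0, 1), got {frequency}")
    if dose <= 0:
        raise ValueError("dose must be positive")
    return 100.0 * float(np.exp(-frequency * dose))


def _log_fractions_for_interpolation(series: DilutionSeries) -> np.ndarray:
    """ln(fraction non-reactive) with a 0.5-count continuity correction for
    all-reactive doses (interpolation/plotting only; never used by the MLE)."""
    nonreactive = np.where(series.nonreactive == 0, 0.5, series.nonreactive)
    return np.log(nonreactive / series.tested)


def estimate_frequency_crossing37(series: DilutionSeries) -> FrequencyEstimate:
    """Frequency from the dose at which 37 % of wells are non-reactive.

    Finds the dose n37 where ln(fraction non-reactive) crosses -1 by linear
    interpolation against dose between the bracketing densities, and returns
    f = 1/n37.  Requires the observed fractions to bracket e^-1; otherwise
    raises :class:`NoCrossingError` (the MLE has no such requirement).
    """
    y = _log_fractions_for_interpolation(series)
    target = -1.0
    exact = np.isclose(y, target, atol=1e-12)
    if exact.any():
        n37 = float(series.dose[exact][0])
        return FrequencyEstimate(frequency=1.0 / n37, method="crossing37",
                                 extra={"n37": n37})
    above = y > target
    if above.all() or (~above).all():
        raise NoCrossingError(
            "non-reactive fractions never cross 37%; "
            "use estimate_frequency_mle, which needs no bracketing"
        )
    # first adjacent dose pair straddling the target (doses are sorted; under
    # the model y decreases with dose)
    idx = int(np.nonzero(above[:-1] & ~above[1:])[0][0])
    n1, n2 = series.dose[idx], series.dose[idx + 1]
    y1, y2 = y[idx], y[idx + 1]
    n37 = float(n1 + (target - y1) * (n2 - n1) / (y2 - y1))
    return FrequencyEstimate(frequency=1.0 / n37, method="crossing37",
                             extra={"n37": n37})


def _loglik(f: float, series: DilutionSeries) -> float:
    """Binomial log-likelihood of f under p_nonreactive(n) = exp(-f*n)."""
    n, m, k = series.dose, series.tested, series.nonreactive
    ll = -np.sum(k * f * n)
    pos = m - k
    mask = pos > 0
    if mask.any():
        with np.errstate(divide="ignore"):
            ll += np.sum(pos[mask] * np.log1p(-np.exp(-f * n[mask])))
    return float(ll)


def _score(f: float, series: DilutionSeries) -> float:
    n, m, k = series.dose, series.tested, series.nonreactive
    p = np.exp(-f * n)
    return float(np.sum(-k * n + (m - k) * n * p / (1.0 - p)))


def _mle_point(series: DilutionSeries) -> tuple[float, str]:
    """Return (f_hat, boundary) with boundary in {'', 'zero', 'upper'}."""
    total_reactive = float(np.sum(series.tested - series.nonreactive))
    total_nonreactive = float(np.sum(series.nonreactive))
    if total_reactive == 0:
        return 0.0, "zero"
    if total_nonreactive == 0:
        return 1.0, "upper"
    if len(series) == 1:
        # closed form: exp(-f*n) = k/m
        f = -np.log(series.nonreactive[0] / series.tested[0]) / series.dose[0]
        return float(f), ""
    # score is strictly decreasing (concave log-likelihood): bracket and solve
    lo, hi = 1e-12, 1.0
    while _score(hi, series) > 0 and hi < 1e6:  # pragma: no cover - defensive
        hi *= 10
    f_hat = optimize.brentq(_score, lo, hi, args=(series,), xtol=1e-14, rtol=1e-12)
    return float(f_hat), ""


def _profile_ci(series: DilutionSeries, f_hat: float, level: float) -> tuple[float, float]:
    ll_max = _loglik(f_hat, series)
    drop = stats.chi2.ppf(level, df=1) / 2.0

    def g(f):
        return _loglik(f, series) - (ll_max - drop)

    lo = float("nan")
    if f_hat > 0 and g(1e-14) < 0:
        lo = optimize.brentq(g, 1e-14, f_hat, xtol=1e-16)
    elif f_hat > 0:
        lo = 0.0
    hi = float("nan")
    upper = 1.0
    if g(upper) < 0:
        hi = optimize.brentq(g, max(f_hat, 1e-14), upper, xtol=1e-16)
    return lo, hi


def _bootstrap_ci(series: DilutionSeries, level: float, n_boot: int,
                  seed) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    p_obs = series.nonreactive / series.tested
    fs = np.empty(n_boot)
    for b in range(n_boot):
        k_star = rng.binomial(series.tested.astype(int), p_obs)
        boot = DilutionSeries.from_arrays(series.dose, series.tested, k_star)
        fs[b] = _mle_point(boot)[0]
    alpha = 1.0 - level
    lo, hi = np.quantile(fs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def estimate_frequency_mle(
    series: DilutionSeries,
    ci_level: float = 0.95,
    ci_method: str = "profile",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> FrequencyEstimate:
    """Maximum-likelihood frequency under the single-hit binomial model.

    The MLE maximizes sum_d [ k_d ln p_d + (m_d - k_d) ln(1 - p_d) ] with
    p_d = exp(-f * n_d).  Confidence intervals by profile likelihood (default)
    or seeded percentile bootstrap.  Degenerate data (every well reactive, or
    none) give a boundary estimate with a :class:`BoundaryEstimateWarning` and
    a one-sided interval.
    """
    f_hat, boundary = _mle_point(series)
    est = FrequencyEstimate(frequency=f_hat, method="mle", ci_level=ci_level,
                            log_likelihood=_loglik(f_hat, series) if boundary != "upper" else float("nan"))
    if boundary == "zero":
        warnings.warn(
            "all wells non-reactive: frequency estimate at the zero boundary",
            BoundaryEstimateWarning,
        )
        # ll(f) = -sum(m*n)*f; drop of chi2/2 gives the one-sided upper bound
        drop = stats.chi2.ppf(ci_level, df=1) / 2.0
        est.ci_low = 0.0
        est.ci_high = float(drop / np.sum(series.tested * series.dose))
        return est
    if boundary == "upper":
        warnings.warn(
            "all wells reactive: frequency estimate at the upper boundary",
            BoundaryEstimateWarning,
        )
        est.ci_high = 1.0
        drop = stats.chi2.ppf(ci_level, df=1) / 2.0

        def g(f):
            return _loglik(f, series) - (_loglik(1.0, series) - drop)

        # _loglik is increasing toward the boundary here; lower bound only
        try:
            est.ci_low = float(optimize.brentq(g, 1e-14, 1.0, xtol=1e-16))
        except ValueError:  # pragma: no cover - extremely small series
            est.ci_low = 0.0
        return est
    if ci_method == "profile":
        est.ci_low, est.ci_high = _profile_ci(series, f_hat, ci_level)
    elif ci_method == "bootstrap":
        est.ci_low, est.ci_high = _bootstrap_ci(series, ci_level, n_boot, seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    gof = single_hit_gof(series, est)
    est.gof_p = gof.p_value if gof.applicable else float("nan")
    return est


def aggregate_frequency(n_positive: int, n_cultures: int,
                        cells_per_culture: int = 500) -> FrequencyEstimate:
    """Cohort-level frequency assuming one reactive B cell per positive culture.

    f = n_positive / (n_cultures * cells_per_culture).  This is a lower bound
    on the true frequency: when f*cells_per_culture is not small, wells seeded
    with several reactive clones still count as a single positive culture.
    """
    if n_cultures < 1 or cells_per_culture < 1:
        raise ValueError("n_cultures and cells_per_culture must be >= 1")
    if not 0 <= n_positive <= n_cultures:
        raise ValueError("need 0 <= n_positive <= n_cultures")
    if n_positive == 0:
        raise UndefinedFrequencyError(
            "no positive cultures: aggregate frequency undefined"
        )
    f = n_positive / (n_cultures * cells_per_culture)
    return FrequencyEstimate(frequency=float(f), method="aggregate",
                             extra={"n_positive": n_positive,
                                    "n_cultures": n_cultures,
                                    "cells_per_culture": cells_per_culture})


def single_hit_gof(series: DilutionSeries, estimate: FrequencyEstimate) -> GofResult:
    """Deviance test of the exp(-f*n) fit against the saturated model.

    Residual deviance compared with chi-square on (number of doses - 1)
    degrees of freedom; not applicable to single-dose series (the fit is
    saturated there).
    """
    if len(series) < 2:
        return GofResult(applicable=False)
    f = estimate.frequency
    n, m, k = series.dose, series.tested, series.nonreactive
    p_hat = np.exp(-f * n)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(k > 0, k * np.log(k / (m * p_hat)), 0.0)
        term2 = np.where(m - k > 0, (m - k) * np.log((m - k) / (m * (1 - p_hat))), 0.0)
    deviance = float(2.0 * np.sum(term1 + term2))
    df = len(series) - 1
    return GofResult(applicable=True, deviance=deviance, df=df,
                     p_value=float(stats.chi2.sf(deviance, df)))


class LimitingDilutionEstimator(BaseEstimator):
    """Scikit-learn-style estimator for the per-cell reactive frequency.

    Parameters
    ----------
    method : {"mle", "crossing37"}
        Point estimator: maximum likelihood (default) or the 37 %-crossing
        graphical criterion.
    ci_level : float
        Confidence level for the interval (MLE only).
    ci_method : {"profile", "bootstrap"}
    n_boot, seed :
        Bootstrap resamples and seed when ``ci_method="bootstrap"``.

    Attributes
    ----------
    frequency_ : float
        Estimated per-cell frequency f.
    estimate_ : FrequencyEstimate
        Full result (CI, log-likelihood, goodness of fit).
    gof_ : GofResult
        Single-hit deviance goodness of fit (NaN p for single-dose series).

    Examples
    --------
    >>> s = DilutionSeries.from_arrays([500], [20], [15])
    >>> LimitingDilutionEstimator().fit(s).estimate_.one_in
    1740.0
    """

    def __init__(self, method: str = "mle", ci_level: float = 0.95,
                 ci_method: str = "profile", n_boot: int = 1000,
                 seed: int | None = 0):
        self.method = method
        self.ci_level = ci_level
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y=None):
        """Fit to a DilutionSeries (or a dose/wells/non-reactive table)."""
        series = X if isinstance(X, DilutionSeries) else DilutionSeries.from_dataframe(X)
        if self.method == "mle":
            self.estimate_ = estimate_frequency_mle(
                series, ci_level=self.ci_level, ci_method=self.ci_method,
                n_boot=self.n_boot, seed=self.seed,
            )
        elif self.method == "crossing37":
            self.estimate_ = estimate_frequency_crossing37(series)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.frequency_ = self.estimate_.frequency
        self.gof_ = single_hit_gof(series, self.estimate_)
        return self

    def predict(self, dose) -> np.ndarray:
        """Predicted fraction of non-reactive wells at the given dose(s)."""
        if not hasattr(self, "frequency_"):
            raise RuntimeError("estimator is not fitted")
        return np.exp(-self.frequency_ * np.asarray(dose, dtype=float))


def plot_dilution(series: DilutionSeries, estimate: FrequencyEstimate | None = None,
                  ax=None):
    """Semi-log dose-response plot: ln(fraction non-reactive) vs cells/well,
    with the e^-1 (37 %) criterion line and, if given, the fitted model."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    y = _log_fractions_for_interpolation(series)
    ax.plot(series.dose, y, "o-", label="observed")
    ax.axhline(-1.0, linestyle=":", color="gray", label="37% non-reactive")
    if estimate is not None and estimate.frequency > 0:
        grid = np.linspace(0, series.dose.max(), 100)
        ax.plot(grid, -estimate.frequency * grid, "--",
                label=f"fit: 1 in {estimate.one_in:,.0f}")
    ax.set_xlabel("B cells plated per well")
    ax.set_ylabel("ln(fraction non-reactive)")
    ax.legend()
    return ax
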