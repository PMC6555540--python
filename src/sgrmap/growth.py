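"""Doubling times, suppression indices and mutation-frequency estimates.

Doubling times are fitted by ordinary least squares of log2(OD) on time
over an automatically selected exponential-phase window; the doubling
time is the reciprocal of the fitted slope.  Suppressor-mutation
frequencies are plain colony-per-viable-cell ratios with exact binomial
(Clopper-Pearson) intervals, and the UV mutagenesis effect is the ratio
of the UV-induced to the spontaneous frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .simulate import FluctuationCounts, GrowthCurve

__all__ = [
    "DoublingEstimate",
    "SuppressionIndex",
    "FrequencyEstimate",
    "fit_doubling_time",
    "suppression_index",
    "estimate_frequency",
    "uv_fold",
]


@dataclass(frozen=True)
class DoublingEstimate:
    strain: str
    tau_hat: float          # minutes
    se: float               # delta-method standard error, minutes
    fit_window: tuple[int, int]  # [start, stop) indices of points used
    r_squared: float


@dataclass(frozen=True)
class SuppressionIndex:
    """Fraction of a growth defect rescued by a suppressor.

    1 means the double mutant grows like wild type, 0 means no rescue.
    """

    value: float
    tau_wt: float
    tau_mut: float
    tau_double: float


@dataclass(frozen=True)
class FrequencyEstimate:
    condition: str
    frequency: float
    ci_low: float
    ci_high: float
    colonies: int
    viable_cells: float


def _ols_log2(t: np.ndarray, log2_od: np.ndarray):
    res = stats.linregress(t, log2_od)
    # guard against tiny negative rounding in r**2 for perfect fits
    r2 = min(res.rvalue**2, 1.0)
    return res.slope, res.stderr, r2


def fit_doubling_time(curve: GrowthCurve, fit_window: tuple[int, int] | None = None) -> DoublingEstimate:
    """Log-linear OLS estimate of the doubling time.

    The exponential window defaults to the full series when its R^2 is
    at least 0.99; otherwise every contiguous run of >= 4 points is
    scanned and the run maximising R^2 (longest on ties) is used.  An
    explicit ``fit_window`` of point indices overrides the selection.

    Raises ``ValueError`` when the fitted slope is not positive.
    """
    t = curve.times
    y = np.log2(curve.od)
    n = t.size

    if fit_window is not None:
        a, b = fit_window
        if b - a < 4:
            raise ValueError("fit window must contain at least 4 points")
        window = (a, b)
        slope, stderr, r2 = _ols_log2(t[a:b], y[a:b])
    else:
        slope, stderr, r2 = _ols_log2(t, y)
        window = (0, n)
        if r2 < 0.99:
            best = (-np.inf, 0)  # (r2 rounded, length)
            for a in range(0, n - 3):
                for b in range(a + 4, n + 1):
                    s, se, r2_ab = _ols_log2(t[a:b], y[a:b])
                    key = (round(r2_ab, 10), b - a)
                    if key > best:
                        best = key
                        slope, stderr, r2, window = s, se, r2_ab, (a, b)

    if slope <= 0:
        raise ValueError("no positive growth detected (slope <= 0)")
    tau = 1.0 / slope
    se_tau = stderr / slope**2 if np.isfinite(stderr) else 0.0
    return DoublingEstimate(
        strain=curve.strain, tau_hat=tau, se=se_tau, fit_window=window, r_squared=r2
    )


def suppression_index(tau_wt: float, tau_mut: float, tau_double: float) -> SuppressionIndex:
    """Fraction of the doubling-time defect rescued by a suppressor.

    ``(tau_mut - tau_double) / (tau_mut - tau_wt)``; unit-free, so
    invariant to expressing the three doubling times in any common unit.
    """
    if tau_mut <= tau_wt:
        raise ValueError("no growth defect to suppress (tau_mut <= tau_wt)")
    value = (tau_mut - tau_double) / (tau_mut - tau_wt)
    return SuppressionIndex(value=value, tau_wt=tau_wt, tau_mut=tau_mut, tau_double=tau_double)


def estimate_frequency(fc: FluctuationCounts, confidence: float = 0.95) -> FrequencyEstimate:
    """Suppressor frequency per viable plated cell with an exact CI.

    Viable cells = cells_plated * survival_fraction (UV kills part of
    the plating).  The interval is Clopper-Pearson on the colony count
    over viable cells.
    """
    viable = fc.cells_plated * fc.survival_fraction
    if viable <= 0:
        raise ValueError("no viable cells plated")
    k = fc.suppressor_colonies
    freq = k / viable
    lo, hi = proportion_confint(k, int(round(viable)), alpha=1 - confidence, method="beta")
    return FrequencyEstimate(
        condition=fc.condition, frequency=freq,
        ci_low=float(lo), ci_high=float(hi),
        colonies=k, viable_cells=viable,
    )


def uv_fold(spont: FrequencyEstimate, uv: FrequencyEstimate, confidence: float = 0.95):
    """Fold increase of the mutation frequency after UV, with a CI.

    Fold = uv.frequency / spont.frequency; the interval comes from the
    delta method on the log scale using the two binomial standard
    errors, so it is approximate and requires at least one colony in
    each condition.
    """
    if spont.frequency <= 0:
        raise ValueError(
            "spontaneous frequency is zero; report a lower bound on the fold "
            "from its CI upper limit instead"
        )
    if uv.frequency <= 0:
        raise ValueError("UV frequency is zero; fold undefined")
    fold = uv.frequency / spont.frequency
    # binomial SE of each frequency on its viable-cell denominator
    var_log = 0.0
    for est in (spont, uv):
        se = np.sqrt(est.frequency * (1 - est.frequency) / est.viable_cells)
        var_log += (se / est.frequency) ** 2
    z = stats.norm.ppf(0.5 + confidence / 2)
    half = z * np.sqrt(var_log)
    return fold, (fold * np.exp(-half), fold * np.exp(half))
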