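"""Per-subject dose-response analytics.

Fits the four-parameter log-logistic activation curve to one subject's
percent-activated series, flags basophil nonresponders, and derives the two
summary metrics used to read BAT beyond single-concentration reactivity:

* **CD-sens** — basophil allergen threshold sensitivity, ``100 / EC50`` with
  EC50 in µg/mL (the concentration at half-maximal activation, taken from
  the fitted curve). Higher CD-sens means the basophils respond at lower
  allergen doses. Undefined for nonresponders, mirroring clinical practice:
  a half-maximal concentration does not exist on a flat curve.
* **curve AUC** — trapezoidal area of background-subtracted activation over
  the log10-concentration axis (percent · log10-units). Needs no fit, so it
  is available for every subject, responder or not.

Also provides the data-driven selection of the stimulation concentrations
that best discriminate allergic subjects from controls.
"""
from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .errors import InputError, UndefinedValueError
from .synthetic import latent_logistic
from .types import BATSeries, DoseResponseFit, SubjectRecord

__all__ = [
    "fit_curve", "is_responder", "cd_sens", "curve_auc",
    "select_discriminating_concentrations",
    "DEFAULT_MIN_PEAK", "DEFAULT_FOLD_OVER_BACKGROUND", "BACKGROUND_FLOOR",
]

#: Nonresponder-rule defaults: a subject responds if their peak activation
#: reaches 5% and at least doubles the background (background floored at
#: 0.5% so a near-zero unstimulated well cannot make the fold test vacuous).
DEFAULT_MIN_PEAK = 5.0
DEFAULT_FOLD_OVER_BACKGROUND = 2.0
BACKGROUND_FLOOR = 0.5

_SLOPE_BOUNDS = (0.3, 5.0)


def is_responder(series: BATSeries,
                 min_peak: float = DEFAULT_MIN_PEAK,
                 fold_over_background: float = DEFAULT_FOLD_OVER_BACKGROUND,
                 background_floor: float = BACKGROUND_FLOOR) -> bool:
    """Peak-activation nonresponder rule.

    True iff ``max(activation) >= min_peak`` and
    ``max(activation) >= fold_over_background * max(background, floor)``.
    """
    peak = float(np.max(series.activation_pct))
    ref = max(float(series.background_pct), background_floor)
    return peak >= min_peak and peak >= fold_over_background * ref


def _model(theta, logc):
    # Reparametrised so the box 0<=b, 0<=E, b+E<=100 is exact:
    # theta = (b, s, m, h) with E = s * (100 - b), s in [0, 1].
    b, s, m, h = theta
    E = s * (100.0 - b)
    return b + E / (1.0 + 10.0 ** (h * (m - logc)))


_LN10 = np.log(10.0)


def _jac(theta, logc):
    b, s, m, h = theta
    g = 10.0 ** (h * (m - logc))
    D = 1.0 + g
    E = s * (100.0 - b)
    J = np.empty((len(logc), 4))
    J[:, 0] = 1.0 - s / D
    J[:, 1] = (100.0 - b) / D
    J[:, 2] = -E * g * _LN10 * h / D ** 2
    J[:, 3] = -E * g * _LN10 * (m - logc) / D ** 2
    return J


def fit_curve(series: BATSeries, concentrations,
              min_peak: float = DEFAULT_MIN_PEAK,
              fold_over_background: float = DEFAULT_FOLD_OVER_BACKGROUND) -> DoseResponseFit:
    """Constrained least-squares fit of the log-logistic curve to one series.

    Box constraints: ``0 <= b``, ``0 <= E``, ``b + E <= 100``, slope in
    [0.3, 5], log10 EC50 within one decade of the measured concentration
    range. Multistart over a grid of EC50 starting values (one per measured
    concentration) guards against the local minima that plateau-heavy series
    create. Nonresponders keep their baseline estimate but report the
    remaining parameters (and CD-sens) as NaN.
    """
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(series.activation_pct, dtype=float)
    if len(conc) < 4 or len(y) != len(conc):
        raise InputError(
            f"need >= 4 aligned concentration points, got {len(y)} values "
            f"for {len(conc)} concentrations")
    if np.any((y < 0) | (y > 100)):
        raise InputError("activation percentages must lie in [0, 100]")
    logc = np.log10(conc)

    responder = is_responder(series, min_peak, fold_over_background)
    auc = curve_auc(series, conc)

    if np.ptp(y) == 0.0:
        # Degenerate flat series: exact flat fit, no optimisation.
        return DoseResponseFit(
            series.subject_id, series.allergen, series.marker,
            baseline_hat=float(y[0]), emax_hat=0.0,
            log10_ec50_hat=np.nan, slope_hat=np.nan, cd_sens=np.nan,
            curve_auc=auc, responder=responder, fit_converged=True)

    m_lo, m_hi = logc[0] - 1.0, logc[-1] + 1.0
    b0 = float(np.clip(y.min(), 0.0, 99.0))
    s0 = float(np.clip((y.max() - y.min()) / (100.0 - b0), 1e-3, 1.0))
    lower = [0.0, 0.0, m_lo, _SLOPE_BOUNDS[0]]
    upper = [100.0, 1.0, m_hi, _SLOPE_BOUNDS[1]]

    best = None
    for m_start in logc:  # one start per measured concentration
        x0 = np.clip([b0, s0, m_start, 1.0],
                     np.asarray(lower) + 1e-9, np.asarray(upper) - 1e-9)
        try:
            res = optimize.least_squares(
                lambda th: _model(th, logc) - y, x0, jac=lambda th: _jac(th, logc),
                bounds=(lower, upper), xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-18 * max(1, len(y)):
            break  # exact interpolation reached; later starts cannot improve
    converged = best is not None and best.success

    if best is None:
        b_hat = float(np.min(y))
        e_hat = m_hat = h_hat = np.nan
    else:
        b_hat, s_hat, m_hat, h_hat = (float(v) for v in best.x)
        e_hat = s_hat * (100.0 - b_hat)

    if not responder:
        e_hat = m_hat = h_hat = np.nan
    cdsens = (100.0 / 10.0 ** m_hat) if (responder and converged
                                         and np.isfinite(m_hat)) else np.nan
    return DoseResponseFit(
        series.subject_id, series.allergen, series.marker,
        baseline_hat=b_hat, emax_hat=e_hat, log10_ec50_hat=m_hat,
        slope_hat=h_hat, cd_sens=cdsens, curve_auc=auc,
        responder=responder, fit_converged=converged)


def cd_sens(fit: DoseResponseFit,
            series: BATSeries = None, concentrations=None,
            interpolate: bool = False) -> float:
    """Basophil allergen threshold sensitivity, ``100 / C50`` (C50 in µg/mL).

    By default C50 is the fitted EC50 (``10**log10_ec50_hat``) — stable under
    counting noise. With ``interpolate=True`` and the raw series supplied,
    C50 is instead found by log-linear interpolation between the measured
    points that bracket half-maximal activation (sensitivity analysis only).
    """
    if not (fit.responder and fit.fit_converged):
        raise UndefinedValueError(
            f"CD-sens undefined for {fit.subject_id}/{fit.allergen}/{fit.marker}: "
            "cannot be calculated in nonallergic (nonresponding) individuals")
    if not interpolate:
        return 100.0 / 10.0 ** fit.log10_ec50_hat
    if series is None or concentrations is None:
        raise InputError("interpolated CD-sens needs the raw series and concentrations")
    y = np.asarray(series.activation_pct, dtype=float)
    logc = np.log10(np.asarray(concentrations, dtype=float))
    half = fit.baseline_hat + fit.emax_hat / 2.0
    above = np.nonzero(y >= half)[0]
    if len(above) == 0 or above[0] == 0:
        return 100.0 / 10.0 ** (logc[0] if len(above) else fit.log10_ec50_hat)
    j = above[0]
    frac = (half - y[j - 1]) / (y[j] - y[j - 1])
    log_c50 = logc[j - 1] + frac * (logc[j] - logc[j - 1])
    return 100.0 / 10.0 ** log_c50


def curve_auc(series: BATSeries, concentrations,
              background_subtract: bool = True,
              log_axis: bool = True) -> float:
    """Trapezoidal area of (background-subtracted, floored at 0) activation
    over the log10-concentration axis; percent · log10-units."""
    y = np.asarray(series.activation_pct, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if len(y) < 2 or len(conc) != len(y):
        raise InputError("curve AUC needs >= 2 aligned points")
    if background_subtract:
        y = np.maximum(y - float(series.background_pct), 0.0)
    x = np.log10(conc) if log_axis else conc
    return float(np.trapezoid(y, x))


def select_discriminating_concentrations(all_series, subjects, k: int,
                                         concentrations,
                                         marker: str = None,
                                         allergen: str = None):
    """Rank stimulation concentrations by control-vs-allergic separation.

    Separation at each concentration is the two-sample rank statistic
    (Mann-Whitney U scaled to [0,1], i.e. the probability an allergic
    subject's activation exceeds a control's, ties half-weighted). Ties in
    the ranking break toward the higher concentration. Returns the top ``k``
    concentrations (µg/mL) in ascending order.
    """
    from .diagnostics import roc_auc  # local import to avoid a cycle

    conc = np.asarray(concentrations, dtype=float)
    n_conc = len(conc)
    if not (1 <= k <= n_conc):
        raise InputError(f"k must be in [1, {n_conc}], got {k}")
    cohort_of = {s.subject_id: s.cohort for s in subjects}
    pool = [s for s in all_series
            if (marker is None or s.marker == marker)
            and (allergen is None or s.allergen == allergen)
            and len(s.activation_pct) == n_conc]
    if not pool:
        raise InputError("no series match the requested marker/allergen")

    allergic = [s for s in pool if cohort_of[s.subject_id] == "ALLERGIC"]
    control = [s for s in pool if cohort_of[s.subject_id] == "CONTROL"]
    if not allergic or not control:
        raise InputError("both cohorts must be represented among the series")

    scores = []
    for i in range(n_conc):
        va = [s.activation_pct[i] for s in allergic]
        vc = [s.activation_pct[i] for s in control]
        scores.append(roc_auc(va, vc))
    # Sort by (score, index): equal scores prefer the higher concentration.
    order = sorted(range(n_conc), key=lambda i: (scores[i], i), reverse=True)
    return [float(conc[i]) for i in sorted(order[:k])]
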