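"""ROC-based diagnostic cut-offs and the BAT positivity rule.

A cut-off for "positive BAT" is derived per marker × stimulation
concentration from the empirical ROC curve of percent-activated values in
allergic subjects versus controls; the working point maximises the Youden
index J = sensitivity + specificity − 100 (a max-accuracy alternative is
pluggable). A subject is then called BAT-positive for a marker when their
activation exceeds the per-concentration cut-off at two or more
*consecutive* concentrations — a run requirement that suppresses isolated
noisy exceedances.

Empirical AUC is computed in its Mann-Whitney form (the probability a
random allergic value exceeds a random control value, ties half-weighted),
which equals the trapezoidal area under the empirical ROC curve.
"""
from __future__ import annotations

import numpy as np

from .errors import InputError
from .types import BATSeries, CutoffEntry, PositivityCall

__all__ = [
    "roc_curve", "roc_auc", "optimal_cutoff", "derive_cutoffs",
    "classify_subject", "positivity_rate", "PAPER_DEFAULT_CUTOFFS",
]


def roc_curve(values_allergic, values_control):
    """Empirical ROC curve over midpoint thresholds.

    Thresholds are midpoints between consecutive distinct pooled values,
    plus sentinels below the minimum and above the maximum. At threshold t:
    sensitivity = % of allergic values > t, specificity = % of controls <= t.
    Returns a list of ``(threshold, sensitivity_pct, specificity_pct)``
    ordered by ascending threshold.
    """
    a = np.asarray(values_allergic, dtype=float)
    c = np.asarray(values_control, dtype=float)
    if a.size == 0 or c.size == 0:
        raise InputError("both the allergic and control value lists must be nonempty")
    pooled = np.unique(np.concatenate([a, c]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    thresholds = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    out = []
    for t in thresholds:
        sens = 100.0 * np.mean(a > t)
        spec = 100.0 * np.mean(c <= t)
        out.append((float(t), float(sens), float(spec)))
    return out


def roc_auc(values_allergic, values_control) -> float:
    """Empirical AUC: Mann-Whitney U scaled to [0, 1], ties counted 1/2."""
    a = np.asarray(values_allergic, dtype=float)
    c = np.asarray(values_control, dtype=float)
    if a.size == 0 or c.size == 0:
        raise InputError("both the allergic and control value lists must be nonempty")
    diff = a[:, None] - c[None, :]
    u = np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
    return float(u / (a.size * c.size))


def optimal_cutoff(curve, n_allergic: int, n_control: int,
                   criterion: str = "youden"):
    """Pick the working point on an empirical ROC curve.

    ``criterion='youden'`` maximises J = sens + spec − 100;
    ``criterion='accuracy'`` maximises (TP+TN)/(P+N). Ties break toward
    larger specificity, then larger threshold. PPV/NPV come from the
    confusion counts at the observed cohort composition. Returns a dict
    fragment (threshold + metrics) for :class:`CutoffEntry` assembly;
    ``informative`` is False when the best J is 0 (complete overlap).
    """
    if not curve:
        raise InputError("empty ROC curve")

    def score(point):
        t, sens, spec = point
        if criterion == "youden":
            s = sens + spec - 100.0
        elif criterion == "accuracy":
            tp = sens / 100.0 * n_allergic
            tn = spec / 100.0 * n_control
            s = (tp + tn) / (n_allergic + n_control)
        else:
            raise InputError(f"unknown cut-off criterion {criterion!r}")
        return (s, spec, t)

    t, sens, spec = max(curve, key=score)
    tp = sens / 100.0 * n_allergic
    fn = n_allergic - tp
    tn = spec / 100.0 * n_control
    fp = n_control - tn
    ppv = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else np.nan
    npv = 100.0 * tn / (tn + fn) if (tn + fn) > 0 else np.nan
    j = sens + spec - 100.0
    return {
        "cutoff": float(t), "sensitivity": float(sens),
        "specificity": float(spec), "ppv": float(ppv), "npv": float(npv),
        "youden_j": float(j), "informative": bool(j > 0),
    }


def derive_cutoffs(all_series, subjects, concentrations, evaluated,
                   marker: str, allergen: str = "PRU_P_3",
                   criterion: str = "youden"):
    """Derive one :class:`CutoffEntry` per evaluated concentration.

    ``evaluated`` lists the concentrations (µg/mL, subset of
    ``concentrations``) at which a cut-off is wanted, typically the
    discriminating ones.
    """
    conc = np.asarray(concentrations, dtype=float)
    cohort_of = {s.subject_id: s.cohort for s in subjects}
    pool = [s for s in all_series if s.marker == marker and s.allergen == allergen]
    if not pool:
        raise InputError(f"no series for marker {marker!r} / allergen {allergen!r}")
    entries = []
    for cv in evaluated:
        matches = np.nonzero(np.isclose(conc, cv, rtol=1e-9))[0]
        if len(matches) == 0:
            raise InputError(f"evaluated concentration {cv} not among the data concentrations")
        i = int(matches[0])
        va = [s.activation_pct[i] for s in pool if cohort_of[s.subject_id] == "ALLERGIC"]
        vc = [s.activation_pct[i] for s in pool if cohort_of[s.subject_id] == "CONTROL"]
        curve = roc_curve(va, vc)
        frag = optimal_cutoff(curve, len(va), len(vc), criterion=criterion)
        # Orientation "allergic => higher activation" gives AUC >= 0.5 on any
        # informative data; report as computed.
        entries.append(CutoffEntry(
            marker=marker, concentration=float(cv),
            roc_auc=roc_auc(va, vc), **frag))
    return entries


def classify_subject(series: BATSeries, cutoffs, concentrations_evaluated,
                     concentrations=None) -> PositivityCall:
    """BAT positivity call for one subject × marker.

    ``exceeded[i]`` is True when activation at the i-th evaluated
    concentration is strictly greater than that concentration's cut-off;
    the call is positive iff ``exceeded`` contains >= 2 consecutive True
    values. ``concentrations`` gives the axis of ``series.activation_pct``
    (defaults to the evaluated list when the series is already restricted).
    """
    evaluated = [float(c) for c in concentrations_evaluated]
    if any(evaluated[i] >= evaluated[i + 1] for i in range(len(evaluated) - 1)):
        raise InputError("evaluated concentrations must be ascending")
    axis = np.asarray(concentrations if concentrations is not None else evaluated,
                      dtype=float)
    cutoff_by_conc = {}
    for e in cutoffs:
        if e.marker == series.marker:
            cutoff_by_conc[float(e.concentration)] = float(e.cutoff)

    exceeded = []
    for cv in evaluated:
        idx = np.nonzero(np.isclose(axis, cv, rtol=1e-9))[0]
        if len(idx) == 0:
            raise InputError(
                f"subject {series.subject_id}: no measurement at evaluated "
                f"concentration {cv} µg/mL")
        matching = [c for c in cutoff_by_conc if np.isclose(c, cv, rtol=1e-9)]
        if not matching:
            raise InputError(
                f"no {series.marker} cut-off supplied for concentration {cv} µg/mL")
        exceeded.append(bool(series.activation_pct[int(idx[0])] > cutoff_by_conc[matching[0]]))

    positive = any(exceeded[i] and exceeded[i + 1] for i in range(len(exceeded) - 1))
    return PositivityCall(
        subject_id=series.subject_id, marker=series.marker,
        positive=positive, exceeded=tuple(exceeded),
        concentrations=tuple(evaluated))


def positivity_rate(calls, subjects, grouping: str = "cohort"):
    """Percent BAT-positive per group.

    ``grouping`` is a SubjectRecord attribute (``cohort``, ``severity``,
    ``peanut_group``) or ``"all"``. Returns ``{group: (percent, n_positive,
    n_total)}``; groups with no calls are reported as missing (absent), not
    as 0%.
    """
    by_subject = {}
    for call in calls:
        by_subject.setdefault(call.subject_id, []).append(call)
    out = {}
    groups = {}
    for subj in subjects:
        key = "ALL" if grouping == "all" else getattr(subj, grouping)
        groups.setdefault(key, []).append(subj)
    for key, members in groups.items():
        n_pos = n_tot = 0
        for subj in members:
            for call in by_subject.get(subj.subject_id, []):
                n_tot += 1
                n_pos += int(call.positive)
        if n_tot:
            out[key] = (100.0 * n_pos / n_tot, n_pos, n_tot)
    return out


#: Published reference cut-offs (percent activated) for Pru p 3 BAT at the
#: three discriminating concentrations — shipped so the classifier can be
#: applied to new data with the original study's thresholds. The PPV/NPV
#: printed alongside them are reference constants, not recomputable from the
#: entries alone.
PAPER_DEFAULT_CUTOFFS = (
    CutoffEntry("CD63", 1e-1, 0.947, 12.35, 85.26, 93.75, 100.0, 100.0),
    CutoffEntry("CD63", 1e-2, 0.938, 5.87, 92.05, 87.50, 97.8, 100.0),
    CutoffEntry("CD63", 1e-3, 0.914, 6.605, 85.06, 93.75, 98.7, 53.6),
    CutoffEntry("CD203c", 1e-1, 1.0, 9.96, 100.0, 100.0, 100.0, 100.0),
    CutoffEntry("CD203c", 1e-2, 0.973, 17.25, 80.48, 100.0, 100.0, 71.4),
    CutoffEntry("CD203c", 1e-3, 0.951, 9.655, 92.06, 100.0, 100.0, 75.0),
)
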