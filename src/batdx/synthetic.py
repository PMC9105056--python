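"""Synthetic BAT cohort generator.

Emulates the data structure of an LTP-allergy BAT study: a control group and
an allergic cohort split into three reaction-severity groups (oral allergy
syndrome, urticaria/angioedema, anaphylaxis), with the allergic cohort
further divided into peanut-tolerant (Group A) and peanut-allergic (Group B)
subsets. Each subject carries clinical metadata (IgE serology, SPT wheal
areas, profilin co-sensitization) and, per allergen × activation marker, a
percent-activated series over seven ten-fold stimulation concentrations.

The observation model is summary-level: the latent per-subject dose-response
curve is a four-parameter log-logistic, and each well's observed percent is
a binomial draw over ``n_events_per_well`` basophil events — the minimal
counting-noise mechanism consistent with flow-cytometry percentages. Allergic
subjects are responders by construction (the generator emulates an analyzed
cohort from which any BAT nonresponder has already been excluded).

Peanut-tolerant subjects get a strictly attenuated Ara h 9 Emax relative to
their Pru p 3 curve; peanut-allergic subjects a comparable one. The
attenuation applies to the CD63 readout; whether it also applies to CD203c
is switchable (default off, matching the readout asymmetry this emulates).
"""
from __future__ import annotations

import numpy as np

from .errors import BatDxError
from .types import (
    BATSeries,
    GroupBlock,
    SimulationConfig,
    SubjectRecord,
)

__all__ = ["latent_logistic", "simulate_cohort"]


def latent_logistic(c, b, E, m, h):
    """Four-parameter log-logistic activation curve.

    ``b + E / (1 + 10**(h * (m - log10(c))))`` — baseline ``b`` percent,
    span ``E`` percent, ``m`` the log10 EC50 (µg/mL), Hill slope ``h`` > 0.
    Monotone nondecreasing in ``c``; evaluates elementwise on arrays.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise BatDxError("concentration must be > 0")
    out = b + E / (1.0 + 10.0 ** (h * (m - np.log10(c))))
    return out if out.ndim else float(out)


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Rejection-free truncated normal via clipping — adequate for the mild
    truncation used here (tails re-massed at the bounds)."""
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _lognormal(rng, median, sigma):
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _draw_curve(rng, block: GroupBlock, coupling: float = 0.0):
    """Draw one latent curve. ``coupling`` is the loading of a shared
    subject-level factor on both Emax and −log10 EC50: basophils that mount
    larger responses also tend to respond at lower allergen doses, which is
    what couples reactivity (AUC) to sensitivity (CD-sens) in real cohorts."""
    b = _truncnorm(rng, block.baseline_mean, block.baseline_sd, 0.2, 3.0)
    u = rng.normal()
    w = float(np.sqrt(max(0.0, 1.0 - coupling ** 2)))
    zE = coupling * u + w * rng.normal()
    zm = -coupling * u + w * rng.normal()
    E = float(np.clip(block.emax_mean + block.emax_sd * zE, block.emax_lo,
                      min(block.emax_hi, 100.0 - b)))
    m = float(np.clip(block.log10_ec50_mean + block.log10_ec50_sd * zm,
                      -6.5, -2.5))
    h = _truncnorm(rng, block.hill_mean, block.hill_sd, 0.6, 3.0)
    return float(b), E, m, float(h)


def _observe(rng, latent_pct, n_events, noise_free):
    """Binomial counting noise: percent -> event count -> percent."""
    latent_pct = np.clip(np.asarray(latent_pct, dtype=float), 0.0, 100.0)
    if noise_free:
        return latent_pct
    counts = rng.binomial(n_events, latent_pct / 100.0)
    return 100.0 * counts / n_events


def _subject_metadata(rng, sid, cohort, severity, peanut_group, cfg):
    block: GroupBlock = cfg.group_parameter_blocks[
        "CONTROL" if cohort == "CONTROL" else severity]
    age = float(_truncnorm(rng, block.age_mean, block.age_sd, 18.0, 80.0))
    sex = "F" if rng.random() < block.female_prob else "M"
    tige = _lognormal(rng, block.tige_median, block.tige_sigma)
    sige_p = _lognormal(rng, block.sige_prup3_median, block.sige_prup3_sigma)
    sige_a = _lognormal(rng, block.sige_arah9_median, block.sige_arah9_sigma)
    spt_peach = _lognormal(rng, block.spt_peach_median, block.spt_peach_sigma)
    spt_peanut = _lognormal(rng, block.spt_peanut_median, block.spt_peanut_sigma)
    if cohort == "CONTROL":
        # Controls are non-sensitized by construction: sIgE below the 0.35
        # kU/L assay positivity threshold, SPT wheals below 7 mm².
        sige_p = min(sige_p, 0.34)
        sige_a = min(sige_a, 0.34)
        spt_peach = min(spt_peach, 6.5)
        spt_peanut = min(spt_peanut, 6.5)
        profilin = False
    else:
        profilin = bool(rng.random() < cfg.profilin_probs.get(severity, 0.0))
    return SubjectRecord(
        subject_id=sid, cohort=cohort, severity=severity,
        peanut_group=peanut_group, profilin_sensitized=profilin,
        age=round(age, 1), sex=sex,
        total_ige=round(tige, 2), sige_prup3=round(sige_p, 3),
        sige_arah9=round(sige_a, 3),
        spt_peach_area=round(spt_peach, 1), spt_peanut_area=round(spt_peanut, 1),
    )


def simulate_cohort(config: SimulationConfig):
    """Generate ``(subjects, series)`` for one synthetic cohort.

    Deterministic given ``config.seed``: one ``numpy`` Generator drives every
    draw in a fixed subject/allergen/marker order. Each subject gets one
    :class:`BATSeries` per requested (allergen, marker) pair.

    Returns
    -------
    subjects : list of SubjectRecord
    series : list of BATSeries
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.concentrations, dtype=float)

    plan = (
        [("CONTROL", "NONE")] * config.n_controls
        + [("ALLERGIC", "OAS")] * config.n_oas
        + [("ALLERGIC", "URT_ANG")] * config.n_urt_ang
        + [("ALLERGIC", "ANAPH")] * config.n_anaph
    )
    n_allergic = config.n_oas + config.n_urt_ang + config.n_anaph
    # Peanut-allergic (Group B) membership spread over the allergic cohort.
    allergic_idx = rng.permutation(n_allergic)
    group_b = set(allergic_idx[: config.n_group_b])

    subjects, series = [], []
    allergic_seen = 0
    for i, (cohort, severity) in enumerate(plan):
        sid = f"S{i + 1:03d}"
        if cohort == "CONTROL":
            pg = "NA"
        else:
            pg = "B_ALLERGIC" if allergic_seen in group_b else "A_TOLERANT"
            allergic_seen += 1
        subjects.append(_subject_metadata(rng, sid, cohort, severity, pg, config))

        block = config.group_parameter_blocks["CONTROL" if cohort == "CONTROL" else severity]
        # Per-subject latent Pru p 3 curve, shared across markers up to a
        # marker-level jitter; Ara h 9 scales the Emax by peanut group.
        coupling = 0.0 if cohort == "CONTROL" else config.reactivity_sensitivity_coupling
        b0, E0, m0, h0 = _draw_curve(rng, block, coupling)
        lo_a, hi_a = config.arah9_factor_group_a
        lo_b, hi_b = config.arah9_factor_group_b
        f_comparable = float(rng.uniform(lo_b, hi_b))
        f_attenuated = float(rng.uniform(lo_a, hi_a))
        for allergen in config.allergens:
            for marker in config.markers:
                E = E0 * float(rng.uniform(0.9, 1.1))  # marker-level jitter
                m, h = m0, h0
                if allergen == "ARA_H_9" and cohort == "ALLERGIC":
                    if pg == "B_ALLERGIC":
                        E *= f_comparable
                    elif marker == "CD63" or config.attenuate_cd203c:
                        E *= f_attenuated
                    else:
                        E *= f_comparable
                E = min(E, 100.0 - b0)
                latent = latent_logistic(conc, b0, E, m, h)
                background = config.background_pct if config.noise_free else float(
                    _observe(rng, config.background_pct,
                             config.n_events_per_well, False))
                observed = _observe(rng, latent, config.n_events_per_well,
                                    config.noise_free)
                series.append(BATSeries(
                    subject_id=sid, allergen=allergen, marker=marker,
                    background_pct=background, activation_pct=observed,
                ))
    return subjects, series
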