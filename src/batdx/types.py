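"""Domain types shared across the BAT analysis pipeline.

The unit of raw data is a summary-level flow-cytometry readout: the percent
of basophils positive for an activation marker (CD63 or CD203c-high) in one
stimulation well, never event-level FCS data. One :class:`BATSeries` holds
the activation-vs-concentration vector for one subject, one allergen
(Pru p 3 or Ara h 9) and one marker, plus the unstimulated background well.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

# Allergen / marker / group label vocabularies (stored as plain strings in
# the delimited tables, so these are the canonical spellings).
ALLERGENS = ("PRU_P_3", "ARA_H_9")
MARKERS = ("CD63", "CD203c")
COHORTS = ("CONTROL", "ALLERGIC")
SEVERITIES = ("NONE", "OAS", "URT_ANG", "ANAPH")
PEANUT_GROUPS = ("NA", "A_TOLERANT", "B_ALLERGIC")

#: Seven ten-fold allergen concentrations, µg/mL.
DEFAULT_CONCENTRATIONS = (1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)

#: SPT wheal area (mm²) at or above which the prick test is read as positive.
SPT_POSITIVE_AREA_MM2 = 7.0


@dataclass
class GroupBlock:
    """Latent dose-response and serology distributions for one cohort group.

    Emax / baseline are percent activated; ``log10_ec50`` is log10 of the
    half-maximal concentration in µg/mL; Hill slope is dimensionless.
    Serology medians are kU/L (lognormal, ``*_sigma`` on the natural-log
    scale); SPT areas mm².
    """

    emax_mean: float
    emax_sd: float
    emax_lo: float
    emax_hi: float
    log10_ec50_mean: float
    log10_ec50_sd: float
    hill_mean: float = 1.2
    hill_sd: float = 0.3
    baseline_mean: float = 1.0
    baseline_sd: float = 0.3
    age_mean: float = 33.0
    age_sd: float = 10.0
    female_prob: float = 0.68
    tige_median: float = 120.0
    tige_sigma: float = 1.1
    sige_prup3_median: float = 6.0
    sige_prup3_sigma: float = 1.1
    sige_arah9_median: float = 2.6
    sige_arah9_sigma: float = 1.4
    spt_peach_median: float = 52.0
    spt_peach_sigma: float = 0.6
    spt_peanut_median: float = 40.0
    spt_peanut_sigma: float = 0.6


def _default_group_blocks() -> dict:
    # Calibrated to the orders of magnitude of the study population table:
    # allergic sIgE Pru p 3 median ~6 kU/L vs ~0.01 in controls, tIgE medians
    # ~88 (controls) to ~187 (mild), SPT peach medians 36-65 mm² by severity.
    return {
        "CONTROL": GroupBlock(
            emax_mean=1.0, emax_sd=0.5, emax_lo=0.0, emax_hi=3.0,
            log10_ec50_mean=-2.0, log10_ec50_sd=0.5,
            baseline_mean=1.0, baseline_sd=0.3,
            age_mean=34.25, age_sd=13.79, female_prob=0.6875,
            tige_median=88.2, tige_sigma=0.9,
            sige_prup3_median=0.01, sige_prup3_sigma=1.5,
            sige_arah9_median=0.004, sige_arah9_sigma=1.8,
            spt_peach_median=2.0, spt_peach_sigma=0.5,
            spt_peanut_median=2.0, spt_peanut_sigma=0.5,
        ),
        "OAS": GroupBlock(
            emax_mean=45.0, emax_sd=12.0, emax_lo=20.0, emax_hi=85.0,
            log10_ec50_mean=-4.0, log10_ec50_sd=0.6,
            age_mean=32.30, age_sd=9.09, female_prob=0.5652,
            tige_median=186.5, tige_sigma=0.9,
            sige_prup3_median=4.26, sige_prup3_sigma=1.1,
            sige_arah9_median=12.8, sige_arah9_sigma=1.6,
            spt_peach_median=36.0, spt_peach_sigma=0.6,
            spt_peanut_median=25.0, spt_peanut_sigma=0.7,
        ),
        "URT_ANG": GroupBlock(
            emax_mean=50.0, emax_sd=12.0, emax_lo=20.0, emax_hi=85.0,
            log10_ec50_mean=-4.2, log10_ec50_sd=0.6,
            age_mean=34.75, age_sd=11.10, female_prob=0.7273,
            tige_median=115.0, tige_sigma=1.1,
            sige_prup3_median=4.82, sige_prup3_sigma=1.2,
            sige_arah9_median=1.31, sige_arah9_sigma=1.6,
            spt_peach_median=54.0, spt_peach_sigma=0.6,
            spt_peanut_median=30.0, spt_peanut_sigma=0.7,
        ),
        "ANAPH": GroupBlock(
            emax_mean=55.0, emax_sd=12.0, emax_lo=20.0, emax_hi=85.0,
            log10_ec50_mean=-4.4, log10_ec50_sd=0.6,
            age_mean=31.22, age_sd=9.47, female_prob=0.72,
            tige_median=121.5, tige_sigma=1.2,
            sige_prup3_median=8.73, sige_prup3_sigma=1.2,
            sige_arah9_median=0.74, sige_arah9_sigma=1.5,
            spt_peach_median=65.0, spt_peach_sigma=0.6,
            spt_peanut_median=30.0, spt_peanut_sigma=0.7,
        ),
    }


#: Per-severity probability of profilin co-sensitization (profilin-positive
#: fractions decline with severity: 30.44% OAS, 15.91% URT/ANG, 4% ANAPH).
DEFAULT_PROFILIN_PROBS = {"OAS": 0.3044, "URT_ANG": 0.1591, "ANAPH": 0.04}


@dataclass
class SimulationConfig:
    """Cohort-generator configuration; one seed controls all randomness."""

    n_controls: int = 16
    n_oas: int = 23
    n_urt_ang: int = 44
    n_anaph: int = 25
    n_group_b: int = 37
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    n_events_per_well: int = 500
    seed: int = 0
    noise_free: bool = False
    group_parameter_blocks: dict = field(default_factory=_default_group_blocks)
    profilin_probs: dict = field(default_factory=lambda: dict(DEFAULT_PROFILIN_PROBS))
    background_pct: float = 1.0
    #: Ara h 9 Emax multiplier range for peanut-tolerant (Group A) subjects
    #: — strictly attenuated vs their Pru p 3 response.
    arah9_factor_group_a: tuple = (0.25, 0.5)
    #: ... and for peanut-allergic (Group B) subjects — comparable response.
    arah9_factor_group_b: tuple = (0.85, 1.05)
    #: The Pru p 3 vs Ara h 9 attenuation was observed on %CD63+ but not on
    #: %CD203c-high; by default CD203c is left unattenuated in Group A.
    attenuate_cd203c: bool = False
    #: Loading of a shared per-subject factor on Emax and −log10 EC50:
    #: couples reactivity to sensitivity so CD-sens and curve AUC correlate
    #: strongly, as they do in allergic cohorts.
    reactivity_sensitivity_coupling: float = 0.8
    markers: Sequence[str] = MARKERS
    allergens: Sequence[str] = ALLERGENS

    def validate(self) -> None:
        counts = {
            "n_controls": self.n_controls, "n_oas": self.n_oas,
            "n_urt_ang": self.n_urt_ang, "n_anaph": self.n_anaph,
            "n_group_b": self.n_group_b,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v!r}")
        n_allergic = self.n_oas + self.n_urt_ang + self.n_anaph
        if self.n_group_b > n_allergic:
            raise ConfigurationError(
                f"n_group_b ({self.n_group_b}) exceeds the allergic total ({n_allergic})")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or len(conc) == 0:
            raise ConfigurationError("concentrations must be a nonempty 1-D sequence")
        if np.any(conc <= 0):
            raise ConfigurationError("concentrations must all be > 0")
        if np.any(np.diff(conc) <= 0):
            raise ConfigurationError("concentrations must be strictly increasing")
        if not self.noise_free and self.n_events_per_well <= 0:
            raise ConfigurationError("n_events_per_well must be positive")
        for sev, p in self.profilin_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"profilin_probs[{sev!r}] = {p} not in [0, 1]")
        if not (0.0 <= self.background_pct <= 100.0):
            raise ConfigurationError("background_pct must lie in [0, 100]")


@dataclass
class SubjectRecord:
    """Clinical metadata and group labels for one individual."""

    subject_id: str
    cohort: str                 # CONTROL | ALLERGIC
    severity: str               # NONE | OAS | URT_ANG | ANAPH
    peanut_group: str           # NA | A_TOLERANT | B_ALLERGIC
    profilin_sensitized: bool
    age: float                  # years
    sex: str                    # F | M
    total_ige: float            # kU/L
    sige_prup3: float           # kU/L
    sige_arah9: float           # kU/L
    spt_peach_area: float       # mm²
    spt_peanut_area: float      # mm²


@dataclass
class BATSeries:
    """Activation-vs-concentration vector for one subject × allergen × marker."""

    subject_id: str
    allergen: str
    marker: str
    background_pct: float
    activation_pct: np.ndarray

    def __post_init__(self):
        self.activation_pct = np.asarray(self.activation_pct, dtype=float)


@dataclass
class DoseResponseFit:
    """Four-parameter log-logistic fit plus derived per-curve metrics.

    ``cd_sens`` is 100 / EC50 with EC50 in µg/mL (so its magnitude depends on
    that unit convention); it is NaN unless the subject is a responder and
    the fit converged. ``curve_auc`` is the trapezoidal area of
    background-subtracted activation over log10 concentration
    (percent·log10-units) and is defined for every series.
    """

    subject_id: str
    allergen: str
    marker: str
    baseline_hat: float
    emax_hat: float
    log10_ec50_hat: float
    slope_hat: float
    cd_sens: float
    curve_auc: float
    responder: bool
    fit_converged: bool


@dataclass
class CutoffEntry:
    """ROC-derived decision threshold and accuracy metrics for one
    marker × stimulation concentration."""

    marker: str
    concentration: float        # µg/mL
    roc_auc: float              # [0, 1]
    cutoff: float               # percent activated
    sensitivity: float          # %
    specificity: float          # %
    ppv: float                  # %
    npv: float                  # %
    youden_j: float = math.nan  # sens + spec - 100 at the cut-off
    informative: bool = True    # False when J == 0 (complete overlap)


@dataclass
class PositivityCall:
    """Per subject × marker BAT call under the two-consecutive rule."""

    subject_id: str
    marker: str
    positive: bool
    exceeded: tuple             # booleans aligned to the evaluated concentrations
    concentrations: tuple       # the evaluated concentrations, ascending
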