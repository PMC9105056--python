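"""End-to-end orchestration: simulate/read → fit → select concentrations →
ROC cut-offs → positivity calls → cohort statistics → PCA.

Every stage logs what it decided (responder exclusions, selected
concentrations, cut-off source) to stderr, writes its artifact as a CSV in
``out_dir``, and the whole run is deterministic given the configured seed.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, diagnostics, dose_response, synthetic
from .errors import BatDxError
from .io import PipelineConfig, read_bat_long, read_subjects, write_bat_long, write_subjects
from .types import DEFAULT_CONCENTRATIONS

logger = logging.getLogger("batdx")

__all__ = ["run_pipeline", "fits_to_frame", "cutoffs_to_frame", "calls_to_frame"]


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(f) for f in fits])


def cutoffs_to_frame(cutoffs) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in cutoffs])


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"subject_id": c.subject_id, "marker": c.marker,
               "positive": c.positive}
        for conc, ex in zip(c.concentrations, c.exceeded):
            row[f"exceeds_at_{conc:g}"] = ex
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_to_frame(summary) -> pd.DataFrame:
    rows = []
    for label, g in summary.groups.items():
        row = {"group": label, "n": g["n"],
               "percent_female": g["percent_female"]["percent"],
               "age_mean": g["age_mean"], "age_sd": g["age_sd"],
               "percent_profilin": g["percent_profilin"]["percent"]}
        for var in ("spt_peach", "spt_peanut", "total_ige", "sige_prup3", "sige_arah9"):
            st = g[var]
            row[f"{var}_median"] = st["median"]
            row[f"{var}_q1"] = st["q1"]
            row[f"{var}_q3"] = st["q3"]
        rows.append(row)
    df = pd.DataFrame(rows)
    derived = pd.DataFrame(
        [{"group": name, "n": d["denominator"],
          "percent_female": np.nan, "derived_percent": d["percent"],
          "numerator": d["numerator"], "denominator": d["denominator"]}
         for name, d in summary.derived.items()])
    return pd.concat([df, derived], ignore_index=True)


def _comparisons(fits_df, subjects, selected, markers) -> pd.DataFrame:
    """Severity-group and cohort comparisons on reactivity/sensitivity metrics."""
    sev_of = {s.subject_id: s.severity for s in subjects}
    cohort_of = {s.subject_id: s.cohort for s in subjects}
    rows = []

    def record(res):
        entries = res if isinstance(res, list) else [res]
        for r in entries:
            rows.append({
                "variable": r.variable, "groups": "|".join(r.groups),
                "test": r.test, "statistic": r.statistic,
                "p_value": r.p_value, "adjusted_p": r.adjusted_p,
                "direction": r.direction})

    prup3 = fits_df[fits_df.allergen == "PRU_P_3"]
    for marker in markers:
        sub = prup3[prup3.marker == marker]
        auc_by = {"CONTROL": [], "ALLERGIC": []}
        sev_by = {}
        for _, f in sub.iterrows():
            auc_by[cohort_of[f.subject_id]].append(f.curve_auc)
            if cohort_of[f.subject_id] == "ALLERGIC":
                sev_by.setdefault(sev_of[f.subject_id], []).append(f.curve_auc)
        record(cohort_stats.compare_groups(
            auc_by, scale="nonparametric", variable=f"curve_auc_{marker}"))
        if len(sev_by) >= 3:
            record(cohort_stats.compare_groups(
                sev_by, scale="nonparametric", variable=f"curve_auc_{marker}_severity"))
        # CD-sens vs curve AUC association among responders with a defined fit.
        resp = sub[np.isfinite(sub.cd_sens)]
        if len(resp) >= 3:
            r, p = cohort_stats.correlate(np.log10(resp.cd_sens), resp.curve_auc,
                                          method="spearman")
            rows.append({"variable": f"cdsens_vs_auc_{marker}",
                         "groups": "ALLERGIC", "test": "Spearman",
                         "statistic": r, "p_value": p, "adjusted_p": None,
                         "direction": "positive" if r > 0 else "negative"})
    return pd.DataFrame(rows)


def _pca_features(fits_df, subjects, selected_top, series_by_key, concentrations):
    """Feature table mirroring the three-variable analysis: log10 sIgE
    Pru p 3 + %CD63+ and %CD203c-high reactivity at the top concentration."""
    conc = np.asarray(concentrations, dtype=float)
    i_top = int(np.nonzero(np.isclose(conc, selected_top))[0][0])
    rows = {}
    for s in subjects:
        feats = {"log10_sige_prup3": np.log10(s.sige_prup3 + 0.01)}
        for marker in ("CD63", "CD203c"):
            key = (s.subject_id, "PRU_P_3", marker)
            if key in series_by_key:
                feats[f"pct_{marker.lower()}"] = series_by_key[key].activation_pct[i_top]
        if len(feats) == 3:
            rows[s.subject_id] = feats
    return pd.DataFrame.from_dict(rows, orient="index")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns a dict of in-memory artifacts and
    writes each as CSV under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = config.simulation_config()
            subjects, series = synthetic.simulate_cohort(sim_cfg)
            concentrations = np.asarray(sim_cfg.concentrations, dtype=float)
            write_subjects(subjects, out / "subjects.csv")
            write_bat_long(series, concentrations, out / "bat_long.csv")
            logger.info("simulate: %d subjects, %d series", len(subjects), len(series))
        else:
            subjects, _ = read_subjects(config.subjects_path)
            series, concentrations, _ = read_bat_long(config.bat_long_path)
            logger.info("read: %d subjects, %d series", len(subjects), len(series))
        artifacts["subjects"], artifacts["series"] = subjects, series
        artifacts["concentrations"] = concentrations

        stage = "fit"
        fits = [dose_response.fit_curve(
                    s, concentrations, min_peak=config.min_peak,
                    fold_over_background=config.fold_over_background)
                for s in series]
        fits_df = fits_to_frame(fits)
        fits_df.to_csv(out / "fits.csv", index=False)
        n_nonresp = int((~fits_df.responder).sum())
        logger.info("fit: %d curves, %d nonresponder series", len(fits), n_nonresp)
        artifacts["fits"] = fits
        artifacts["fits_df"] = fits_df

        stage = "select"
        selected = dose_response.select_discriminating_concentrations(
            series, subjects, k=config.n_selected,
            concentrations=concentrations, marker="CD63", allergen="PRU_P_3")
        logger.info("select: discriminating concentrations %s µg/mL", selected)
        artifacts["selected_concentrations"] = selected
        evaluated = (list(concentrations) if config.evaluate_all_concentrations
                     else selected)

        stage = "roc"
        if config.cutoff_source == "paper":
            cutoffs = [e for e in diagnostics.PAPER_DEFAULT_CUTOFFS
                       if any(np.isclose(e.concentration, evaluated))]
            logger.info("roc: using bundled reference cut-offs")
        else:
            cutoffs = []
            for marker in config.markers:
                cutoffs.extend(diagnostics.derive_cutoffs(
                    series, subjects, concentrations, evaluated, marker=marker,
                    criterion=config.cutoff_criterion))
            logger.info("roc: derived %d cut-offs", len(cutoffs))
        cutoffs_to_frame(cutoffs).to_csv(out / "cutoffs.csv", index=False)
        artifacts["cutoffs"] = cutoffs

        stage = "classify"
        calls = []
        series_by_key = {(s.subject_id, s.allergen, s.marker): s for s in series}
        for s in series:
            if s.allergen != "PRU_P_3" or s.marker not in config.markers:
                continue
            calls.append(diagnostics.classify_subject(
                s, cutoffs, evaluated, concentrations=concentrations))
        calls_to_frame(calls).to_csv(out / "calls.csv", index=False)
        artifacts["calls"] = calls
        pos_rows = []
        for marker in config.markers:
            mcalls = [c for c in calls if c.marker == marker]
            for grouping in ("cohort", "severity"):
                for grp, (pct, npos, ntot) in diagnostics.positivity_rate(
                        mcalls, subjects, grouping).items():
                    pos_rows.append({"marker": marker, "grouping": grouping,
                                     "group": grp, "percent_positive": pct,
                                     "n_positive": npos, "n_total": ntot})
        positivity_df = pd.DataFrame(pos_rows)
        positivity_df.to_csv(out / "positivity.csv", index=False)
        artifacts["positivity"] = positivity_df

        stage = "cohort_stats"
        summary = cohort_stats.summarize_cohort(subjects)
        _summary_to_frame(summary).to_csv(out / "table1.csv", index=False)
        comparisons = _comparisons(fits_df, subjects, selected, config.markers)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        artifacts["summary"] = summary
        artifacts["comparisons"] = comparisons

        stage = "pca"
        from .dimred import run_pca
        features = _pca_features(fits_df, subjects, selected[-1],
                                 series_by_key, concentrations)
        pca = run_pca(features)
        cohort_of = {s.subject_id: s.cohort for s in subjects}
        scores = pd.DataFrame(
            pca.scores[:, :2], index=pca.index, columns=["PC1", "PC2"])
        scores["group"] = [cohort_of[i] for i in scores.index]
        scores.to_csv(out / "scores.csv", index_label="subject_id")
        pd.DataFrame(pca.loadings, index=pca.feature_names,
                     columns=[f"PC{i+1}" for i in range(pca.loadings.shape[1])]
                     ).to_csv(out / "loadings.csv", index_label="feature")
        logger.info("pca: PC1+PC2 explain %.1f%% of variance",
                    float(pca.explained_variance_pct[:2].sum()))
        artifacts["pca"] = pca
    except Exception as exc:
        if isinstance(exc, BatDxError):
            raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc
        raise BatDxError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return artifacts
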