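"""End-to-end cohort analysis: clips -> TICs -> fits -> tables.

Runs the whole chain on a (synthetic) cohort: extract ROI time-intensity
curves from every cine replicate, fit the replenishment model, gate
unreliable fits, aggregate triplicates into exam-level perfusion records,
and produce the group-comparison outputs: the overall and per-stratum
median/IQR comparison tables, central-vs-peripheral contrasts, cardiac and
Doppler summaries with Spearman correlations, and the crossmatch test on
the pooled (MFV, transit time) cloud with per-group parabola fits.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict

import numpy as np
import pandas as pd

from . import crossmatch as cm
from . import stats as gs
from .cine import detect_flash, extract_tic, rasterize_roi
from .errors import ExcludedFitError
from .fitting import aggregate_replicates, derive_perfusion, fit_reperfusion
from .hemodynamics import compute_pi, derive_cardiac, join_cardiac_perfusion
from .synthetic import CohortConfig, CohortSim, simulate_cardiac_table, simulate_cohort, simulate_doppler

__all__ = ["run_cohort_analysis", "perfusion_records_from_cohort"]

logger = logging.getLogger(__name__)

CARDIAC_VARS = ("cco", "lvco", "rvco", "lv_rv_ratio")


def perfusion_records_from_cohort(sim: CohortSim) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Fit every replicate of every acquisition and aggregate per exam.

    Returns (exam-level table, replicate-level table, number of excluded
    replicate fits).  Exam-regions with no surviving replicate are missing
    rows, not zeros.
    """
    replicate_rows = []
    excluded = 0
    by_exam: dict[tuple, list] = defaultdict(list)
    for acq in sim.acquisitions:
        flash_idx = detect_flash(acq.clip)
        t_f = flash_idx * acq.clip.frame_interval_s
        for roi in acq.rois:
            mask = rasterize_roi(roi, acq.clip)
            tic = extract_tic(
                acq.clip,
                mask,
                roi_label=roi.label,
                replicate=acq.replicate,
                animal_id=acq.animal_id,
                group=acq.group,
                day=acq.day,
            )
            fit = fit_reperfusion(tic, t_f)
            if fit.excluded:
                excluded += 1
                continue
            rec = derive_perfusion(
                fit,
                animal_id=acq.animal_id,
                group=acq.group,
                day_on_circuit=acq.day,
                region=roi.label,
                replicate=acq.replicate,
            )
            replicate_rows.append(rec)
            by_exam[(acq.animal_id, acq.day, roi.label)].append(rec)

    exam_rows = []
    for key, recs in sorted(by_exam.items()):
        agg = aggregate_replicates(recs)
        if agg is not None:
            exam_rows.append(agg)

    def _frame(records):
        return pd.DataFrame(
            {
                "animal_id": [r.animal_id for r in records],
                "group": [r.group for r in records],
                "day": [r.day_on_circuit for r in records],
                "stratum": [r.stratum for r in records],
                "region": [r.region for r in records],
                "mfv": [r.mfv for r in records],
                "transit_time": [r.transit_time for r in records],
                "mbf": [r.mbf for r in records],
                "replicate": [r.replicate for r in records],
                "n_replicates": [r.n_replicates for r in records],
            }
        )

    if excluded:
        logger.info("perfusion_records_from_cohort: %d replicate fits excluded", excluded)
    return _frame(exam_rows), _frame(replicate_rows), excluded


def _doppler_table(config: CohortConfig, exams: pd.DataFrame) -> pd.DataFrame:
    """Per-exam MCA pulsatility indices around the configured group medians."""
    rng = np.random.default_rng(config.seed + 2_000_029)
    tamv = 30.0  # cm/s, time-averaged envelope velocity of the synthetic waveform
    rows = []
    for _, exam in exams.drop_duplicates(subset=["animal_id", "day"]).iterrows():
        pi_med = config.pi_medians[exam["group"]]
        pi_target = pi_med * float(np.exp(rng.standard_normal() * config.dispersion / 2.0))
        delta = pi_target * tamv
        trace = simulate_doppler(
            psv=tamv + delta / 2.0,
            edv=tamv - delta / 2.0,
            heart_rate_hz=2.5,
            n_cycles=5,
            sample_rate_hz=200.0,
        )
        rows.append(
            {
                "animal_id": exam["animal_id"],
                "group": exam["group"],
                "day": exam["day"],
                "psv": trace.psv,
                "edv": trace.edv,
                "tamv": trace.tamv,
                "pi": compute_pi(trace),
            }
        )
    return pd.DataFrame(rows)


def _correlation_table(config: CohortConfig, exams: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of cardiac variables vs perfusion per group/region."""
    raw = simulate_cardiac_table(config)
    cardiac = pd.DataFrame(
        [
            vars(
                derive_cardiac(
                    row.LVCO,
                    row.RVCO,
                    row.circuit_flow,
                    animal_id=row.animal_id,
                    day=row.day,
                    oxygen_delivery=row.oxygen_delivery,
                    group=row.group,
                )
            )
            for row in raw.itertuples()
        ]
    )
    joined = join_cardiac_perfusion(cardiac.drop(columns=["group"]), exams)
    results: list[gs.CorrelationResult] = []
    for group in sorted(joined["group"].unique()):
        for region in sorted(joined["region"].unique()):
            sub = joined[(joined["group"] == group) & (joined["region"] == region)]
            for cvar in CARDIAC_VARS:
                for pvar in gs.PERFUSION_PARAMS:
                    pair = sub[[cvar, pvar]].dropna()
                    if len(pair) < 3:
                        continue
                    results.append(
                        gs.spearman_rho(
                            pair[cvar],
                            pair[pvar],
                            cardiac_variable=cvar,
                            perfusion_variable=pvar,
                            region=region,
                            group=group,
                        )
                    )
    defined = [r for r in results if not r.undefined]
    if defined:
        adj = gs.bh_adjust([r.p_raw for r in defined])
        for r, a in zip(defined, adj):
            r.p_adjusted = float(a)
    return pd.DataFrame([vars(r) for r in results])


def run_cohort_analysis(
    config: CohortConfig | None = None,
    outdir: str | os.PathLike | None = None,
    crossmatch_pool: str = "exams",
) -> dict:
    """Simulate a cohort and run the complete analysis.

    ``crossmatch_pool`` selects whether the crossmatch test uses one
    (MFV, TT) point per exam ("exams") or the per-animal median ("animals").
    Returns a dict of result tables; when ``outdir`` is given each table is
    also written as CSV.
    """
    if config is None:
        config = CohortConfig()
    if crossmatch_pool not in ("exams", "animals"):
        raise ValueError("crossmatch_pool must be 'exams' or 'animals'")

    sim = simulate_cohort(config)
    exams, replicates, n_excluded = perfusion_records_from_cohort(sim)

    table1 = gs.summarize_table1(exams)
    strata_tables = []
    for stratum in gs.STRATA:
        sub = exams[exams["stratum"] == stratum]
        if sub.empty or sub["group"].nunique() < 2:
            continue
        strata_tables.append(gs.summarize_table1(sub, stratum=stratum))
    strata = pd.concat(strata_tables, ignore_index=True) if strata_tables else pd.DataFrame()

    contrasts, contrast_tests = gs.region_contrasts(exams)
    correlations = _correlation_table(config, exams)

    doppler = _doppler_table(config, exams)
    pi_test = gs.mann_whitney_u(
        doppler.loc[doppler["group"] == "hypoxic", "pi"],
        doppler.loc[doppler["group"] == "normoxic", "pi"],
        variable="mca_pi",
    )

    wb = exams[exams["region"] == "whole_brain"]
    if crossmatch_pool == "animals":
        wb = wb.groupby(["animal_id", "group"], as_index=False)[["mfv", "transit_time"]].median()
    points = {
        g: wb.loc[wb["group"] == g, ["mfv", "transit_time"]].to_numpy()
        for g in ("hypoxic", "normoxic")
    }
    xm = cm.crossmatch_test(points["hypoxic"], points["normoxic"])
    parabolas = [
        cm.fit_parabola(
            wb.loc[wb["group"] == g, "mfv"], wb.loc[wb["group"] == g, "transit_time"], group=g
        )
        for g in ("hypoxic", "normoxic")
        if (wb["group"] == g).sum() >= 4
    ]

    results = {
        "truth": sim.truth,
        "perfusion_exams": exams,
        "perfusion_replicates": replicates,
        "n_excluded_fits": n_excluded,
        "table1": table1,
        "table1_strata": strata,
        "region_contrasts": contrasts,
        "region_contrast_tests": contrast_tests,
        "correlations": correlations,
        "doppler_pi": doppler,
        "doppler_pi_test": pd.DataFrame([vars(pi_test) | {"significant": pi_test.significant}]),
        "crossmatch": pd.DataFrame(
            [
                {
                    "n_hypoxic": xm.n0,
                    "n_normoxic": xm.n1,
                    "a1": xm.a1,
                    "null_mean": xm.null_mean,
                    "p_value": xm.p_value,
                    "pool": crossmatch_pool,
                }
            ]
        ),
        "crossmatch_result": xm,
        "parabola_fits": pd.DataFrame([vars(p) for p in parabolas]),
    }

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for name, value in results.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
    return results
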