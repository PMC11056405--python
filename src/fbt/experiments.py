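"""Validation studies on synthetic cohorts.

Each function runs the full pipeline on generated data with known ground
truth and summarises how well the analysis recovers it: effect recovery
and power for an injected cardiac-output bolus response, type-I error on
effect-free cohorts, and covariate balance under confounding by
indication.  They are used by the test suite and by the results-
reproduction script; problem sizes are arguments with the study defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fbt import analyze, pipeline, synth

log = logging.getLogger(__name__)

#: the reference cardiac-output response: +0.2 l/min peaking 40 min after
#: the bolus end, sustained over the observation hour and dissipating over
#: a few hours.
CO_KERNEL = synth.EffectKernel(
    "co", peak_delta=0.2, peak_time=40.0, dissipation_half_life=180.0
)


def _recovery_config(n_patients: int, seed: int) -> pipeline.RunConfig:
    # generate only the channels this experiment touches (the analysed CO
    # plus the matching covariates); all other cohort conditions default
    channels = {
        ch: p for ch, p in synth._default_channels().items()
        if ch in ("co", "sv", "hr", "map", "sbp", "dbp", "cvp")
    }
    return pipeline.RunConfig(
        seed=seed,
        synth=synth.CohortConfig(
            n_patients=n_patients,
            effect_kernels=(CO_KERNEL,),
            channel_params=channels,
        ),
        variables_continuous=("co",),
        variables_sporadic=(),
        responder_variables=(),
        size_rate_outcomes=(),
    )


@dataclass
class RecoveryReplicate:
    seed: int
    p_bolus: float
    peak_estimate: float
    peak_ci_lo: float
    peak_ci_hi: float
    peak_time_min: int
    n_pairs: int


def co_recovery_replicate(seed: int, n_patients: int = 1300) -> RecoveryReplicate:
    """One pipeline run on a cohort carrying the reference CO kernel.

    Returns the mixed-model p-value for the bolus indicator and the peak of
    the matched FBT group's mean change-from-baseline curve (the statistic
    the maximum CO increase is read from), with its 95% CI.
    """
    res = pipeline.run_pipeline(_recovery_config(n_patients, seed))
    matched = res.binned[
        res.binned["episode_id"].isin(
            np.concatenate([res.pairs["bolus_episode_id"].to_numpy(),
                            res.pairs["control_episode_id"].to_numpy()])
        )
    ]
    peak = analyze.peak_group_change(matched, "co", kind="bolus")
    p_bolus = float(res.lmm_results.set_index("variable").loc["co", "p_bolus"])
    return RecoveryReplicate(
        seed=seed,
        p_bolus=p_bolus,
        peak_estimate=peak.estimate,
        peak_ci_lo=peak.ci_lo,
        peak_ci_hi=peak.ci_hi,
        peak_time_min=peak.peak_time_min,
        n_pairs=len(res.pairs),
    )


def co_recovery_study(
    n_replicates: int = 50,
    n_patients: int = 1300,
    seed: int = 0,
    alpha: float | None = None,
    true_peak: float = 0.2,
) -> pd.DataFrame:
    """Replicate the CO-recovery experiment; one row per replicate.

    Adds boolean columns ``significant`` (bolus p-value below the
    Bonferroni threshold) and ``covers`` (the peak estimate's 95% CI
    contains the injected peak).
    """
    if alpha is None:
        alpha = analyze.bonferroni_alpha(31)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for i, s in enumerate(seeds):
        rep = co_recovery_replicate(int(s), n_patients)
        rows.append(dataclasses.asdict(rep))
        log.info("replicate %d/%d: p=%.2g peak=%.3f", i + 1, n_replicates,
                 rep.p_bolus, rep.peak_estimate)
    df = pd.DataFrame(rows)
    df["significant"] = df["p_bolus"] < alpha
    df["covers"] = (df["peak_ci_lo"] <= true_peak) & (true_peak <= df["peak_ci_hi"])
    return df


def type_one_error_study(
    n_variables: int = 200,
    n_patients: int = 40,
    seed: int = 0,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Bolus-indicator p-values on effect-free cohorts.

    Cohorts are generated without any response kernel and without
    confounding by indication, so every rejection is a false positive.
    Each cohort contributes one p-value per continuous variable; cohorts
    are added until ``n_variables`` p-values are collected.
    """
    if alpha is None:
        alpha = analyze.bonferroni_alpha(31)
    variables = pipeline.CONTINUOUS_VARIABLES
    rows: list[dict] = []
    ss = np.random.SeedSequence(seed)
    k = 0
    while len(rows) < n_variables:
        s = int(ss.generate_state(k + 1)[k] % (2**31))
        k += 1
        cfg = pipeline.RunConfig(
            seed=s,
            synth=synth.CohortConfig(
                n_patients=n_patients,
                effect_kernels=(),
                confounding_strength=0.0,
            ),
            variables_continuous=variables,
            variables_sporadic=(),
            responder_variables=(),
            size_rate_outcomes=(),
        )
        try:
            res = pipeline.run_pipeline(cfg)
        except pipeline.PipelineError as exc:
            log.warning("null cohort skipped: %s", exc)
            continue
        for _, r in res.lmm_results.iterrows():
            if np.isfinite(r["p_bolus"]) and len(rows) < n_variables:
                rows.append(
                    {"cohort_seed": s, "variable": r["variable"],
                     "p_bolus": float(r["p_bolus"])}
                )
    df = pd.DataFrame(rows)
    df["rejected"] = df["p_bolus"] < alpha
    return df


def confounded_balance_run(
    n_patients: int = 500, seed: int = 0
) -> tuple[pipeline.PipelineResult, pd.DataFrame]:
    """Full default pipeline on a confounded cohort; returns the run and its
    balance table (standardised differences before/after matching)."""
    cfg = pipeline.RunConfig(
        seed=seed,
        synth=synth.CohortConfig(n_patients=n_patients),
        variables_sporadic=(),
        responder_variables=(),
        size_rate_outcomes=(),
        variables_continuous=("co", "map"),
    )
    res = pipeline.run_pipeline(cfg)
    return res, res.balance.table


def reported_responder_tables(n_per_group: int = 3572) -> pd.DataFrame:
    """Chi-squared tests on 2x2 responder tables reconstructed from the
    study's printed responder percentages at the reported group size."""
    printed = {
        "co": (60.6, 49.1),
        "sv": (62.3, 50.5),
        "map": (51.7, 53.4),
        "vis_increase": (8.9, 5.1),
    }
    rows = []
    for var, (pct_b, pct_c) in printed.items():
        r_b = round(pct_b / 100 * n_per_group)
        r_c = round(pct_c / 100 * n_per_group)
        chi2, p = analyze.responder_chi2(
            [[r_b, n_per_group - r_b], [r_c, n_per_group - r_c]]
        )
        rows.append(
            {"variable": var, "pct_bolus": pct_b, "pct_control": pct_c,
             "n_per_group": n_per_group, "chi2": chi2, "p": p}
        )
    return pd.DataFrame(rows)
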