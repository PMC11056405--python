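"""Episode baselines, propensity scores, 1:1 matching, balance diagnostics.

Baselines are means over the 30 min preceding the episode start.  The
propensity model is a logistic regression of episode kind (bolus vs
control) on the baseline covariate vector; matching is greedy nearest
neighbour on the logit of the propensity score, without replacement,
within a caliper expressed as a multiple of the SD of the logit score.
Balance is reported as the standardised difference

    SDiff(x) = 100 * |mean_b - mean_c| / sqrt((var_b + var_c) / 2)

with the proportion analogue ``p(1-p)`` variances for binary covariates;
SDiff below 10% is the conventional adequacy gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from fbt._util import group_observations, interval_means

log = logging.getLogger(__name__)

MIN = pd.Timedelta(minutes=1)

#: baseline hemodynamic channels averaged over the 30-min pre-window.
#: SV is carried for the bolus-size regressions but is not a default
#: matching covariate.
BASELINE_CHANNELS = ("map", "sbp", "dbp", "hr", "co", "sv", "cvp", "vis")
MATCHING_CHANNELS = ("map", "sbp", "dbp", "hr", "co", "cvp", "vis")

#: patient-level covariates copied onto every episode.
PATIENT_COVARIATES = (
    "age_years", "sex", "height_cm", "weight_kg", "apache2",
    "admission_type", "surgery_type", "mechanical_ventilation",
)

CATEGORICAL = ("sex", "admission_type", "surgery_type", "mechanical_ventilation")

DEFAULT_COVARIATES = tuple(
    f"bl_{c}" for c in MATCHING_CHANNELS
) + ("time_since_admission_h",) + PATIENT_COVARIATES


def compute_baselines(
    episodes: pd.DataFrame,
    observations: pd.DataFrame,
    patients: pd.DataFrame,
    baseline_min: float = 30.0,
    min_samples: int = 3,
    channels: tuple[str, ...] = BASELINE_CHANNELS,
) -> pd.DataFrame:
    """Per-episode baseline covariate vector.

    Baseline means use only observations in ``[start - baseline_min, start)``.
    Episodes with fewer than ``min_samples`` observations for any required
    channel are dropped with a logged reason.
    """
    by_pc = group_observations(observations, channels)

    out = episodes[["episode_id", "patient_id", "kind", "start_ts"]].reset_index(drop=True)
    lo_all = (out["start_ts"] - baseline_min * MIN).to_numpy()
    hi_all = out["start_ts"].to_numpy()
    patient_idx = out.groupby("patient_id", sort=False).indices
    for ch in channels:
        means = np.full(len(out), np.nan)
        counts = np.zeros(len(out), dtype=int)
        for pid, idx in patient_idx.items():
            ts_cum = by_pc.get((pid, ch))
            if ts_cum is None:
                continue
            ts, cum = ts_cum
            means[idx], counts[idx] = interval_means(ts, cum, lo_all[idx], hi_all[idx])
        out[f"bl_{ch}"] = means
        out[f"bl_{ch}_n"] = counts

    ok = np.all(
        np.column_stack([out[f"bl_{ch}_n"].to_numpy() >= min_samples for ch in channels]),
        axis=1,
    )
    if (~ok).any():
        log.info("dropped %d episodes with < %d baseline samples",
                 int((~ok).sum()), min_samples)
    out = out.loc[ok].reset_index(drop=True)
    pat = patients.set_index("patient_id")
    out = out.join(pat[list(PATIENT_COVARIATES) + ["admit_ts"]], on="patient_id")
    out["time_since_admission_h"] = (
        (out["start_ts"] - out["admit_ts"]) / MIN / 60.0
    ).astype(float)
    return out.drop(columns=["start_ts", "admit_ts"])


def _design(baselines: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cats = [c for c in covariates if c in CATEGORICAL]
    cont = [c for c in covariates if c not in CATEGORICAL]
    X = baselines[cont].astype(float)
    if cats:
        dummies = pd.get_dummies(baselines[cats].astype(str), drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def estimate_propensity(
    baselines: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Logistic bolus-vs-control model; returns baselines plus ``ps`` column.

    Complete-case: episodes with missing covariates are dropped (logged).
    Perfect separation raises with advice to review the covariate list.
    """
    df = baselines.dropna(subset=[c for c in covariates]).reset_index(drop=True)
    if len(df) < len(baselines):
        log.info("propensity model: dropped %d incomplete episodes",
                 len(baselines) - len(df))
    y = (df["kind"] == "bolus").to_numpy(dtype=float)
    X = sm.add_constant(_design(df, covariates))
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and kin
        raise ValueError(
            "propensity model failed (possible perfect separation); "
            "review the covariate list"
        ) from exc
    if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 1e3:
        raise ValueError(
            "propensity model shows (near-)perfect separation; review the covariate list"
        )
    out = df.copy()
    out["ps"] = np.clip(fit.predict(X), 1e-12, 1 - 1e-12)
    return out


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # bolus_episode_id, control_episode_id, ps_*, logit_distance
    caliper: float
    n_bolus: int
    n_control: int


def match_pairs(
    scored: pd.DataFrame,
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on logit(PS) without replacement.

    Bolus episodes are processed in a seeded random order; candidate
    controls must lie within ``caliper_sd * SD(logit PS)``; exact distance
    ties break toward the lower control ``episode_id``.  Unmatched episodes
    are discarded.
    """
    logit = np.log(scored["ps"] / (1 - scored["ps"]))
    scored = scored.assign(logit_ps=logit)
    caliper = caliper_sd * float(logit.std(ddof=1))
    bolus = scored[scored["kind"] == "bolus"]
    control = scored[scored["kind"] == "control"]
    if len(bolus) == 0 or len(control) == 0:
        raise ValueError(
            f"cannot match: {len(bolus)} bolus and {len(control)} control episodes"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bolus))

    c_sorted = control.sort_values(["logit_ps", "episode_id"]).reset_index(drop=True)
    c_logit = c_sorted["logit_ps"].to_numpy()
    c_id = c_sorted["episode_id"].to_numpy()
    c_ps = c_sorted["ps"].to_numpy()
    used = np.zeros(len(c_sorted), dtype=bool)

    rows = []
    for bi in order:
        b = bolus.iloc[bi]
        x = b["logit_ps"]
        k = np.searchsorted(c_logit, x)
        best = -1
        best_d = np.inf
        # scan outward from the insertion point; the candidate distance d is
        # non-decreasing, so we can stop at the caliper or past a found match
        left, right = k - 1, k
        while left >= 0 or right < len(c_sorted):
            l_d = abs(x - c_logit[left]) if left >= 0 else np.inf
            r_d = abs(c_logit[right] - x) if right < len(c_sorted) else np.inf
            if l_d <= r_d:
                idx, d = left, l_d
                left -= 1
            else:
                idx, d = right, r_d
                right += 1
            if d > caliper or (best >= 0 and d > best_d):
                break
            if used[idx]:
                continue
            if best < 0 or d < best_d or (d == best_d and c_id[idx] < c_id[best]):
                best, best_d = idx, d
        if best >= 0:
            used[best] = True
            rows.append(
                {
                    "bolus_episode_id": int(b["episode_id"]),
                    "control_episode_id": int(c_id[best]),
                    "ps_bolus": float(b["ps"]),
                    "ps_control": float(c_ps[best]),
                    "logit_distance": float(best_d),
                }
            )
    if not rows:
        raise ValueError(
            "zero matches within caliper "
            f"{caliper:.4f} (logit-PS ranges: bolus "
            f"[{bolus['logit_ps'].min():.2f}, {bolus['logit_ps'].max():.2f}], control "
            f"[{control['logit_ps'].min():.2f}, {control['logit_ps'].max():.2f}])"
        )
    pairs = pd.DataFrame(rows).sort_values("bolus_episode_id").reset_index(drop=True)
    return MatchResult(pairs=pairs, caliper=caliper,
                       n_bolus=len(bolus), n_control=len(control))


def _sdiff(x_b: np.ndarray, x_c: np.ndarray, binary: bool) -> float:
    m_b, m_c = np.mean(x_b), np.mean(x_c)
    if binary:
        v_b, v_c = m_b * (1 - m_b), m_c * (1 - m_c)
    else:
        v_b = np.var(x_b, ddof=1) if len(x_b) > 1 else 0.0
        v_c = np.var(x_c, ddof=1) if len(x_c) > 1 else 0.0
    pooled = np.sqrt((v_b + v_c) / 2.0)
    if pooled == 0:
        return 0.0 if m_b == m_c else np.inf
    return 100.0 * abs(m_b - m_c) / pooled


@dataclass
class BalanceReport:
    table: pd.DataFrame  # covariate, binary, sdiff_pre, sdiff_post
    n_matched: int

    @property
    def all_pass(self) -> bool:
        return bool((self.table["sdiff_post"] < 10.0).all())


def balance(
    baselines: pd.DataFrame,
    pairs: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> BalanceReport:
    """Standardised differences before (all episodes) and after matching."""
    if len(pairs) == 0:
        raise ValueError("pairs must be non-empty")
    X = _design(baselines, covariates)
    binary = {c: set(np.unique(X[c].dropna())) <= {0.0, 1.0} for c in X.columns}
    is_b = (baselines["kind"] == "bolus").to_numpy()
    eid = baselines["episode_id"].to_numpy()
    in_b_post = np.isin(eid, pairs["bolus_episode_id"])
    in_c_post = np.isin(eid, pairs["control_episode_id"])
    rows = []
    for c in X.columns:
        x = X[c].to_numpy(dtype=float)
        rows.append(
            {
                "covariate": c,
                "binary": binary[c],
                "sdiff_pre": _sdiff(x[is_b], x[~is_b], binary[c]),
                "sdiff_post": _sdiff(x[in_b_post], x[in_c_post], binary[c]),
            }
        )
    return BalanceReport(table=pd.DataFrame(rows), n_matched=len(pairs))
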