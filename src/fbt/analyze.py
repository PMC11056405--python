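"""Trajectory binning, mixed-effects modelling, responder classification,
bolus size/rate regressions, and multiplicity control.

For every episode and variable, the 30-min pre-start baseline mean and
twelve 5-min bin means over the 60 min after the episode end are computed
(bin ``k`` covers ``[(k-5), k)`` minutes post-end, labelled 5, 10, ..., 60).
Bins with no observations stay missing; nothing is imputed.

The repeated-measures model for a matched set is a linear mixed model

    value ~ bolus + time_c + bolus:time_c + baseline + (1 | patient)

fit by REML with the time covariate (minutes after episode end) centred,
so the bolus coefficient is the adjusted group difference at mid-window.
Fixed-effect p-values are Wald (normal) approximations.

A responder shows a >10% increase of the variable over its baseline; by
default the maximum of the twelve bin means is the post statistic.  The
responder proportions of the two groups are compared with Pearson's
chi-squared test without continuity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fbt._util import group_observations, interval_means

log = logging.getLogger(__name__)

MIN = pd.Timedelta(minutes=1)

BIN_LABELS = tuple(range(5, 65, 5))


def bonferroni_alpha(m: int = 31, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling the family-wise rate."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return family_alpha / m


# ---------------------------------------------------------------------------
# binning


def bin_trajectories(
    observations: pd.DataFrame,
    episodes: pd.DataFrame,
    variables: tuple[str, ...],
    bin_width_min: float = 5.0,
    n_bins: int = 12,
    baseline_min: float = 30.0,
) -> pd.DataFrame:
    """Per-episode, per-variable baseline and post-window bin means.

    Returns one row per (episode, variable) with columns ``baseline``,
    ``baseline_n``, ``bin_<k>`` and ``n_<k>`` for each bin label ``k``.
    Episodes with no baseline observation for a variable are omitted for
    that variable (logged in aggregate).
    """
    labels = [int((i + 1) * bin_width_min) for i in range(n_bins)]
    by_pc = group_observations(observations, variables)

    base = episodes[["episode_id", "patient_id", "kind"]].reset_index(drop=True)
    start_all = episodes["start_ts"].to_numpy()
    bl_lo_all = (episodes["start_ts"] - baseline_min * MIN).to_numpy()
    end_all = episodes["end_ts"].to_numpy()
    offsets = np.array(
        [np.timedelta64(int(k * bin_width_min * 60), "s") for k in range(n_bins + 1)]
    )
    patient_idx = base.groupby("patient_id", sort=False).indices

    cols = ["episode_id", "patient_id", "kind", "variable", "baseline", "baseline_n"]
    for lab in labels:
        cols += [f"bin_{lab}", f"n_{lab}"]
    parts = []
    n_omitted = 0
    for var in variables:
        bl_mean = np.full(len(base), np.nan)
        bl_n = np.zeros(len(base), dtype=int)
        bins = np.full((len(base), n_bins), np.nan)
        bin_n = np.zeros((len(base), n_bins), dtype=int)
        for pid, idx in patient_idx.items():
            ts_cum = by_pc.get((pid, var))
            if ts_cum is None:
                continue
            ts, cum = ts_cum
            bl_mean[idx], bl_n[idx] = interval_means(
                ts, cum, bl_lo_all[idx], start_all[idx]
            )
            edges = end_all[idx][:, None] + offsets[None, :]
            for b in range(n_bins):
                bins[idx, b], bin_n[idx, b] = interval_means(
                    ts, cum, edges[:, b], edges[:, b + 1]
                )
        part = base.copy()
        part["variable"] = var
        part["baseline"] = bl_mean
        part["baseline_n"] = bl_n
        for b, lab in enumerate(labels):
            part[f"bin_{lab}"] = bins[:, b]
            part[f"n_{lab}"] = bin_n[:, b]
        has_bl = bl_n > 0
        n_omitted += int((~has_bl).sum())
        parts.append(part.loc[has_bl])
    if n_omitted:
        log.info("omitted %d (episode, variable) trajectories without baseline data",
                 n_omitted)
    if not parts:
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)[cols]


def bin_labels(binned: pd.DataFrame) -> list[int]:
    return sorted(int(c[4:]) for c in binned.columns if c.startswith("bin_"))


def to_long(binned: pd.DataFrame) -> pd.DataFrame:
    """Melt a binned table to rows (episode, variable, time_min, value)."""
    labels = bin_labels(binned)
    keep = ["episode_id", "patient_id", "kind", "variable", "baseline"]
    long = binned.melt(
        id_vars=keep,
        value_vars=[f"bin_{k}" for k in labels],
        var_name="bin",
        value_name="value",
    )
    long["time_min"] = long["bin"].str[4:].astype(float)
    return long.drop(columns="bin").dropna(subset=["value"]).reset_index(drop=True)


def changes_from_baseline(binned: pd.DataFrame) -> pd.DataFrame:
    """Bin-minus-baseline changes, one column per bin label."""
    labels = bin_labels(binned)
    out = binned[["episode_id", "patient_id", "kind", "variable", "baseline"]].copy()
    for k in labels:
        out[f"d_{k}"] = binned[f"bin_{k}"] - binned["baseline"]
    return out


# ---------------------------------------------------------------------------
# mixed-effects model


@dataclass
class LMMResult:
    variable: str
    coef: dict = field(default_factory=dict)  # term -> (estimate, lo, hi)
    p_bolus: float = np.nan
    p_interaction: float = np.nan
    n_episodes: int = 0
    n_patients: int = 0
    fallback_ols: bool = False
    pvalue_method: str = "wald-normal"

    def to_row(self) -> dict:
        row = {
            "variable": self.variable,
            "p_bolus": self.p_bolus,
            "p_interaction": self.p_interaction,
            "n_episodes": self.n_episodes,
            "n_patients": self.n_patients,
            "fallback_ols": self.fallback_ols,
        }
        for term, (est, lo, hi) in self.coef.items():
            row[f"coef_{term}"] = est
            row[f"ci_lo_{term}"] = lo
            row[f"ci_hi_{term}"] = hi
        return row


def fit_lmm(
    binned: pd.DataFrame,
    variable: str,
    include_time: bool = True,
    alpha: float = 0.05,
) -> LMMResult:
    """Mixed model of one variable's post-window values for a matched set.

    ``binned`` must contain only the episodes to analyse (e.g. the matched
    ones).  Requires both groups and at least two patients.  A failed or
    singular random-intercept fit falls back to OLS and is flagged.
    """
    import statsmodels.formula.api as smf

    df = to_long(binned[binned["variable"] == variable]).dropna(subset=["baseline"])
    if df.empty or df["kind"].nunique() < 2:
        raise ValueError(f"{variable}: need both bolus and control episodes")
    if df["patient_id"].nunique() < 2:
        raise ValueError(f"{variable}: need at least two patients")
    df = df.assign(
        bolus=(df["kind"] == "bolus").astype(float),
        time_c=df["time_min"] - df["time_min"].mean(),
    )
    formula = "value ~ bolus + time_c + bolus:time_c + baseline" if include_time \
        else "value ~ bolus + baseline"
    result = LMMResult(
        variable=variable,
        n_episodes=df["episode_id"].nunique(),
        n_patients=df["patient_id"].nunique(),
    )
    fit = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # random intercepts for patient and for episode within patient:
            # bins of one episode are repeated measurements, episodes of one
            # patient share the patient's physiology
            model = smf.mixedlm(
                formula, df, groups=df["patient_id"],
                vc_formula={"episode": "0 + C(episode_id)"},
            )
            fit = model.fit(reml=True)
        drop = [t for t in fit.bse.index if "Var" in t]
        if not np.all(np.isfinite(fit.bse.drop(labels=drop, errors="ignore"))):
            fit = None
    except Exception:
        fit = None
    if fit is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(formula, df).fit()
        result.fallback_ols = True
    ci = fit.conf_int(alpha)
    for term in [t for t in fit.params.index if "Var" not in t]:
        result.coef[term] = (
            float(fit.params[term]), float(ci.loc[term, 0]), float(ci.loc[term, 1])
        )
    result.p_bolus = float(fit.pvalues.get("bolus", np.nan))
    if include_time:
        result.p_interaction = float(fit.pvalues.get("bolus:time_c", np.nan))
    return result


# ---------------------------------------------------------------------------
# responders


@dataclass
class ResponderTable:
    variable: str
    n_bolus: int
    n_control: int
    responders_bolus: int
    responders_control: int
    chi2: float
    p: float

    def to_row(self) -> dict:
        return {
            "variable": self.variable,
            "n_bolus": self.n_bolus,
            "n_control": self.n_control,
            "responders_bolus": self.responders_bolus,
            "responders_control": self.responders_control,
            "frac_bolus": self.responders_bolus / self.n_bolus,
            "frac_control": self.responders_control / self.n_control,
            "chi2": self.chi2,
            "p": self.p,
        }


def responder_chi2(table_2x2: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2x2 count table.

    A degenerate table (all or no responders in both groups) carries no
    evidence of a group difference: chi2 = 0, p = 1.
    """
    t = np.asarray(table_2x2, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def _responder_flags(
    binned: pd.DataFrame, threshold: float, rule: str
) -> pd.Series:
    labels = bin_labels(binned)
    bins = binned[[f"bin_{k}" for k in labels]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if rule in ("max_bin", "any_bin"):
            post = np.nanmax(bins, axis=1)
        elif rule == "mean_window":
            post = np.nanmean(bins, axis=1)
        else:
            raise ValueError(f"unknown responder rule {rule!r}")
    baseline = binned["baseline"].to_numpy(dtype=float)
    flags = np.full(len(binned), np.nan)
    valid = np.isfinite(post)
    pos = valid & (baseline > 0)
    flags[pos] = (post[pos] - baseline[pos]) / baseline[pos] > threshold
    # zero baseline (e.g. VIS off): any positive post value is an increase
    zero = valid & (baseline == 0)
    flags[zero] = post[zero] > 0
    n_neg = int((valid & (baseline < 0)).sum())
    if n_neg:
        log.info("responder rule: excluded %d episodes with negative baseline", n_neg)
    return pd.Series(flags, index=binned.index)


def classify_responders(
    binned: pd.DataFrame,
    variable: str,
    threshold: float = 0.10,
    rule: str = "max_bin",
) -> ResponderTable:
    """Responder fractions (> ``threshold`` relative increase) by group."""
    sub = binned[binned["variable"] == variable]
    flags = _responder_flags(sub, threshold, rule).dropna()
    sub = sub.loc[flags.index]
    is_b = sub["kind"] == "bolus"
    n_b, n_c = int(is_b.sum()), int((~is_b).sum())
    if n_b == 0 or n_c == 0:
        raise ValueError(f"{variable}: empty group in responder table")
    r_b = int(flags[is_b].sum())
    r_c = int(flags[~is_b].sum())
    chi2, p = responder_chi2([[r_b, n_b - r_b], [r_c, n_c - r_c]])
    return ResponderTable(variable, n_b, n_c, r_b, r_c, chi2, p)


# ---------------------------------------------------------------------------
# bolus size / rate regressions


@dataclass
class SizeRateModel:
    outcome: str
    table: pd.DataFrame  # term, coef, ci_lo, ci_hi, p
    n: int

    def coef(self, term: str) -> tuple[float, float, float]:
        row = self.table.set_index("term").loc[term]
        return float(row["coef"]), float(row["ci_lo"]), float(row["ci_hi"])


SIZE_RATE_BASELINES = ("hr", "map", "sbp", "dbp", "cvp", "vis")


def fit_size_rate_models(
    binned: pd.DataFrame,
    baselines: pd.DataFrame,
    episodes: pd.DataFrame,
    outcomes: tuple[str, ...] = ("map", "co", "sv"),
) -> list[SizeRateModel]:
    """Linear models of the mean post-bolus change on bolus size and rate.

    Outcome: mean change from baseline over the 60-min window, bolus
    episodes only.  Predictors: bolus volume per 100 ml, mean infusion rate
    (ml/min), baseline HR/MAP/SBP/DBP/CVP/VIS, the VIS change from baseline,
    age, sex and height, plus baseline CO and SV for those outcomes.
    Complete-case; a rank-deficient design raises naming the collinear
    columns.
    """
    import statsmodels.api as sm

    ep = episodes[episodes["kind"] == "bolus"].set_index("episode_id")
    bl = baselines.set_index("episode_id")
    ch = changes_from_baseline(binned[binned["kind"] == "bolus"])
    labels = bin_labels(binned)
    ch["mean_change"] = ch[[f"d_{k}" for k in labels]].mean(axis=1)
    mean_change = ch.pivot_table(index="episode_id", columns="variable",
                                 values="mean_change")

    out = []
    for outcome in outcomes:
        extra = [v for v in ("co", "sv") if outcome in ("co", "sv")]
        need_bl = list(dict.fromkeys(SIZE_RATE_BASELINES + tuple(extra)))
        df = pd.DataFrame(
            {
                "y": mean_change.get(outcome),
                "size_100ml": ep["volume_ml"] / 100.0,
                "rate_ml_min": ep["mean_rate_ml_h"] / 60.0,
                "delta_vis": mean_change.get("vis"),
            }
        )
        for c in need_bl:
            df[f"bl_{c}"] = bl[f"bl_{c}"]
        df["age_years"] = bl["age_years"]
        df["sex_m"] = (bl["sex"] == "M").astype(float)
        df["height_cm"] = bl["height_cm"]
        df = df.dropna()
        y = df.pop("y")
        X = sm.add_constant(df.astype(float))
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            corr = X.drop(columns="const").corr().abs()
            np.fill_diagonal(corr.values, 0)
            worst = corr.stack().idxmax()
            raise ValueError(
                f"{outcome}: rank-deficient design (rank {rank} < {X.shape[1]}); "
                f"most collinear columns: {worst}"
            )
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int()
        table = pd.DataFrame(
            {
                "term": fit.params.index,
                "coef": fit.params.to_numpy(),
                "ci_lo": ci[0].to_numpy(),
                "ci_hi": ci[1].to_numpy(),
                "p": fit.pvalues.to_numpy(),
            }
        )
        out.append(SizeRateModel(outcome=outcome, table=table, n=int(fit.nobs)))
    return out


# ---------------------------------------------------------------------------
# matched-pair effect curves and reporting


@dataclass
class PeakEffect:
    variable: str
    estimate: float
    ci_lo: float
    ci_hi: float
    peak_time_min: int
    n_pairs: int


def paired_effect_curve(
    binned: pd.DataFrame, pairs: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Mean matched-pair difference in change-from-baseline per bin.

    For each pair the change from baseline of the control episode is
    subtracted from that of its matched bolus episode, bin by bin; the
    mean and 95% t-interval across pairs are returned per bin.
    """
    ch = changes_from_baseline(binned[binned["variable"] == variable])
    labels = bin_labels(binned)
    d_cols = [f"d_{k}" for k in labels]
    b = ch.set_index("episode_id").reindex(pairs["bolus_episode_id"])[d_cols]
    c = ch.set_index("episode_id").reindex(pairs["control_episode_id"])[d_cols]
    diff = b.to_numpy(dtype=float) - c.to_numpy(dtype=float)
    rows = []
    for j, k in enumerate(labels):
        col = diff[:, j]
        col = col[np.isfinite(col)]
        n = col.size
        m = float(col.mean()) if n else np.nan
        if n > 1:
            half = float(stats.t.ppf(0.975, n - 1) * col.std(ddof=1) / np.sqrt(n))
        else:
            half = np.nan
        rows.append(
            {"time_min": k, "mean_diff": m, "ci_lo": m - half, "ci_hi": m + half, "n": n}
        )
    return pd.DataFrame(rows)


def group_change_curve(
    binned: pd.DataFrame, variable: str, kind: str = "bolus"
) -> pd.DataFrame:
    """Mean change from baseline per bin within one episode group.

    This is the per-group trajectory summary (mean and 95% t-interval of
    the within-episode changes at each time point) from which the "maximum
    increase above baseline" of a group is read off.
    """
    sub = binned[(binned["variable"] == variable) & (binned["kind"] == kind)]
    ch = changes_from_baseline(sub)
    rows = []
    for k in bin_labels(binned):
        col = ch[f"d_{k}"].dropna().to_numpy(dtype=float)
        n = col.size
        m = float(col.mean()) if n else np.nan
        if n > 1:
            half = float(stats.t.ppf(0.975, n - 1) * col.std(ddof=1) / np.sqrt(n))
        else:
            half = np.nan
        rows.append(
            {"time_min": k, "mean_change": m, "ci_lo": m - half, "ci_hi": m + half, "n": n}
        )
    return pd.DataFrame(rows)


def peak_group_change(
    binned: pd.DataFrame, variable: str, kind: str = "bolus"
) -> PeakEffect:
    """Maximum of a group's mean change-from-baseline curve, with its CI."""
    curve = group_change_curve(binned, variable, kind)
    i = int(curve["mean_change"].idxmax())
    row = curve.loc[i]
    return PeakEffect(
        variable=variable,
        estimate=float(row["mean_change"]),
        ci_lo=float(row["ci_lo"]),
        ci_hi=float(row["ci_hi"]),
        peak_time_min=int(row["time_min"]),
        n_pairs=int(row["n"]),
    )


def peak_effect(binned: pd.DataFrame, pairs: pd.DataFrame, variable: str) -> PeakEffect:
    """Largest per-bin mean matched-pair difference with its 95% CI."""
    curve = paired_effect_curve(binned, pairs, variable)
    i = int(curve["mean_diff"].idxmax())
    row = curve.loc[i]
    return PeakEffect(
        variable=variable,
        estimate=float(row["mean_diff"]),
        ci_lo=float(row["ci_lo"]),
        ci_hi=float(row["ci_hi"]),
        peak_time_min=int(row["time_min"]),
        n_pairs=int(row["n"]),
    )


def bin_summary(binned: pd.DataFrame) -> pd.DataFrame:
    """Group mean (95% CI) of baseline and every bin, per variable: the wide
    per-5-min report layout."""
    labels = bin_labels(binned)
    rows = []
    for (var, kind), grp in binned.groupby(["variable", "kind"]):
        row = {"variable": var, "kind": kind, "n_episodes": len(grp)}
        for name, col in [("baseline", grp["baseline"])] + [
            (str(k), grp[f"bin_{k}"]) for k in labels
        ]:
            x = col.dropna().to_numpy(dtype=float)
            if x.size > 1:
                m = x.mean()
                half = stats.t.ppf(0.975, x.size - 1) * x.std(ddof=1) / np.sqrt(x.size)
                row[name] = f"{m:.2f} ({m - half:.2f}-{m + half:.2f})"
            elif x.size == 1:
                row[name] = f"{x[0]:.2f}"
            else:
                row[name] = ""
        rows.append(row)
    return pd.DataFrame(rows)


def plot_trajectories(
    binned: pd.DataFrame,
    pairs: pd.DataFrame,
    variables: tuple[str, ...],
    path=None,
):
    """Per-variable two-panel figure: group bin means and mean change from
    baseline, with 95% CIs.  Returns the matplotlib figure; saves to
    ``path`` (PNG/SVG by extension) when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matched_ids = np.concatenate(
        [pairs["bolus_episode_id"].to_numpy(), pairs["control_episode_id"].to_numpy()]
    )
    sub_all = binned[binned["episode_id"].isin(matched_ids)]
    labels = bin_labels(binned)
    fig, axes = plt.subplots(
        2, len(variables), figsize=(4 * len(variables), 6), squeeze=False
    )
    for j, var in enumerate(variables):
        sub = sub_all[sub_all["variable"] == var]
        for kind, color in (("bolus", "tab:red"), ("control", "tab:blue")):
            g = sub[sub["kind"] == kind]
            means = [g[f"bin_{k}"].mean() for k in labels]
            axes[0][j].plot(labels, means, marker="o", ms=3, color=color, label=kind)
            chg = changes_from_baseline(g)
            dmeans = [chg[f"d_{k}"].mean() for k in labels]
            axes[1][j].plot(labels, dmeans, marker="o", ms=3, color=color, label=kind)
        axes[0][j].set_title(var)
        axes[1][j].axhline(0.0, color="grey", lw=0.5)
        axes[1][j].set_xlabel("min after episode end")
    axes[0][0].set_ylabel("bin mean")
    axes[1][0].set_ylabel("mean change from baseline")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
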