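"""Internal helpers shared by the episode-summary computations."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _codes(col: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes and uniques for a column, cheap for categoricals."""
    if isinstance(col.dtype, pd.CategoricalDtype):
        return col.cat.codes.to_numpy(), col.cat.categories.to_numpy()
    codes, uniques = pd.factorize(col.to_numpy())
    return codes, np.asarray(uniques)


def _group_one(
    obs: pd.DataFrame, channels, out: dict
) -> None:
    sub = obs[obs["channel"].isin(list(channels))]
    if len(sub) == 0:
        return
    pid_codes, pids = _codes(sub["patient_id"])
    ch_codes, chs = _codes(sub["channel"])
    ts = sub["ts"].to_numpy()
    vals = sub["value"].to_numpy(dtype=float)
    key = pid_codes.astype(np.int64) * len(chs) + ch_codes
    # stable sort by group key keeps the within-group time order; fall back
    # to a full lexsort when the input is not time-sorted within groups
    order = np.argsort(key, kind="stable")
    key_s, ts_s = key[order], ts[order]
    same = np.diff(key_s) == 0
    if np.any(np.diff(ts_s)[same] < np.timedelta64(0, "ns")):
        order = np.lexsort((ts, key))
        key_s, ts_s = key[order], ts[order]
    vals_s = vals[order]
    bounds = np.flatnonzero(np.diff(key_s)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(key_s)]])
    for s, e in zip(starts, ends):
        k = key_s[s]
        pid = pids[k // len(chs)]
        ch = chs[k % len(chs)]
        out[(pid, ch)] = (
            ts_s[s:e],
            np.concatenate([[0.0], np.cumsum(vals_s[s:e])]),
        )


def group_observations(
    obs, channels
) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """Split long observation tables into per-(patient, channel) arrays.

    ``obs`` may be one DataFrame or a list of DataFrames whose
    (patient, channel) groups are disjoint.  Returns
    ``{(patient_id, channel): (ts_sorted, cumsum)}`` where ``cumsum`` is the
    zero-prefixed cumulative sum of the values in time order, so any
    half-open time-interval mean is two searchsorted lookups.
    """
    frames = obs if isinstance(obs, (list, tuple)) else [obs]
    out: dict = {}
    for frame in frames:
        _group_one(frame, channels, out)
    return out


def interval_means(
    ts: np.ndarray, cum: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and count of observations in each half-open interval [lo, hi)."""
    i = np.searchsorted(ts, lo, side="left")
    j = np.searchsorted(ts, hi, side="left")
    n = j - i
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(n > 0, (cum[j] - cum[i]) / np.maximum(n, 1), np.nan)
    return m, n
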