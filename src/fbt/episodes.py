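"""Fluid-bolus detection, the isolation rule, and control-episode sampling.

A fluid bolus (FB) is the continuous administration of >= 250 ml of
crystalloid within <= 30 min, which implies a mean rate >= 500 ml/h.
"Continuous" is resolved on the recording grid: adjacent crystalloid
records separated by no more than a gap tolerance (default one 2-min grid
step) are merged into a single candidate administration.

Each episode carries an observation window from 60 min before its start to
60 min after its end.  A bolus is *isolated* when no other detected bolus
falls inside that window.  Control episodes are pseudo-epochs of the same
duration as their index bolus, sampled uniformly over the stay where no
fluid above a maintenance threshold was running anywhere in the window.

All intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MIN = pd.Timedelta(minutes=1)
NS_PER_MIN = 60_000_000_000
WINDOW_MIN = 60.0  # minutes before start / after end

BOLUS_MIN_VOLUME_ML = 250.0
BOLUS_MAX_DURATION_MIN = 30.0
BOLUS_MIN_RATE_ML_H = 500.0

EPISODE_COLUMNS = [
    "episode_id", "patient_id", "kind", "start_ts", "end_ts", "volume_ml",
    "duration_min", "mean_rate_ml_h", "window_start_ts", "window_end_ts",
    "source_bolus_id",
]


def qualifies_as_bolus(volume_ml: float, duration_min: float) -> bool:
    """The operational FB definition; the rate bound is implied but re-checked."""
    if duration_min <= 0:
        return False
    rate = volume_ml / duration_min * 60.0
    return (
        volume_ml >= BOLUS_MIN_VOLUME_ML
        and duration_min <= BOLUS_MAX_DURATION_MIN
        and rate >= BOLUS_MIN_RATE_ML_H
    )


# ---------------------------------------------------------------------------
# numpy cores (timestamps as int64 nanoseconds)


def _detect_spans(
    starts_ns: np.ndarray, ends_ns: np.ndarray, vols: np.ndarray,
    gap_tolerance_min: float,
) -> list[tuple[int, int, float]]:
    """Maximal qualifying merged spans as (start_ns, end_ns, volume) tuples."""
    n = len(starts_ns)
    if n == 0:
        return []
    if np.any(ends_ns <= starts_ns):
        raise ValueError("infusion records must have end_ts > start_ts")
    if np.any(np.diff(starts_ns) < 0):
        raise ValueError("infusion records must be sorted by start_ts")
    if np.any(starts_ns[1:] < ends_ns[:-1]):
        raise ValueError("overlapping crystalloid records: malformed input")

    gap_ns = int(gap_tolerance_min * NS_PER_MIN)
    run_id = np.concatenate([[0], np.cumsum(starts_ns[1:] - ends_ns[:-1] > gap_ns)])

    candidates: list[tuple[int, int]] = []
    for i in range(n):
        cum = 0.0
        for j in range(i, n):
            if run_id[j] != run_id[i]:
                break
            cum += vols[j]
            dur = (ends_ns[j] - starts_ns[i]) / NS_PER_MIN
            if dur > BOLUS_MAX_DURATION_MIN:
                break
            if qualifies_as_bolus(cum, dur):
                candidates.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in candidates
        if not any((i2 <= i and j <= j2 and (i2, j2) != (i, j)) for i2, j2 in candidates)
    ]
    maximal.sort(key=lambda ij: starts_ns[ij[0]])
    return [
        (int(starts_ns[i]), int(ends_ns[j]), float(vols[i : j + 1].sum()))
        for i, j in maximal
    ]


def _isolated_mask(starts_ns: np.ndarray, ends_ns: np.ndarray) -> np.ndarray:
    """True where no other bolus intersects the +/-60-min window."""
    n = len(starts_ns)
    keep = np.ones(n, dtype=bool)
    margin = int(WINDOW_MIN * NS_PER_MIN)
    for i in range(n):
        others = np.arange(n) != i
        overlap = (starts_ns[others] < ends_ns[i] + margin) & (
            ends_ns[others] > starts_ns[i] - margin
        )
        keep[i] = not overlap.any()
    return keep


def _control_starts(
    rng: np.random.Generator,
    stay_min: float,
    dur_min: float,
    excl_lo_min: np.ndarray,
    excl_hi_min: np.ndarray,
    n_wanted: int,
    grid_step_min: int,
) -> np.ndarray:
    """Admissible control start offsets (minutes since admission), sampled
    uniformly without replacement from the grid."""
    last_start = stay_min - (dur_min + WINDOW_MIN)
    ks = np.arange(
        int(np.ceil(WINDOW_MIN / grid_step_min)),
        int(np.floor(last_start / grid_step_min)) + 1,
    )
    if ks.size == 0:
        return np.empty(0)
    t0 = ks * grid_step_min
    bad = (t0[:, None] - WINDOW_MIN < excl_hi_min[None, :]) & (
        t0[:, None] + dur_min + WINDOW_MIN > excl_lo_min[None, :]
    )
    admissible = t0[~bad.any(axis=1)]
    if admissible.size == 0:
        return np.empty(0)
    chosen = rng.choice(admissible, size=min(n_wanted, admissible.size), replace=False)
    return np.sort(chosen)


# ---------------------------------------------------------------------------
# public per-patient operations


def _episode_row(patient_id, kind, start, end, volume_ml, source_bolus_id=None) -> dict:
    duration = (end - start) / MIN
    return {
        "patient_id": patient_id,
        "kind": kind,
        "start_ts": start,
        "end_ts": end,
        "volume_ml": float(volume_ml),
        "duration_min": float(duration),
        "mean_rate_ml_h": float(volume_ml) / duration * 60.0 if duration > 0 else np.nan,
        "window_start_ts": start - WINDOW_MIN * MIN,
        "window_end_ts": end + WINDOW_MIN * MIN,
        "source_bolus_id": source_bolus_id,
    }


def detect_boluses(infusions: pd.DataFrame, gap_tolerance_min: float = 2.0) -> pd.DataFrame:
    """Detect fluid boluses in one patient's crystalloid infusion records.

    Parameters
    ----------
    infusions
        Records of a single patient, crystalloid substance only, with
        ``start_ts``, ``end_ts`` and ``volume_ml`` columns, sorted by start.
    gap_tolerance_min
        Largest gap between consecutive records still treated as one
        continuous administration.

    Returns
    -------
    DataFrame of bolus episodes: every *maximal* merged run of records that
    satisfies the FB definition (volume >= 250 ml, duration <= 30 min, mean
    rate >= 500 ml/h).  Maximal means not extendable to a longer qualifying
    run of contiguous records.

    Raises
    ------
    ValueError
        If records of the same patient overlap in time (malformed input).
    """
    df = infusions.reset_index(drop=True)
    if len(df) == 0:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    spans = _detect_spans(
        df["start_ts"].to_numpy().astype("datetime64[ns]").view(np.int64),
        df["end_ts"].to_numpy().astype("datetime64[ns]").view(np.int64),
        df["volume_ml"].to_numpy(dtype=float),
        gap_tolerance_min,
    )
    pid = df["patient_id"].iloc[0]
    rows = [
        _episode_row(pid, "bolus", pd.Timestamp(s), pd.Timestamp(e), v)
        for s, e, v in spans
    ]
    if not rows:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    out = pd.DataFrame(rows, columns=EPISODE_COLUMNS[1:])
    out.insert(0, "episode_id", range(len(out)))
    return out


def filter_isolated(boluses: pd.DataFrame) -> pd.DataFrame:
    """Keep boluses with no other bolus of the same patient inside their window.

    Two boluses mutually exclude each other whenever the gap between their
    administration intervals is below the 60-min window margin, so the rule
    is symmetric.
    """
    if len(boluses) <= 1:
        return boluses.reset_index(drop=True)
    keep = _isolated_mask(
        boluses["start_ts"].to_numpy().astype("datetime64[ns]").view(np.int64),
        boluses["end_ts"].to_numpy().astype("datetime64[ns]").view(np.int64),
    )
    return boluses.loc[keep].reset_index(drop=True)


def sample_controls(
    patient: pd.Series,
    infusions: pd.DataFrame,
    boluses: pd.DataFrame,
    index_boluses: pd.DataFrame | None = None,
    n_per_bolus: int = 2,
    max_maintenance_rate_ml_h: float = 50.0,
    grid_step_min: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample no-fluid control pseudo-episodes for each bolus of one patient.

    Each control copies the duration of its index bolus (rows of
    ``index_boluses``, defaulting to ``boluses``); its start time is drawn
    uniformly (without replacement) from the grid of admissible start
    points.  A start point is admissible when (i) the full +/-60-min window
    lies within the stay, (ii) the window does not intersect the observation
    window of *any* detected bolus (``boluses``), and (iii) no infusion
    running above ``max_maintenance_rate_ml_h`` intersects the window.  When
    fewer than ``n_per_bolus`` admissible points exist, the shortfall is
    logged and a partial set returned.
    """
    admit, discharge = patient["admit_ts"], patient["discharge_ts"]
    rng = np.random.default_rng(seed)
    if index_boluses is None:
        index_boluses = boluses
    excl_lo, excl_hi = _exclusion_intervals(
        admit, boluses, infusions, max_maintenance_rate_ml_h
    )
    stay_min = (discharge - admit) / MIN
    rows = []
    for b in index_boluses.itertuples(index=False):
        starts = _control_starts(
            rng, stay_min, float(b.duration_min), excl_lo, excl_hi,
            n_per_bolus, grid_step_min,
        )
        if starts.size < n_per_bolus:
            log.warning(
                "patient %s bolus %s: only %d of %d control starts available",
                patient["patient_id"], getattr(b, "episode_id", None),
                starts.size, n_per_bolus,
            )
        for t in starts:
            start = admit + float(t) * MIN
            rows.append(
                _episode_row(
                    patient["patient_id"], "control", start,
                    start + float(b.duration_min) * MIN, 0.0,
                    source_bolus_id=getattr(b, "episode_id", None),
                )
            )
    return pd.DataFrame(rows, columns=EPISODE_COLUMNS[1:])


def _exclusion_intervals(admit, boluses, infusions, max_maintenance_rate_ml_h):
    """Bolus windows and above-threshold infusions, minutes since admission."""
    heavy = infusions[infusions["rate_ml_h"] > max_maintenance_rate_ml_h]
    a64 = np.datetime64(admit)
    lo = np.concatenate(
        [
            (boluses["window_start_ts"].to_numpy() - a64) / np.timedelta64(60, "s"),
            (heavy["start_ts"].to_numpy() - a64) / np.timedelta64(60, "s"),
        ]
    )
    hi = np.concatenate(
        [
            (boluses["window_end_ts"].to_numpy() - a64) / np.timedelta64(60, "s"),
            (heavy["end_ts"].to_numpy() - a64) / np.timedelta64(60, "s"),
        ]
    )
    return lo, hi


# ---------------------------------------------------------------------------
# cohort-level extraction


def extract_episodes(
    infusions: pd.DataFrame,
    patients: pd.DataFrame,
    crystalloid: str = "ringer_lactate",
    gap_tolerance_min: float = 2.0,
    n_controls_per_bolus: int = 2,
    max_maintenance_rate_ml_h: float = 50.0,
    grid_step_min: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Run detection, isolation, the in-stay window check and control
    sampling for a whole cohort.

    Returns the episode table (bolus episodes first, then controls, with
    globally unique integer ``episode_id``) and the episode funnel counts.
    Controls reference their index bolus through ``source_bolus_id``.
    """
    funnel = {"detected": 0, "isolated": 0, "window_in_stay": 0, "controls": 0}
    margin_ns = int(WINDOW_MIN * NS_PER_MIN)

    pat = patients.sort_values("patient_id")
    is_crys = infusions["substance"].to_numpy() == crystalloid
    heavy_mask = infusions["rate_ml_h"].to_numpy(dtype=float) > max_maintenance_rate_ml_h
    start_arr = infusions["start_ts"].to_numpy().astype("datetime64[ns]").view(np.int64)
    end_arr = infusions["end_ts"].to_numpy().astype("datetime64[ns]").view(np.int64)
    vol_arr = infusions["volume_ml"].to_numpy(dtype=float)
    rows_by_patient = infusions.groupby("patient_id", sort=False).indices

    bolus_rows: list[dict] = []
    control_rows: list[dict] = []
    shortfalls = 0
    for idx, patient in enumerate(pat.itertuples(index=False)):
        pid = patient.patient_id
        sel = rows_by_patient.get(pid, np.empty(0, dtype=int))
        crys_sel = sel[is_crys[sel]]
        order = np.argsort(start_arr[crys_sel], kind="stable")
        s_ns = start_arr[crys_sel][order]
        e_ns = end_arr[crys_sel][order]
        v = vol_arr[crys_sel][order]
        spans = _detect_spans(s_ns, e_ns, v, gap_tolerance_min)
        funnel["detected"] += len(spans)
        if not spans:
            continue
        b_start = np.array([s for s, _, _ in spans], dtype=np.int64)
        b_end = np.array([e for _, e, _ in spans], dtype=np.int64)
        b_vol = np.array([vo for _, _, vo in spans])
        iso = _isolated_mask(b_start, b_end)
        funnel["isolated"] += int(iso.sum())
        admit_ns = patient.admit_ts.value
        disch_ns = patient.discharge_ts.value
        in_stay = iso & (b_start - margin_ns >= admit_ns) & (b_end + margin_ns <= disch_ns)
        funnel["window_in_stay"] += int(in_stay.sum())
        if not in_stay.any():
            continue

        # exclusion set: every detected bolus window + heavy infusions
        h_sel = sel[heavy_mask[sel]]
        excl_lo = np.concatenate(
            [(b_start - margin_ns - admit_ns) / NS_PER_MIN,
             (start_arr[h_sel] - admit_ns) / NS_PER_MIN]
        )
        excl_hi = np.concatenate(
            [(b_end + margin_ns - admit_ns) / NS_PER_MIN,
             (end_arr[h_sel] - admit_ns) / NS_PER_MIN]
        )
        stay_min = (disch_ns - admit_ns) / NS_PER_MIN
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31)
        )
        local_rows = []
        for k in np.flatnonzero(in_stay):
            s = pd.Timestamp(b_start[k])
            e = pd.Timestamp(b_end[k])
            local_rows.append(_episode_row(pid, "bolus", s, e, b_vol[k]))
        for local_id, k in enumerate(np.flatnonzero(in_stay)):
            dur = (b_end[k] - b_start[k]) / NS_PER_MIN
            starts = _control_starts(
                rng, stay_min, dur, excl_lo, excl_hi,
                n_controls_per_bolus, grid_step_min,
            )
            if starts.size < n_controls_per_bolus:
                shortfalls += 1
            for t in starts:
                cs = pd.Timestamp(admit_ns + int(t * NS_PER_MIN))
                control_rows.append(
                    _episode_row(pid, "control", cs, cs + dur * MIN, 0.0,
                                 source_bolus_id=local_id)
                )
            funnel["controls"] += starts.size
        bolus_rows.extend(local_rows)
    if shortfalls:
        log.warning("%d boluses received fewer than the requested controls", shortfalls)
    if not bolus_rows:
        return pd.DataFrame(columns=EPISODE_COLUMNS), funnel
    episodes = pd.DataFrame(bolus_rows + control_rows, columns=EPISODE_COLUMNS[1:])
    episodes = episodes.sort_values(
        ["kind", "patient_id", "start_ts"], kind="mergesort"
    ).reset_index(drop=True)
    episodes.insert(0, "episode_id", range(len(episodes)))
    return _remap_source_ids(episodes), funnel


def _remap_source_ids(episodes: pd.DataFrame) -> pd.DataFrame:
    """Point each control's ``source_bolus_id`` at the global bolus id.

    Controls record the positional id of their index bolus within the
    patient (by start time); after global renumbering the k-th bolus of a
    patient keeps its relative order, so the mapping is positional.
    """
    episodes = episodes.copy()
    is_bolus = episodes["kind"] == "bolus"
    b = episodes[is_bolus].sort_values(["patient_id", "start_ts"])
    local = b.groupby("patient_id", sort=False).cumcount()
    mapping = {
        (pid, loc): gid
        for pid, loc, gid in zip(b["patient_id"], local, b["episode_id"])
    }
    ctrl = episodes[~is_bolus]
    keys = list(zip(ctrl["patient_id"], ctrl["source_bolus_id"]))
    episodes.loc[~is_bolus, "source_bolus_id"] = [mapping.get(k) for k in keys]
    episodes["source_bolus_id"] = pd.array(
        episodes["source_bolus_id"], dtype="Int64"
    )
    return episodes
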