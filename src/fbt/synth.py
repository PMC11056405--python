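"""Synthetic post-cardiac-surgery ICU cohorts with known bolus effects.

Emulates the structure of a patient-data-management-system export: vital
signs stored on a 2-min grid as autocorrelated (AR(1)) series around
patient-specific set points, sporadic blood-gas panels, vasoactive drips,
a continuous crystalloid maintenance infusion, and Ringer's-lactate fluid
boluses whose occurrence hazard can be made to depend on preceding
hypotension (confounding by indication).  Each bolus adds configurable
response kernels to the latent channel trajectories, so the ground-truth
effect of fluid on every channel is known exactly.

Units: CO l/min, SV ml, pressures mmHg, SpO2/SaO2/SvO2 %, Hb g/dl,
lactate mmol/l, PaO2 mmHg, infusion rates ml/h, urine ml per collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

MIN = pd.Timedelta(minutes=1)

#: channels sourced from the pulmonary artery catheter; their observations
#: stop once the catheter is removed.
PAC_CHANNELS = ("co", "sv", "papm")
PAC_LABS = ("svo2", "pcwp")

#: labs drawn together as one arterial blood-gas panel.
ABG_LABS = ("hb", "ph", "be", "lactate", "pao2", "sao2", "svo2")

CRYSTALLOID = "ringer_lactate"


def _qualifies(volume_ml: float, duration_min: float) -> bool:
    """The fluid-bolus definition: >=250 ml in <=30 min at >=500 ml/h."""
    return (
        volume_ml >= 250.0
        and duration_min <= 30.0
        and volume_ml / duration_min * 60.0 >= 500.0
    )


@dataclass(frozen=True)
class ChannelParams:
    """AR(1) parameters of one continuously recorded channel.

    ``sd`` is the stationary within-patient SD; ``between_sd`` the SD of the
    patient-specific set point around ``mean``; ``ar`` the lag-1
    autocorrelation at the 2-min grid step.
    """

    mean: float
    sd: float
    ar: float = 0.9
    between_sd: float = 0.0
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0 or self.between_sd < 0:
            raise ValueError("channel SDs must be >= 0")
        if not -1 < self.ar < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


@dataclass(frozen=True)
class LabParams:
    mean: float
    sd: float
    between_sd: float = 0.0


@dataclass(frozen=True)
class EffectKernel:
    """Additive response of one channel to a fluid bolus.

    The kernel is zero at and before the bolus start, rises linearly from
    ``onset_time`` (minutes relative to the bolus *end*; negative values
    start the rise during the infusion, clipped at the bolus start) to
    ``peak_delta`` at ``peak_time``, then decays exponentially with
    ``dissipation_half_life`` (``inf`` = sustained effect).

    ``volume_coef_per_100ml`` adds a volume-proportional component to the
    peak: effective peak = ``peak_delta + volume_coef_per_100ml * V/100``.
    """

    variable: str
    peak_delta: float
    peak_time: float = 40.0
    onset_time: float = 0.0
    dissipation_half_life: float = math.inf
    volume_coef_per_100ml: float = 0.0

    def __post_init__(self) -> None:
        if self.onset_time > self.peak_time:
            raise ValueError("onset_time must be <= peak_time")
        if self.dissipation_half_life <= 0:
            raise ValueError("dissipation_half_life must be positive")

    def values(
        self,
        t_after_end_min: np.ndarray,
        duration_min: float,
        volume_ml: float,
    ) -> np.ndarray:
        """Kernel value at times given in minutes after the bolus end."""
        t = np.asarray(t_after_end_min, dtype=float)
        peak = self.peak_delta + self.volume_coef_per_100ml * volume_ml / 100.0
        rise_start = max(self.onset_time, -duration_min)
        out = np.zeros_like(t)
        if self.peak_time > rise_start:
            ramp = (t - rise_start) / (self.peak_time - rise_start)
            out = peak * np.clip(ramp, 0.0, 1.0)
        else:  # step at the peak time
            out = np.where(t >= self.peak_time, peak, 0.0)
        decaying = t > self.peak_time
        if np.isfinite(self.dissipation_half_life) and decaying.any():
            out[decaying] = peak * 0.5 ** (
                (t[decaying] - self.peak_time) / self.dissipation_half_life
            )
        out[t <= -duration_min] = 0.0
        return out


def _default_channels() -> dict[str, ChannelParams]:
    return {
        "co": ChannelParams(5.0, 0.8, 0.9, 0.8, lo=1.5),
        "sv": ChannelParams(70.0, 12.0, 0.9, 12.0, lo=20.0),
        "hr": ChannelParams(82.0, 8.0, 0.9, 10.0, lo=40.0),
        "map": ChannelParams(75.0, 8.0, 0.9, 7.0, lo=35.0),
        "sbp": ChannelParams(112.0, 12.0, 0.9, 10.0, lo=60.0),
        "dbp": ChannelParams(52.0, 6.0, 0.9, 6.0, lo=25.0),
        "cvp": ChannelParams(10.0, 2.5, 0.9, 2.5, lo=0.0),
        "papm": ChannelParams(23.0, 3.5, 0.9, 3.5, lo=5.0),
        "spo2": ChannelParams(97.5, 1.0, 0.9, 0.8, hi=100.0),
    }


def _default_labs() -> dict[str, LabParams]:
    return {
        "hb": LabParams(10.1, 0.6, 1.0),
        "ph": LabParams(7.42, 0.03, 0.02),
        "be": LabParams(-0.5, 1.2, 1.5),
        "lactate": LabParams(1.9, 0.5, 0.6),
        "pao2": LabParams(108.0, 15.0, 15.0),
        "sao2": LabParams(97.3, 1.0, 0.8),
        "svo2": LabParams(59.0, 5.0, 6.0),
        "pcwp": LabParams(13.6, 2.5, 3.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines a synthetic cohort (given ``seed``)."""

    n_patients: int = 300
    seed: int = 0
    # length of stay: lognormal, median ~29 h
    stay_hours_median: float = 29.0
    stay_hours_sigma: float = 0.6
    min_stay_hours: float = 8.0
    grid_step_min: int = 2
    channel_params: dict[str, ChannelParams] = field(default_factory=_default_channels)
    lab_params: dict[str, LabParams] = field(default_factory=_default_labs)
    abg_interval_mean_min: float = 180.0
    pcwp_interval_mean_min: float = 300.0
    vitals_missing_frac: float = 0.01
    pac_removal_hazard_per_h: float = 0.04
    # fluid therapy
    bolus_rate_per_hour: float = 0.10
    bolus_volume_median_ml: float = 355.0
    bolus_volume_sigma: float = 0.40
    bolus_duration_mean_min: float = 18.2
    bolus_duration_sd_min: float = 9.0
    bolus_duration_range_min: tuple[float, float] = (5.0, 30.0)
    bolus_refractory_min: float = 10.0
    maintenance_rate_ml_h: float = 30.0
    maintenance_pause_min: float = 4.0
    # default bolus responses: sustained over the 60-min observation window,
    # dissipating over a few hours as crystalloid redistributes
    effect_kernels: tuple[EffectKernel, ...] = (
        EffectKernel("co", peak_delta=0.2, peak_time=40.0, dissipation_half_life=180.0),
        EffectKernel("sv", peak_delta=2.3, peak_time=25.0, dissipation_half_life=180.0),
    )
    confounding_strength: float = 1.0
    confounding_lookback_min: float = 30.0
    # vasoactive drips (the dominant post-cardiac-surgery agents)
    p_norepinephrine: float = 0.6
    p_milrinone: float = 0.3
    drip_segment_mean_h: float = 2.0
    norepinephrine_rate_median_ml_h: float = 12.0
    milrinone_rate_median_ml_h: float = 6.0
    drip_rate_sigma: float = 0.5
    urine_mean_ml_h: float = 95.0
    urine_sd_ml_h: float = 35.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if 60 % self.grid_step_min != 0:
            raise ValueError("grid_step_min must divide 60")
        for kernel in self.effect_kernels:
            if kernel.variable not in self.channel_params:
                raise ValueError(f"effect kernel targets unknown channel {kernel.variable!r}")


@dataclass
class SyntheticCohort:
    """Long-format tables of one simulated cohort plus the ground-truth log."""

    patients: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    infusions: pd.DataFrame
    urine: pd.DataFrame
    truth: pd.DataFrame


_ADMIT_BASE = pd.Timestamp("2019-01-01 08:00:00")

PATIENT_COLUMNS = [
    "patient_id", "age_years", "sex", "height_cm", "weight_kg", "apache2",
    "admission_type", "surgery_type", "mechanical_ventilation",
    "admit_ts", "discharge_ts",
]
OBS_COLUMNS = ["patient_id", "ts", "channel", "value"]
INFUSION_COLUMNS = ["patient_id", "substance", "start_ts", "end_ts", "volume_ml", "rate_ml_h"]
URINE_COLUMNS = ["patient_id", "ts", "volume_ml"]
TRUTH_COLUMNS = [
    "bolus_id", "patient_id", "start_ts", "end_ts", "volume_ml",
    "duration_min", "qualifies", "variable", "peak_delta_effective",
    "peak_time", "onset_time", "dissipation_half_life",
]


def _ar1(rng: np.random.Generator, n: int, p: ChannelParams, set_point: float) -> np.ndarray:
    """Stationary AR(1) series of length ``n`` around ``set_point``."""
    innov_sd = p.sd * math.sqrt(1.0 - p.ar**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x0 = rng.normal(0.0, p.sd)
    dev = signal.lfilter([1.0], [1.0, -p.ar], eps, zi=[p.ar * x0])[0]
    return np.clip(set_point + dev, p.lo, p.hi)


def _trailing_mean(x: np.ndarray, width: int) -> np.ndarray:
    """Mean of the last ``width`` values (fewer at the start), causal."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    n = np.arange(1, len(x) + 1)
    lo = np.maximum(0, n - width)
    return (c[n] - c[lo]) / (n - lo)


def _place_boluses(
    rng: np.random.Generator,
    cfg: CohortConfig,
    map_latent: np.ndarray,
    n_steps: int,
) -> list[tuple[int, float, float]]:
    """Sequential bolus placement: (start step, duration min, volume ml).

    The per-step hazard is the base rate scaled by exp(c * z) where z is the
    standardised deficit of the trailing-mean MAP below the population mean,
    producing confounding by indication when c > 0.  The hazard uses the
    kernel-free latent MAP so that injected kernels never alter bolus
    placement (keeps the injected-effect accounting exact).
    """
    step_h = cfg.grid_step_min / 60.0
    base_p = cfg.bolus_rate_per_hour * step_h
    mp = cfg.channel_params["map"]
    sd_total = math.hypot(mp.sd, mp.between_sd)
    width = max(1, int(round(cfg.confounding_lookback_min / cfg.grid_step_min)))
    z = (mp.mean - _trailing_mean(map_latent, width)) / sd_total
    p = np.clip(base_p * np.exp(cfg.confounding_strength * z), 0.0, 0.5)
    u = rng.uniform(size=n_steps)
    candidates = np.flatnonzero(u < p)

    lo, hi = cfg.bolus_duration_range_min
    boluses: list[tuple[int, float, float]] = []
    next_free_min = 0.0
    stay_min = n_steps * cfg.grid_step_min
    for k in candidates:
        t_start = float(k * cfg.grid_step_min)
        if t_start < next_free_min:
            continue
        dur = rng.normal(cfg.bolus_duration_mean_min, cfg.bolus_duration_sd_min)
        while not lo <= dur <= hi:  # truncation by rejection
            dur = rng.normal(cfg.bolus_duration_mean_min, cfg.bolus_duration_sd_min)
        dur = float(np.clip(round(dur), lo, hi))
        vol = float(
            np.exp(rng.normal(math.log(cfg.bolus_volume_median_ml), cfg.bolus_volume_sigma))
        )
        vol = round(vol, 1)
        if t_start + dur > stay_min:
            continue
        boluses.append((int(k), dur, vol))
        next_free_min = t_start + dur + cfg.bolus_refractory_min
    return boluses


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate one cohort; identical config (incl. seed) gives identical tables."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    step = cfg.grid_step_min

    patients: list[dict] = []
    vit_parts: list[tuple] = []  # (patient_id, ts_ns, channel, value) arrays
    lab_parts: list[tuple] = []  # (patient_id, ts_ns, channel, value) rows
    inf_parts: list[dict] = []
    urine_parts: list[tuple] = []  # (patient_id, ts_ns, volume) arrays
    truth_rows: list[dict] = []
    bolus_counter = 0

    channel_names = list(cfg.channel_params)
    pac_code_mask = np.array([ch in PAC_CHANNELS for ch in channel_names])
    kernels_by_channel: dict[str, list[EffectKernel]] = {}
    for kern in cfg.effect_kernels:
        kernels_by_channel.setdefault(kern.variable, []).append(kern)

    for i in range(cfg.n_patients):
        pid = f"P{i:04d}"
        admit = _ADMIT_BASE + pd.Timedelta(hours=6 * i)
        stay_h = max(
            cfg.min_stay_hours,
            float(np.exp(rng.normal(math.log(cfg.stay_hours_median), cfg.stay_hours_sigma))),
        )
        n_steps = int(stay_h * 60 // step)
        stay_min = n_steps * step
        discharge = admit + stay_min * MIN

        patients.append(
            {
                "patient_id": pid,
                "age_years": round(float(np.clip(rng.normal(66.9, 11.45), 18, 95)), 1),
                "sex": "F" if rng.uniform() < 0.258 else "M",
                "height_cm": round(float(rng.normal(170.9, 9.9)), 1),
                "weight_kg": round(float(np.clip(rng.normal(80.4, 17.7), 40, 160)), 1),
                "apache2": int(np.clip(round(rng.normal(17.4, 6.2)), 0, 50)),
                "admission_type": "emergency" if rng.uniform() < 0.058 else "elective",
                "surgery_type": ["cabg", "valve", "cabg_valve"][
                    int(rng.choice(3, p=[0.441, 0.366, 0.193]))
                ],
                "mechanical_ventilation": bool(rng.uniform() < 0.6),
                "admit_ts": admit,
                "discharge_ts": discharge,
            }
        )

        grid_min = np.arange(n_steps) * step  # minutes since admission
        ts = admit + pd.to_timedelta(grid_min, unit="m")

        set_points = {
            ch: p.mean + rng.normal(0.0, p.between_sd) for ch, p in cfg.channel_params.items()
        }
        latent = {
            ch: _ar1(rng, n_steps, p, set_points[ch]) for ch, p in cfg.channel_params.items()
        }

        boluses = _place_boluses(rng, cfg, latent["map"], n_steps)

        # add response kernels on top of the latent series (no RNG consumed).
        # Only administrations meeting the FB definition carry an effect:
        # sub-threshold volumes/rates are treated as hemodynamically inert,
        # so control windows (which exclude all detected-bolus windows) stay
        # free of kernel transients.
        for k_start, dur, vol in boluses:
            if not _qualifies(vol, dur):
                continue
            t_end_min = k_start * step + dur
            t_after_end = grid_min - t_end_min
            for ch, kerns in kernels_by_channel.items():
                for kern in kerns:
                    latent[ch] = latent[ch] + kern.values(t_after_end, dur, vol)

        # observation dropout + PAC removal
        pac_removal_min = math.inf
        if cfg.pac_removal_hazard_per_h > 0:
            pac_removal_min = rng.exponential(60.0 / cfg.pac_removal_hazard_per_h)
        values = np.concatenate([latent[ch] for ch in channel_names])
        chan_codes = np.repeat(np.arange(len(channel_names)), n_steps)
        t_col = np.tile(grid_min, len(channel_names))
        keep = rng.uniform(size=values.size) >= cfg.vitals_missing_frac
        keep &= ~(pac_code_mask[chan_codes] & (t_col >= pac_removal_min))
        ts_ns = admit.value + (t_col[keep] * 60e9).astype(np.int64)
        vit_parts.append((pid, ts_ns, chan_codes[keep], np.round(values[keep], 4)))

        # sporadic labs: shared ABG panels plus separate PCWP recordings
        lab_means = {
            lab: p.mean + rng.normal(0.0, p.between_sd) for lab, p in cfg.lab_params.items()
        }

        def _sample_times(mean_gap: float) -> np.ndarray:
            gaps = rng.exponential(mean_gap, size=max(4, int(3 * stay_min / mean_gap) + 4))
            t = np.cumsum(gaps)
            return np.round(t[t < stay_min])

        abg_t = _sample_times(cfg.abg_interval_mean_min)
        for lab in ABG_LABS:
            p = cfg.lab_params[lab]
            vals = lab_means[lab] + rng.normal(0.0, p.sd, size=abg_t.size)
            for t, v in zip(abg_t, vals):
                if lab in PAC_LABS and t >= pac_removal_min:
                    continue
                lab_parts.append((pid, admit.value + int(t * 60e9), lab, round(float(v), 4)))
        pcwp_t = _sample_times(cfg.pcwp_interval_mean_min)
        p = cfg.lab_params["pcwp"]
        vals = lab_means["pcwp"] + rng.normal(0.0, p.sd, size=pcwp_t.size)
        for t, v in zip(pcwp_t, vals):
            if t < pac_removal_min:
                lab_parts.append((pid, admit.value + int(t * 60e9), "pcwp", round(float(v), 4)))

        # infusions: boluses, maintenance crystalloid, vasoactive drips
        bolus_intervals = []
        for k_start, dur, vol in boluses:
            s_min, e_min = k_start * step, k_start * step + dur
            bolus_intervals.append((s_min, e_min))
            inf_parts.append(
                {
                    "patient_id": pid,
                    "substance": CRYSTALLOID,
                    "start_ts": admit + s_min * MIN,
                    "end_ts": admit + e_min * MIN,
                    "volume_ml": vol,
                    "rate_ml_h": round(vol / dur * 60.0, 2),
                }
            )
            q = _qualifies(vol, dur)
            base = {
                "bolus_id": f"{pid}-t{bolus_counter}",
                "patient_id": pid,
                "start_ts": admit + s_min * MIN,
                "end_ts": admit + e_min * MIN,
                "volume_ml": vol,
                "duration_min": dur,
                "qualifies": q,
            }
            if cfg.effect_kernels:
                for kern in cfg.effect_kernels:
                    truth_rows.append(
                        base
                        | {
                            "variable": kern.variable,
                            "peak_delta_effective": (
                                kern.peak_delta
                                + kern.volume_coef_per_100ml * vol / 100.0
                            ) if q else 0.0,
                            "peak_time": kern.peak_time,
                            "onset_time": kern.onset_time,
                            "dissipation_half_life": kern.dissipation_half_life,
                        }
                    )
            else:
                truth_rows.append(
                    base
                    | {
                        "variable": None,
                        "peak_delta_effective": np.nan,
                        "peak_time": np.nan,
                        "onset_time": np.nan,
                        "dissipation_half_life": np.nan,
                    }
                )
            bolus_counter += 1

        if cfg.maintenance_rate_ml_h > 0:
            # maintenance pauses around each bolus (separate line during FB),
            # leaving a gap wider than the detection gap tolerance
            edges = [0.0]
            for s_min, e_min in bolus_intervals:
                edges += [max(0.0, s_min - cfg.maintenance_pause_min),
                          min(stay_min, e_min + cfg.maintenance_pause_min)]
            edges.append(stay_min)
            for s_min, e_min in zip(edges[::2], edges[1::2]):
                if e_min - s_min < 1.0:
                    continue
                inf_parts.append(
                    {
                        "patient_id": pid,
                        "substance": CRYSTALLOID,
                        "start_ts": admit + s_min * MIN,
                        "end_ts": admit + e_min * MIN,
                        "volume_ml": round(cfg.maintenance_rate_ml_h * (e_min - s_min) / 60.0, 2),
                        "rate_ml_h": cfg.maintenance_rate_ml_h,
                    }
                )

        for drug, p_on, med_rate in (
            ("norepinephrine", cfg.p_norepinephrine, cfg.norepinephrine_rate_median_ml_h),
            ("milrinone", cfg.p_milrinone, cfg.milrinone_rate_median_ml_h),
        ):
            if rng.uniform() >= p_on:
                continue
            t = 0.0
            while t < stay_min:
                seg = min(stay_min - t, rng.exponential(cfg.drip_segment_mean_h * 60.0))
                seg = max(seg, float(step))
                rate = float(np.exp(rng.normal(math.log(med_rate), cfg.drip_rate_sigma)))
                inf_parts.append(
                    {
                        "patient_id": pid,
                        "substance": drug,
                        "start_ts": admit + round(t) * MIN,
                        "end_ts": admit + round(min(stay_min, t + seg)) * MIN,
                        "volume_ml": round(rate * seg / 60.0, 2),
                        "rate_ml_h": round(rate, 2),
                    }
                )
                t += seg

        hours = np.arange(60, stay_min, 60.0)
        if hours.size:
            urine_parts.append(
                (
                    pid,
                    admit.value + (hours * 60e9).astype(np.int64),
                    np.round(
                        np.clip(rng.normal(cfg.urine_mean_ml_h, cfg.urine_sd_ml_h,
                                           size=hours.size), 0, None), 1),
                )
            )

    def _concat(parts, columns):
        if not parts:
            return pd.DataFrame(columns=columns)
        out = pd.concat(parts, ignore_index=True) if isinstance(parts[0], pd.DataFrame) \
            else pd.DataFrame(parts)
        return out[columns]

    infusions = _concat(inf_parts, INFUSION_COLUMNS)
    if len(infusions):
        infusions = infusions.sort_values(
            ["patient_id", "start_ts", "substance"], kind="mergesort"
        ).reset_index(drop=True)
    if vit_parts:
        counts = [len(p[1]) for p in vit_parts]
        pid_list = [p[0] for p in vit_parts]
        # categorical id/channel columns: identical text on disk, far
        # cheaper to group in memory
        vitals = pd.DataFrame(
            {
                "patient_id": pd.Categorical.from_codes(
                    np.repeat(np.arange(len(pid_list)), counts), categories=pid_list
                ),
                "ts": np.concatenate([p[1] for p in vit_parts]).view("M8[ns]"),
                "channel": pd.Categorical.from_codes(
                    np.concatenate([p[2] for p in vit_parts]).astype(np.int8),
                    categories=channel_names,
                ),
                "value": np.concatenate([p[3] for p in vit_parts]),
            }
        )
    else:
        vitals = pd.DataFrame(columns=OBS_COLUMNS)
    if lab_parts:
        labs = pd.DataFrame(lab_parts, columns=OBS_COLUMNS)
        labs["ts"] = labs["ts"].to_numpy(dtype=np.int64).view("M8[ns]")
        labs = labs.sort_values(["patient_id", "ts", "channel"],
                                kind="mergesort").reset_index(drop=True)
    else:
        labs = pd.DataFrame(columns=OBS_COLUMNS)
    if urine_parts:
        u_counts = [len(p[1]) for p in urine_parts]
        urine = pd.DataFrame(
            {
                "patient_id": np.repeat(
                    np.array([p[0] for p in urine_parts], dtype=object), u_counts
                ),
                "ts": np.concatenate([p[1] for p in urine_parts]).view("M8[ns]"),
                "volume_ml": np.concatenate([p[2] for p in urine_parts]),
            }
        )
    else:
        urine = pd.DataFrame(columns=URINE_COLUMNS)
    return SyntheticCohort(
        patients=pd.DataFrame(patients, columns=PATIENT_COLUMNS),
        vitals=vitals,
        labs=labs,
        infusions=infusions,
        urine=urine,
        truth=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
    )


def null_config(config: CohortConfig) -> CohortConfig:
    """The same cohort conditions with every bolus-response kernel removed."""
    return replace(config, effect_kernels=())


# ---------------------------------------------------------------------------
# file round-trip

_TABLES = {
    "patients": (PATIENT_COLUMNS, ["admit_ts", "discharge_ts"]),
    "vitals": (OBS_COLUMNS, ["ts"]),
    "labs": (OBS_COLUMNS, ["ts"]),
    "infusions": (INFUSION_COLUMNS, ["start_ts", "end_ts"]),
    "urine": (URINE_COLUMNS, ["ts"]),
    "truth": (TRUTH_COLUMNS, ["start_ts", "end_ts"]),
}


def write_cohort(cohort: SyntheticCohort, directory, fmt: str = "csv") -> list[str]:
    """Write the five input tables (plus the truth log) to ``directory``.

    CSV files use ISO-8601 timestamps; the round trip through
    :func:`read_cohort` is lossless.
    """
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, (columns, _) in _TABLES.items():
        df = getattr(cohort, name)
        path = directory / f"{name}.{fmt}"
        if fmt == "csv":
            df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
        elif fmt == "parquet":
            df.to_parquet(path, index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        written.append(str(path))
    return written


def read_cohort(directory, fmt: str = "csv") -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort` (truth table optional)."""
    import pathlib

    directory = pathlib.Path(directory)
    frames = {}
    for name, (columns, ts_cols) in _TABLES.items():
        path = directory / f"{name}.{fmt}"
        if not path.exists():
            if name == "truth":
                frames[name] = pd.DataFrame(columns=columns)
                continue
            raise FileNotFoundError(path)
        if fmt == "csv":
            df = pd.read_csv(path, parse_dates=ts_cols)
        else:
            df = pd.read_parquet(path)
        frames[name] = df[columns]
    return SyntheticCohort(**frames)
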