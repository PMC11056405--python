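"""Derived physiological quantities: VIS, perfusion pressure, SVR, DO2.

Formulas are the standard clinical identities:

* vasoactive-inotropic score (Gaies):
  ``VIS = dopamine + dobutamine + 100*epinephrine + 10*milrinone
  + 10,000*vasopressin + 100*norepinephrine`` with catecholamine doses in
  ug/kg/min and vasopressin in U/kg/min;
* perfusion pressure = MAP - CVP (mmHg);
* SVR = 80*(MAP - CVP)/CO (dyn*s*cm^-5), undefined when CO is missing or
  non-positive;
* DO2 = 10*CO*(1.34*Hb*SaO2/100 + 0.0031*PaO2) (ml O2/min, Hb in g/dl).

Missing inputs always propagate to missing outputs; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

VIS_WEIGHTS: dict[str, float] = {
    "dopamine": 1.0,
    "dobutamine": 1.0,
    "epinephrine": 100.0,
    "milrinone": 10.0,
    "vasopressin": 10_000.0,
    "norepinephrine": 100.0,
}

#: default pump concentrations; ug/ml except vasopressin (U/ml).
#: Configurable: drug dilutions are institution-specific.
DEFAULT_CONCENTRATIONS: dict[str, float] = {
    "norepinephrine": 20.0,
    "epinephrine": 20.0,
    "dopamine": 3200.0,
    "dobutamine": 2000.0,
    "milrinone": 200.0,
    "vasopressin": 0.4,
}


def vis(doses: Mapping[str, float]) -> float:
    """Vasoactive-inotropic score of a weight-normalised dose vector.

    Unknown drugs are ignored; absent drugs count as zero; negative doses
    are rejected.
    """
    total = 0.0
    for drug, weight in VIS_WEIGHTS.items():
        dose = float(doses.get(drug, 0.0))
        if dose < 0:
            raise ValueError(f"negative dose for {drug}")
        total += weight * dose
    return total


@dataclass(frozen=True)
class DoseTrace:
    """Piecewise-constant weight-normalised dose over ``[start_ts, end_ts)``."""

    drug: str
    start_ts: pd.Timestamp
    end_ts: pd.Timestamp
    dose: float  # ug/kg/min (U/kg/min for vasopressin)

    def at(self, times) -> np.ndarray:
        t = pd.DatetimeIndex(times)
        return np.where((t >= self.start_ts) & (t < self.end_ts), self.dose, 0.0)

    def total_mass_ug(self, weight_kg: float) -> float:
        minutes = (self.end_ts - self.start_ts) / pd.Timedelta(minutes=1)
        return self.dose * weight_kg * minutes


def infusion_to_dose(record: Mapping, concentration: float, weight_kg: float) -> DoseTrace:
    """Convert a pump record (rate in ml/h) to a weight-normalised dose trace.

    dose [ug/kg/min] = rate [ml/h] * concentration [ug/ml] / 60 / weight [kg].
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    if concentration is None or not np.isfinite(concentration):
        raise ValueError(f"missing concentration for {record['substance']!r}")
    rate = record.get("rate_ml_h")
    if rate is None or (isinstance(rate, float) and np.isnan(rate)):
        minutes = (record["end_ts"] - record["start_ts"]) / pd.Timedelta(minutes=1)
        rate = record["volume_ml"] / minutes * 60.0
    dose = float(rate) * concentration / 60.0 / weight_kg
    return DoseTrace(record["substance"], record["start_ts"], record["end_ts"], dose)


def perfusion_pressure(map_mmhg, cvp_mmhg):
    return np.asarray(map_mmhg, dtype=float) - np.asarray(cvp_mmhg, dtype=float)


def svr(map_mmhg, cvp_mmhg, co_l_min):
    co = np.asarray(co_l_min, dtype=float)
    out = 80.0 * (np.asarray(map_mmhg, dtype=float) - np.asarray(cvp_mmhg, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = out / co
    return np.where(co > 0, out, np.nan)


def do2(co_l_min, hb_g_dl, sao2_pct, pao2_mmhg):
    co = np.asarray(co_l_min, dtype=float)
    content = 1.34 * np.asarray(hb_g_dl, dtype=float) * np.asarray(sao2_pct, dtype=float) / 100.0
    content = content + 0.0031 * np.asarray(pao2_mmhg, dtype=float)
    return 10.0 * co * content


def derived_panel(
    vitals_at_t: Mapping[str, float],
    labs_at_t: Mapping[str, float] | None = None,
    doses_at_t: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Point-in-time derived panel; missing inputs yield NaN outputs."""
    labs_at_t = labs_at_t or {}
    v = lambda m, k: float(m.get(k, np.nan))  # noqa: E731
    mapv, cvp, co = (v(vitals_at_t, k) for k in ("map", "cvp", "co"))
    return {
        "perfusion_pressure": float(perfusion_pressure(mapv, cvp)),
        "svr": float(svr(mapv, cvp, co)),
        "do2": float(do2(co, v(labs_at_t, "hb"), v(labs_at_t, "sao2"), v(labs_at_t, "pao2"))),
        "vis": vis(doses_at_t) if doses_at_t is not None else np.nan,
    }


def vis_trace(
    infusions: pd.DataFrame,
    patients: pd.DataFrame,
    grid_step_min: int = 2,
    concentrations: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """VIS at every grid time of every patient's stay (0 when no drips run).

    Returns a long observation frame (patient_id, ts, channel='vis', value).
    """
    conc = dict(DEFAULT_CONCENTRATIONS)
    if concentrations:
        conc.update(concentrations)
    drips = infusions[infusions["substance"].isin(VIS_WEIGHTS)]
    drips_by_patient = dict(tuple(drips.groupby("patient_id", sort=False)))
    pids, ts_parts, val_parts = [], [], []
    for patient in patients.itertuples(index=False):
        pid = patient.patient_id
        admit, discharge = patient.admit_ts, patient.discharge_ts
        n = int((discharge - admit) / pd.Timedelta(minutes=grid_step_min))
        offsets = np.arange(n) * grid_step_min
        total = np.zeros(n)
        recs = drips_by_patient.get(pid)
        if recs is not None:
            for rec in recs.itertuples(index=False):
                dose = infusion_to_dose(rec._asdict(), conc[rec.substance],
                                        patient.weight_kg).dose
                lo = (rec.start_ts - admit) / pd.Timedelta(minutes=1)
                hi = (rec.end_ts - admit) / pd.Timedelta(minutes=1)
                total[(offsets >= lo) & (offsets < hi)] += VIS_WEIGHTS[rec.substance] * dose
        pids.append(pid)
        ts_parts.append(admit.value + (offsets * 60e9).astype(np.int64))
        val_parts.append(np.round(total, 4))
    if not pids:
        return pd.DataFrame(columns=["patient_id", "ts", "channel", "value"])
    counts = [len(t) for t in ts_parts]
    return pd.DataFrame(
        {
            "patient_id": np.repeat(np.array(pids, dtype=object), counts),
            "ts": np.concatenate(ts_parts).view("M8[ns]"),
            "channel": "vis",
            "value": np.concatenate(val_parts),
        }
    )


DERIVED_CHANNELS = ("vis", "perfusion_pressure", "svr", "do2")


def augment_observations(
    vitals: pd.DataFrame,
    labs: pd.DataFrame,
    infusions: pd.DataFrame,
    patients: pd.DataFrame,
    grid_step_min: int = 2,
    concentrations: Mapping[str, float] | None = None,
    derived: tuple[str, ...] = DERIVED_CHANNELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add derived channels to the observation tables.

    Returns ``(vitals_out, labs_out)`` where ``vitals_out`` gains the grid
    channels ``vis``, ``perfusion_pressure`` and ``svr`` (at times where the
    inputs are observed) and ``labs_out`` gains ``do2`` rows at blood-gas
    times whose Hb/SaO2/PaO2 co-occur and a CO observation exists on the
    grid step containing the draw.  ``derived`` restricts which channels
    are computed.
    """
    derived_parts = []
    if "vis" in derived:
        derived_parts.append(vis_trace(infusions, patients, grid_step_min, concentrations))

    if "perfusion_pressure" in derived or "svr" in derived:
        wide = (
            vitals[vitals["channel"].isin(["map", "cvp", "co"])]
            .pivot_table(index=["patient_id", "ts"], columns="channel", values="value",
                         aggfunc="first", observed=True)
            .reset_index()
        )
        for col in ("map", "cvp", "co"):
            if col not in wide:
                wide[col] = np.nan
        if "perfusion_pressure" in derived:
            pp = wide.assign(channel="perfusion_pressure",
                             value=perfusion_pressure(wide["map"], wide["cvp"]))
            derived_parts.append(
                pp.loc[pp["value"].notna(), ["patient_id", "ts", "channel", "value"]]
            )
        if "svr" in derived:
            sv_ = wide.assign(channel="svr", value=svr(wide["map"], wide["cvp"], wide["co"]))
            derived_parts.append(
                sv_.loc[sv_["value"].notna(), ["patient_id", "ts", "channel", "value"]]
            )
    vitals_out = pd.concat([vitals] + derived_parts, ignore_index=True) \
        if derived_parts else vitals

    labs_out = labs
    abg = pd.DataFrame()
    if "do2" in derived:
        abg = (
            labs[labs["channel"].isin(["hb", "sao2", "pao2"])]
            .pivot_table(index=["patient_id", "ts"], columns="channel", values="value",
                         aggfunc="first", observed=True)
            .reset_index()
        )
    if len(abg) and {"hb", "sao2", "pao2"}.issubset(abg.columns):
        co_obs = vitals[vitals["channel"] == "co"][["patient_id", "ts", "value"]].copy()
        co_obs["patient_id"] = np.asarray(co_obs["patient_id"], dtype=object)
        co_obs = co_obs.rename(columns={"ts": "co_ts", "value": "co"}).sort_values("co_ts")
        abg = abg.sort_values("ts")
        merged = pd.merge_asof(
            abg, co_obs, left_on="ts", right_on="co_ts", by="patient_id",
            direction="backward", tolerance=pd.Timedelta(minutes=grid_step_min),
        )
        merged["value"] = do2(merged["co"], merged["hb"], merged["sao2"], merged["pao2"])
        do2_rows = merged.loc[merged["value"].notna(),
                              ["patient_id", "ts", "value"]].assign(channel="do2")
        labs_out = pd.concat(
            [labs, do2_rows[["patient_id", "ts", "channel", "value"]]], ignore_index=True
        )
    return vitals_out, labs_out
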