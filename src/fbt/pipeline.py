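"""End-to-end orchestration: simulate -> extract -> derive -> match -> analyze.

All randomness flows from one root seed through named per-stage substreams,
so a run is reproducible from its manifest.  The episode funnel (detected,
isolated, in-stay, controls, matched) is logged and recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fbt import analyze, derive, episodes as ep_mod, match as match_mod, synth

log = logging.getLogger(__name__)

CONTINUOUS_VARIABLES = (
    "co", "sv", "hr", "map", "sbp", "dbp", "cvp", "papm", "spo2",
    "vis", "perfusion_pressure", "svr",
)
SPORADIC_VARIABLES = ("hb", "lactate", "ph", "be", "svo2", "sao2", "pao2", "pcwp", "do2")
RESPONDER_VARIABLES = ("co", "sv", "map", "vis")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and the funnel so far."""

    def __init__(self, stage: str, message: str, funnel: dict | None = None):
        super().__init__(f"{stage}: {message} (funnel so far: {funnel})")
        self.stage = stage
        self.funnel = funnel or {}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    input_dir: str | None = None  # read a written cohort instead of simulating
    synth: synth.CohortConfig = field(default_factory=synth.CohortConfig)
    write_cohort: bool = False
    gap_tolerance_min: float = 2.0
    n_controls_per_bolus: int = 2
    max_maintenance_rate_ml_h: float = 50.0
    min_baseline_samples: int = 3
    caliper_sd: float = 0.2
    responder_threshold: float = 0.10
    responder_rule: str = "max_bin"
    m_tests: int = 31
    variables_continuous: tuple[str, ...] = CONTINUOUS_VARIABLES
    variables_sporadic: tuple[str, ...] = SPORADIC_VARIABLES
    responder_variables: tuple[str, ...] = RESPONDER_VARIABLES
    size_rate_outcomes: tuple[str, ...] = ("map", "co", "sv")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["channel_params"] = {
            k: dataclasses.asdict(v) for k, v in self.synth.channel_params.items()
        }
        d["synth"]["lab_params"] = {
            k: dataclasses.asdict(v) for k, v in self.synth.lab_params.items()
        }
        d["synth"]["effect_kernels"] = [
            dataclasses.asdict(k) for k in self.synth.effect_kernels
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        s = dict(d.pop("synth", {}))
        if s:
            if "channel_params" in s:
                s["channel_params"] = {
                    k: synth.ChannelParams(**v) for k, v in s["channel_params"].items()
                }
            if "lab_params" in s:
                s["lab_params"] = {
                    k: synth.LabParams(**v) for k, v in s["lab_params"].items()
                }
            if "effect_kernels" in s:
                s["effect_kernels"] = tuple(
                    synth.EffectKernel(**k) for k in s["effect_kernels"]
                )
            if "bolus_duration_range_min" in s:
                s["bolus_duration_range_min"] = tuple(s["bolus_duration_range_min"])
            d["synth"] = synth.CohortConfig(**s)
        for key in ("variables_continuous", "variables_sporadic",
                    "responder_variables", "size_rate_outcomes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: synth.SyntheticCohort
    episodes: pd.DataFrame
    baselines: pd.DataFrame
    pairs: pd.DataFrame
    balance: match_mod.BalanceReport
    binned: pd.DataFrame
    lmm_results: pd.DataFrame
    responders: pd.DataFrame
    size_rate: list
    funnel: dict
    alpha: float
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    funnel: dict = {}
    cfg = config

    # -- simulate / load -----------------------------------------------------
    if cfg.input_dir is not None:
        cohort = synth.read_cohort(cfg.input_dir)
    else:
        sim_cfg = dataclasses.replace(cfg.synth, seed=stage_seed(cfg.seed, "simulate"))
        cohort = synth.generate_cohort(sim_cfg)
    funnel["patients"] = len(cohort.patients)

    # -- extract -------------------------------------------------------------
    episodes, ext_funnel = ep_mod.extract_episodes(
        cohort.infusions,
        cohort.patients,
        gap_tolerance_min=cfg.gap_tolerance_min,
        n_controls_per_bolus=cfg.n_controls_per_bolus,
        max_maintenance_rate_ml_h=cfg.max_maintenance_rate_ml_h,
        grid_step_min=cfg.synth.grid_step_min,
        seed=stage_seed(cfg.seed, "controls"),
    )
    funnel.update(ext_funnel)
    log.info("episode funnel: %s", funnel)
    if len(episodes) == 0 or (episodes["kind"] == "bolus").sum() == 0:
        raise PipelineError("extract", "no episodes", funnel)

    # -- derive --------------------------------------------------------------
    # VIS is always needed (baseline covariate); the other derived channels
    # only when analysed
    needed = ("vis",) + tuple(
        ch for ch in ("perfusion_pressure", "svr")
        if ch in cfg.variables_continuous
    ) + tuple(ch for ch in ("do2",) if ch in cfg.variables_sporadic)
    if needed == ("vis",):
        # keep the big grid table and the VIS trace as separate frames;
        # the episode summaries group them jointly
        vis_rows = derive.vis_trace(
            cohort.infusions, cohort.patients, cfg.synth.grid_step_min
        )
        vitals_aug: object = [cohort.vitals, vis_rows]
        labs_aug = cohort.labs
    else:
        vitals_aug, labs_aug = derive.augment_observations(
            cohort.vitals, cohort.labs, cohort.infusions, cohort.patients,
            grid_step_min=cfg.synth.grid_step_min, derived=needed,
        )

    # -- match ---------------------------------------------------------------
    baselines = match_mod.compute_baselines(
        episodes, vitals_aug, cohort.patients, min_samples=cfg.min_baseline_samples
    )
    if baselines.empty:
        raise PipelineError("match", "no episodes with usable baselines", funnel)
    scored = match_mod.estimate_propensity(baselines)
    try:
        mres = match_mod.match_pairs(
            scored, caliper_sd=cfg.caliper_sd, seed=stage_seed(cfg.seed, "match")
        )
    except ValueError as exc:
        raise PipelineError("match", str(exc), funnel) from exc
    pairs = mres.pairs
    funnel["matched_pairs"] = len(pairs)
    balance = match_mod.balance(baselines, pairs)

    # -- analyze -------------------------------------------------------------
    matched_ids = np.concatenate(
        [pairs["bolus_episode_id"].to_numpy(), pairs["control_episode_id"].to_numpy()]
    )
    matched_eps = episodes[episodes["episode_id"].isin(matched_ids)]
    binned_cont = analyze.bin_trajectories(
        vitals_aug, matched_eps, cfg.variables_continuous
    )
    binned_spor = analyze.bin_trajectories(
        labs_aug, matched_eps, cfg.variables_sporadic,
        bin_width_min=60.0, n_bins=1, baseline_min=60.0,
    )
    alpha = analyze.bonferroni_alpha(cfg.m_tests)

    lmm_rows = []
    for var in cfg.variables_continuous:
        try:
            lmm_rows.append(analyze.fit_lmm(binned_cont, var).to_row())
        except ValueError as exc:
            log.warning("LMM skipped: %s", exc)
    for var in cfg.variables_sporadic:
        try:
            lmm_rows.append(
                analyze.fit_lmm(binned_spor, var, include_time=False).to_row()
            )
        except ValueError as exc:
            log.warning("LMM skipped: %s", exc)
    lmm_results = pd.DataFrame(lmm_rows)

    resp_rows = []
    for var in cfg.responder_variables:
        try:
            resp_rows.append(
                analyze.classify_responders(
                    binned_cont, var, cfg.responder_threshold, cfg.responder_rule
                ).to_row()
            )
        except ValueError as exc:
            log.warning("responder table skipped: %s", exc)
    responders = pd.DataFrame(resp_rows)

    size_rate = analyze.fit_size_rate_models(
        binned_cont, baselines, matched_eps, outcomes=cfg.size_rate_outcomes
    )

    result = PipelineResult(
        config=cfg, cohort=cohort, episodes=episodes, baselines=baselines,
        pairs=pairs, balance=balance,
        binned=pd.concat(
            [b for b in (binned_cont, binned_spor) if len(b)] or [binned_cont],
            ignore_index=True,
        ),
        lmm_results=lmm_results, responders=responders, size_rate=size_rate,
        funnel=funnel, alpha=alpha,
    )
    if cfg.out_dir is not None:
        write_outputs(result, cfg.out_dir)
    return result


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: PipelineResult, out_dir) -> dict:
    """Write all artifact tables plus a manifest with content hashes."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    files: dict[str, pd.DataFrame] = {
        "episodes.csv": result.episodes,
        "baselines.csv": result.baselines,
        "pairs.csv": result.pairs,
        "balance_report.csv": result.balance.table,
        "binned_trajectories.csv": result.binned,
        "lmm_results.csv": result.lmm_results,
        "responders.csv": result.responders,
        "size_rate_models.csv": pd.concat(
            [m.table.assign(outcome=m.outcome, n=m.n) for m in result.size_rate],
            ignore_index=True,
        ) if result.size_rate else pd.DataFrame(),
        "bin_summary.csv": analyze.bin_summary(
            result.binned[result.binned["episode_id"].isin(
                np.concatenate([result.pairs["bolus_episode_id"].to_numpy(),
                                result.pairs["control_episode_id"].to_numpy()])
            )]
        ),
    }
    for name, df in files.items():
        df.to_csv(out / name, index=False, date_format="%Y-%m-%dT%H:%M:%S")
    if cfg.write_cohort:
        synth.write_cohort(result.cohort, out / "cohort")

    config_dict = cfg.to_dict()
    hashable = {k: v for k, v in config_dict.items() if k not in ("out_dir", "input_dir")}
    manifest = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(hashable, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s) for s in ("simulate", "controls", "match")
        },
        "funnel": result.funnel,
        "alpha_bonferroni": result.alpha,
        "n_rows": {name: int(len(df)) for name, df in files.items()},
        "files": {name: _sha256(out / name) for name in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    result.manifest = manifest
    return manifest
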