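"""End-to-end pipeline: recalls -> intakes -> adequacy -> ratios -> inference.

The pipeline consumes either CSV input tables or a simulation
specification, runs the analysis stages in order and writes one CSV per
stage plus a run log.  Runs are deterministic given a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .adequacy import (
    default_energy_config,
    default_iron_table,
    default_requirements,
    energy_ear,
    mpa,
    probability_of_adequacy,
)
from .allocation import PAIRS, household_ratios, ratios_frame
from .inference import fit_determinants, test_equity
from .nutrients import MICRONUTRIENTS, build_profiles
from .records import ROLES, validate_tables
from .simulate import SimulationConfig, simulate_study
from .usual import estimate_usual_intakes

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger("thaali")


class PipelineError(RuntimeError):
    """A stage failure, with the stage name attached."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration (YAML-serialisable).

    Exactly one of ``inputs`` (paths to households/members/recalls/fct
    CSVs) or ``simulation`` (keyword arguments for
    :class:`~thaali.simulate.SimulationConfig`) must be provided.
    """

    inputs: dict | None = None
    simulation: dict | None = None
    seed: int = 0
    out_dir: str | None = None
    requirements_csv: str | None = None
    energy_csv: str | None = None
    iron_table_csv: str | None = None
    symmetric_outlier_exclusion: bool = False
    exclude_proxy_visits: bool = False
    determinant_pairs: tuple = ("PW:HH", "PW:MIL")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError(
                "config must provide exactly one of 'inputs' or 'simulation'"
            )


@dataclass
class PipelineResult:
    intakes: pd.DataFrame
    adequacy: pd.DataFrame
    ratios: pd.DataFrame
    equity: pd.DataFrame
    determinants: pd.DataFrame
    ground_truth: object | None = None
    out_dir: Path | None = None


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:  # attach the stage name
                raise PipelineError(name, err) from err

        return wrapped

    return deco


@_stage("load")
def _load(config: PipelineConfig):
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        households, members, fct, visits, truth = simulate_study(sim)
        return households, members, fct, visits, truth
    paths = dict(config.inputs)
    if "fct" not in paths:
        raise ValueError("inputs must include an 'fct' path")
    households, members, visits = tio.read_tables(paths)
    fct = tio.read_fct(paths["fct"])
    return households, members, fct, visits, None


@_stage("requirements")
def _requirements(config: PipelineConfig):
    if config.requirements_csv:
        from .adequacy import RequirementDistribution

        df = pd.read_csv(config.requirements_csv, comment="#")
        reqs = [
            RequirementDistribution(
                r.nutrient, r.role, r.kind,
                None if pd.isna(r.ear_mean) else float(r.ear_mean),
                None if pd.isna(r.ear_sd) else float(r.ear_sd),
                getattr(r, "source", ""),
            )
            for r in df.itertuples(index=False)
        ]
    else:
        reqs = default_requirements()
    if not reqs:
        raise ValueError("requirement table is empty")
    energy_cfg = default_energy_config()
    if config.energy_csv:
        from .adequacy import EnergyRequirementConfig

        df = pd.read_csv(config.energy_csv, comment="#")
        energy_cfg = EnergyRequirementConfig(
            kcal_per_kg={
                (r.sex, r.activity_level): float(r.kcal_per_kg)
                for r in df.itertuples(index=False)
            }
        )
    if config.iron_table_csv:
        from .adequacy import IronProbabilityTable

        df = pd.read_csv(config.iron_table_csv, comment="#")
        iron = IronProbabilityTable(
            df["upper_bound_mg"].to_numpy(), df["probability"].to_numpy()
        )
    else:
        iron = default_iron_table()
    return reqs, energy_cfg, iron


@_stage("nutrients")
def _intakes(visits, fct, exclude_proxy: bool):
    if exclude_proxy:
        visits = [v for v in visits if not v.proxy_respondent]
    profiles = build_profiles(visits, fct)
    rows = []
    for mid, p in profiles.items():
        row = {"member_id": mid, **p.mean_nutrients.to_dict()}
        for g, v in p.group_grams.items():
            row[f"grams_{g}"] = v
        for g, v in p.consumed_any.items():
            row[f"any_{g}"] = bool(v)
        row["mddw_score"] = p.mddw_score
        row["mddw_adequate"] = p.mddw_adequate
        rows.append(row)
    intakes = pd.DataFrame(rows).set_index("member_id").sort_index()
    return profiles, intakes


@_stage("usual_intake")
def _usual(profiles, members, households):
    hh_by_id = {h.household_id: h for h in households}
    meta = pd.DataFrame(
        {
            "member_id": [m.member_id for m in members],
            "role": [m.role for m in members],
            "cluster_id": [hh_by_id[m.household_id].cluster_id for m in members],
            "stratum": [hh_by_id[m.household_id].stratum for m in members],
        }
    ).set_index("member_id")
    usual_rows = {}
    models = {}
    for role in ROLES:
        mids = meta.index[meta["role"] == role]
        for nutrient in MICRONUTRIENTS:
            recs = []
            for mid in mids:
                if mid not in profiles:
                    continue
                for _, vec in profiles[mid].visit_nutrients.iterrows():
                    recs.append(
                        {
                            "member_id": mid,
                            "cluster_id": meta.loc[mid, "cluster_id"],
                            "stratum": meta.loc[mid, "stratum"],
                            "value": float(vec[nutrient]),
                        }
                    )
            raw = pd.DataFrame(recs)
            model, usual = estimate_usual_intakes(raw, nutrient=nutrient, role=role)
            models[(nutrient, role)] = model
            for mid, val in usual.items():
                usual_rows.setdefault(mid, {})[nutrient] = val
    usual_df = pd.DataFrame.from_dict(usual_rows, orient="index").sort_index()
    usual_df.index.name = "member_id"
    return models, usual_df, meta


@_stage("adequacy")
def _adequacy(usual_df, meta, reqs, iron_table):
    req_map = {(r.nutrient, r.role): r for r in reqs}
    rows = []
    for mid, usual in usual_df.iterrows():
        role = meta.loc[mid, "role"]
        pa_map = {}
        for nutrient in MICRONUTRIENTS:
            dist = req_map.get((nutrient, role))
            if dist is None:
                raise ValueError(f"no requirement for {nutrient}/{role}")
            pa_map[nutrient] = probability_of_adequacy(
                float(usual[nutrient]), dist, iron_table
            )
        rows.append(
            {"member_id": mid, **{f"pa_{n}": v for n, v in pa_map.items()},
             "mpa": mpa(pa_map)}
        )
    return pd.DataFrame(rows).set_index("member_id").sort_index()


@_stage("allocation")
def _allocation(households, members, intakes, adequacy_df, energy_cfg,
                symmetric_exclusion: bool):
    grams_cols = [c for c in intakes.columns if c.startswith("grams_")]
    group_grams = intakes[grams_cols].rename(
        columns=lambda c: c.removeprefix("grams_")
    )
    energy = intakes["energy_kcal"]
    ears = pd.Series(
        {m.member_id: energy_ear(m, energy_cfg) for m in members}, name="energy_ear"
    )
    mpas = adequacy_df["mpa"]
    scores = intakes["mddw_score"]
    members_by_hh: dict[str, dict[str, str]] = {}
    for m in members:
        members_by_hh.setdefault(m.household_id, {})[m.role] = m.member_id
    all_ratios = []
    for h in households:
        all_ratios.extend(
            household_ratios(
                h.household_id,
                members_by_hh[h.household_id],
                group_grams,
                energy,
                ears,
                mpas=mpas,
                mddw_scores=scores,
            )
        )
    df = ratios_frame(all_ratios)
    if symmetric_exclusion:
        df["excluded_mpa_outlier"] = df["excluded_mpa_outlier"] | (
            df["log_mpa_ratio"].abs() > 8.0
        )
    cluster_of_hh = {h.household_id: h.cluster_id for h in households}
    df["cluster_id"] = df["household_id"].map(cluster_of_hh)
    return df, ears


_EQUITY_OUTCOMES = ["log_rdear", "log_mpa_ratio", "log_dd_ratio", "log_dd_ratio_adj"]


@_stage("equity")
def _equity(ratios: pd.DataFrame):
    results = []
    fs_cols = [c for c in ratios.columns if c.startswith("log_fs_")]
    for pair in PAIRS:
        sub = ratios[ratios["pair"] == pair]
        for outcome in _EQUITY_OUTCOMES + fs_cols:
            vals = sub[outcome]
            if outcome == "log_mpa_ratio":
                vals = vals.where(~sub["excluded_mpa_outlier"])
            if vals.notna().sum() < 3:
                continue
            r = test_equity(vals, sub["cluster_id"], pair=pair, outcome=outcome)
            results.append(
                {
                    "pair": pair,
                    "outcome": outcome,
                    "n": r.n,
                    "estimate": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(results)


@_stage("determinants")
def _determinants(ratios: pd.DataFrame, households, intakes, members,
                  pairs) -> pd.DataFrame:
    hh_df = pd.DataFrame(
        {
            "household_id": [h.household_id for h in households],
            "earnings_parity": [h.earnings_parity for h in households],
            "gravidity": [h.gravidity for h in households],
            "empowerment": [h.empowerment for h in households],
            "asset_score": [h.asset_score for h in households],
            "husband_overseas": [h.husband_overseas for h in households],
            "caste_group": [h.caste_group for h in households],
            "season": [h.season for h in households],
        }
    ).set_index("household_id")
    hh_of_member = pd.Series({m.member_id: m.household_id for m in members})
    hh_kcal = (
        intakes["energy_kcal"].groupby(hh_of_member.reindex(intakes.index)).mean()
        / 1000.0
    )
    hh_df["hh_kcal_per_1000"] = hh_kcal

    out_rows = []
    for pair in pairs:
        sub = ratios[ratios["pair"] == pair].set_index("household_id")
        for outcome in ("log_rdear", "log_mpa_ratio"):
            vals = sub[outcome]
            if outcome == "log_mpa_ratio":
                vals = vals.where(~sub["excluded_mpa_outlier"])
            cov = hh_df.loc[vals.index]
            model = fit_determinants(
                vals.to_numpy(),
                cov,
                sub["cluster_id"].to_numpy(),
                pair=pair,
                outcome=outcome,
            )
            for term, row in model.table.iterrows():
                out_rows.append(
                    {
                        "pair": pair,
                        "outcome": outcome,
                        "term": term,
                        "estimate": row["estimate"],
                        "ci_low": row["ci_low"],
                        "ci_high": row["ci_high"],
                        "p_value": row["p_value"],
                        "vif": model.vifs.get(term, np.nan),
                        "n": model.n,
                    }
                )
    return pd.DataFrame(out_rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages; optionally write per-stage CSVs and a run log."""
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    handler = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    try:
        log.info("seed %d", config.seed)
        households, members, fct, visits, truth = _load(config)
        validate_tables(households, members, visits)
        reqs, energy_cfg, iron = _requirements(config)
        profiles, intakes = _intakes(visits, fct, config.exclude_proxy_visits)
        models, usual_df, meta = _usual(profiles, members, households)
        adequacy_df = _adequacy(usual_df, meta, reqs, iron)
        ratios, ears = _allocation(
            households, members, intakes, adequacy_df, energy_cfg,
            config.symmetric_outlier_exclusion,
        )
        equity = _equity(ratios)
        determinants = _determinants(
            ratios, households, intakes, members, config.determinant_pairs
        )
        result = PipelineResult(
            intakes, adequacy_df, ratios, equity, determinants, truth, out_dir
        )
        if out_dir is not None:
            intakes.to_csv(out_dir / "intakes.csv")
            adequacy_df.to_csv(out_dir / "adequacy.csv")
            ratios.to_csv(out_dir / "ratios.csv", index=False)
            equity.to_csv(out_dir / "equity.csv", index=False)
            determinants.to_csv(out_dir / "determinants.csv", index=False)
            if truth is not None:
                truth.members.to_csv(out_dir / "truth_members.csv")
                truth.households.to_csv(out_dir / "truth_households.csv")
                with open(out_dir / "config_echo.yaml", "w") as f:
                    yaml.safe_dump(
                        {
                            "simulation": config.simulation,
                            "seed": config.seed,
                        },
                        f,
                    )
            tio.write_tables(households, members, visits, out_dir / "inputs")
            tio.write_fct(fct, out_dir / "inputs" / "fct.csv")
            log.info(
                "done: %d households, %d members, %d visits",
                len(households), len(members), len(visits),
            )
        return result
    finally:
        if handler is not None:
            log.removeHandler(handler)
            handler.close()
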