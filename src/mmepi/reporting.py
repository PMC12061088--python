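"""Study-shaped outputs: cohort descriptions, algorithm comparison, pipeline.

`run_pipeline` chains simulation → identification (MYLORD and the PALMARO
variants) → follow-up → yearly indicators, writing machine-readable CSV
tables, a JSON run log (seed, config hash, code-list hash, package
version) and trend figures.  Every number in the rendered outputs is
re-derivable from the tables; figures only plot table columns.
Percentages are rounded to two decimals in summaries, full precision is
kept in the tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .claims import ClaimsDataset, write_dataset
from .codes import CodeListConfig, icd10_mask
from .cohort import AlgorithmConfig, identify_mylord, identify_palmaro
from .followup import FollowupConfig, build_followup
from .indicators import StandardPopulation, build_denominators, build_rate_table, segi_world
from .simulate import SimulationConfig, simulate

__all__ = ["RunConfig", "describe_cohort", "compare_algorithms", "run_pipeline"]


def describe_cohort(cohort: pd.DataFrame, ds: ClaimsDataset, codelists: CodeListConfig | None = None) -> dict:
    """Inclusion characteristics: n, age at first MM information
    (mean/SD/median/quartiles), sex split, first-information kinds, and the
    share of members with an LTD registration for MM."""
    codelists = codelists or CodeListConfig()
    if len(cohort) == 0:
        import warnings

        warnings.warn("describe_cohort: empty cohort", RuntimeWarning, stacklevel=2)
        return {"n": 0}
    p = ds.persons.set_index("person_id")
    ages = cohort["first_mm_information_date"].dt.year.to_numpy() - p["birth_year"].reindex(
        cohort["person_id"]
    ).to_numpy()
    sexes = p["sex"].reindex(cohort["person_id"])
    n = len(cohort)
    sex_counts = sexes.value_counts().to_dict()
    kind_counts = cohort["first_mm_information_kind"].value_counts().to_dict()
    ltd = ds.ltd_records
    ltd_ids = (
        set(ltd.loc[icd10_mask(ltd["icd10_code"], codelists.mm_icd10), "person_id"]) if len(ltd) else set()
    )
    n_ltd = int(cohort["person_id"].isin(ltd_ids).sum())
    return {
        "n": n,
        "age_mean": float(np.mean(ages)),
        "age_sd": float(np.std(ages, ddof=1)) if n > 1 else 0.0,
        "age_median": float(np.median(ages)),
        "age_q1": float(np.quantile(ages, 0.25)),
        "age_q3": float(np.quantile(ages, 0.75)),
        "sex_counts": {k: int(v) for k, v in sex_counts.items()},
        "sex_pct": {k: round(100.0 * v / n, 2) for k, v in sex_counts.items()},
        "first_information_counts": {k: int(v) for k, v in kind_counts.items()},
        "first_information_pct": {k: round(100.0 * v / n, 2) for k, v in kind_counts.items()},
        "ltd_registered_n": n_ltd,
        "ltd_registered_pct": round(100.0 * n_ltd / n, 2),
    }


def compare_algorithms(
    ds: ClaimsDataset,
    codelists: CodeListConfig | None = None,
    mylord_config: AlgorithmConfig | None = None,
    palmaro_config: AlgorithmConfig | None = None,
) -> dict:
    """Head-to-head cohort sizes and set relations between MYLORD and the
    PALMARO variants on one dataset."""
    codelists = codelists or CodeListConfig()
    my = identify_mylord(ds, mylord_config, codelists)
    pa = identify_palmaro(ds, "base", palmaro_config, codelists)
    pt = identify_palmaro(ds, "treated_only", None if palmaro_config is None else palmaro_config, codelists)
    sm, sp, st = set(my["person_id"]), set(pa["person_id"]), set(pt["person_id"])
    oral = my[my["criterion"] == "oral_imid_monitored"]
    return {
        "n_mylord": len(sm),
        "n_palmaro": len(sp),
        "n_palmaro_treated": len(st),
        "n_mylord_minus_palmaro_treated": len(sm - st),
        "n_palmaro_treated_minus_mylord": len(st - sm),
        "n_overlap_mylord_palmaro_treated": len(sm & st),
        "n_mylord_oral_arm": len(oral),
        "oral_arm_pct_of_mylord": round(100.0 * len(oral) / len(sm), 2) if sm else 0.0,
    }


class RunConfig(BaseModel):
    """End-to-end pipeline configuration."""

    out_dir: str
    seed: int = 0
    n_persons: int = Field(default=20_000, gt=0)
    simulation: Optional[dict] = None  # extra SimulationConfig overrides
    codelists: Optional[dict] = None
    algorithms: list[str] = ["mylord", "palmaro", "palmaro_treated"]
    make_figures: bool = True
    ci_method: str = "gamma"

    def simulation_config(self) -> SimulationConfig:
        kw = dict(self.simulation or {})
        kw.setdefault("n_persons", self.n_persons)
        kw.setdefault("seed", self.seed)
        return SimulationConfig(**kw)


_ALGOS = {
    "mylord": ("mylord", None),
    "palmaro": ("palmaro", "base"),
    "palmaro_from_2006": ("palmaro", "from_2006"),
    "palmaro_treated": ("palmaro", "treated_only"),
}


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, identify, follow up and tabulate; returns output paths.

    Deterministic: the same configuration (seed included) produces
    byte-identical tables.
    """
    unknown = [a for a in config.algorithms if a not in _ALGOS]
    if unknown:
        raise ValueError(f"unknown algorithms {unknown}; expected {sorted(_ALGOS)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cl = CodeListConfig(**(config.codelists or {}))
    sim_cfg = config.simulation_config()
    fu_cfg = FollowupConfig()
    standard = segi_world()

    ds, truth = simulate(sim_cfg, cl)
    write_dataset(ds, out / "dataset")
    t = truth.copy()
    for c in ("onset_date", "death_date"):
        t[c] = t[c].dt.strftime("%Y-%m-%d")
    t.to_csv(out / "truth.csv", index=False)

    years = list(range(fu_cfg.study_start.year, fu_cfg.study_end.year + 1))
    denominators = build_denominators(ds, years, standard)
    denominators.to_csv(out / "denominators.csv", index=False, float_format="%.10g")

    outputs = {"dataset": str(out / "dataset"), "truth": str(out / "truth.csv")}
    summaries = {}
    for name in config.algorithms:
        algo, variant = _ALGOS[name]
        if algo == "mylord":
            cohort = identify_mylord(ds, None, cl)
            include_treat = True
        else:
            cohort = identify_palmaro(ds, variant, None, cl)
            include_treat = variant == "treated_only"
        fu = build_followup(ds, cohort, cl, None, fu_cfg, include_treatment_in_information=include_treat)
        rates = build_rate_table(fu, ds, denominators, standard, years, ci_method=config.ci_method)

        cpath = out / f"cohort_{name}.csv"
        c = cohort.copy()
        for col in ("first_mm_information_date", "first_stay_date", "first_ltd_date",
                    "first_treatment_date", "oral_qualifying_date"):
            c[col] = pd.to_datetime(c[col]).dt.strftime("%Y-%m-%d")
        c.to_csv(cpath, index=False)
        fpath = out / f"followup_{name}.csv"
        f = fu.copy()
        for col in ("index_date", "followup_start", "followup_end"):
            f[col] = pd.to_datetime(f[col]).dt.strftime("%Y-%m-%d")
        f.to_csv(fpath, index=False)
        rpath = out / f"rates_{name}.csv"
        rates.to_csv(rpath, index=False, float_format="%.10g")
        outputs[f"cohort_{name}"] = str(cpath)
        outputs[f"followup_{name}"] = str(fpath)
        outputs[f"rates_{name}"] = str(rpath)
        summaries[name] = describe_cohort(cohort, ds, cl) if len(cohort) else {"n": 0}

        if config.make_figures:
            _trend_figures(rates, out, name)

    comparison = compare_algorithms(ds, cl)
    (out / "comparison.json").write_text(json.dumps(comparison, indent=2, sort_keys=True) + "\n")
    (out / "cohort_summaries.json").write_text(json.dumps(summaries, indent=2, sort_keys=True) + "\n")

    log = {
        "package_version": __version__,
        "seed": config.seed,
        # hash of the scientific configuration only (output location excluded)
        "config_hash": _config_hash(config.model_dump(exclude={"out_dir"})),
        "codelist_hash": _config_hash(cl.model_dump()),
        "simulation_config": sim_cfg.model_dump(mode="json"),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
    outputs["comparison"] = str(out / "comparison.json")
    outputs["run_log"] = str(out / "run_log.json")
    return outputs


def _trend_figures(rates: pd.DataFrame, out: Path, name: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "mmepi"
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for measure, ax in (("incidence", axes[0]), ("prevalence", axes[1])):
        sub = rates[(rates["measure"] == measure) & (rates["sex"] == "all")]
        ax.plot(sub["year"], sub["count"], marker="o", color="#30505f")
        ax.set_title(f"{measure} — patients per year")
        ax.set_xlabel("year")
        ax.set_ylabel("patients")
    fig.tight_layout()
    fig.savefig(out / f"counts_{name}.svg", metadata={"Date": None})
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for measure, ax in (("incidence", axes[0]), ("prevalence", axes[1])):
        for sexsel, color in (("male", "#355f8d"), ("female", "#a84d57")):
            sub = rates[(rates["measure"] == measure) & (rates["sex"] == sexsel)]
            ax.plot(sub["year"], sub["asr"], marker="o", label=sexsel, color=color)
            ax.fill_between(sub["year"], sub["asr_ci_low"], sub["asr_ci_high"], alpha=0.2, color=color)
        ax.set_title(f"world age-standardized {measure} rate")
        ax.set_xlabel("year")
        ax.set_ylabel("per 100,000")
        ax.legend()
    fig.tight_layout()
    fig.savefig(out / f"asr_{name}.svg", metadata={"Date": None})
    plt.close(fig)
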