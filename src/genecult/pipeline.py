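"""One-command orchestration of the full analysis chain.

Runs, in order: hierarchical AMOVA and within-group F_ST on the population
table; subdivision t-tests; frequency-based allele ages; optionally an LD
age, an outlier scan and a settlement-model neutrality fit on synthetic or
user matrices; and the pollen-date correlation.  Stages are isolated by
default — a failing stage is recorded with its error and later independent
stages still run — and every stochastic stage derives its RNG stream from
the single global seed, so a report is reproducible from its logged seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .allele_age import DemographyParams, kimura_ohta_age
from .coalescent import (
    IslandModelConfig,
    SettlementDemography,
    simulate_settlement_region,
    summarize_loci,
)
from .fstats import amova, within_group_fst
from .geneculture import frequency_vs_age_report, read_pollen_table, subdivision_t_test
from .neutral_fit import neutrality_fit
from .outlier import build_null, outlier_scan
from .popdata import (
    read_population_table,
    subdivision_mean_frequency,
    total_sample_size,
)
from .synthetic_data import fixtures

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: Operation producing each report section (schema documentation).
PRODUCING_OPERATIONS = {
    "amova": "fstats.amova / fstats.within_group_fst",
    "t_tests": "geneculture.subdivision_t_test",
    "kimura_ohta": "popdata.subdivision_mean_frequency + allele_age.kimura_ohta_age",
    "outlier": "outlier.build_null + outlier.outlier_scan",
    "neutral_fit": "coalescent.simulate_settlement_region + neutral_fit.neutrality_fit",
    "correlation": "geneculture.frequency_vs_age_report",
}


@dataclass
class AnalysisConfig:
    """Inputs, toggles and per-stage parameters of a full run."""

    population_table: str | None = None  # None -> packaged fixture
    pollen_table: str | None = None
    stages: tuple[str, ...] = ("amova", "t_tests", "kimura_ohta", "correlation")
    n_permutations: int = 10_000
    demography: DemographyParams = field(default_factory=DemographyParams)
    outlier_sims: int = 2_000
    outlier_target_fst: float = 0.05
    neutral_sims: int = 500
    seed: int = 0
    output_dir: str | None = None
    fail_fast: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        demo = raw.pop("demography", None)
        cfg = cls(**raw)
        if demo:
            cfg.demography = DemographyParams(**demo)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, Mapping):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute every enabled stage and return the consolidated report."""
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in config.stages}
    fx = fixtures()
    table = (
        read_population_table(config.population_table)
        if config.population_table
        else fx.table1
    )
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "producing_operations": {s: PRODUCING_OPERATIONS[s] for s in config.stages},
        "stages": {},
    }

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            result = fn()
            report["stages"][name] = {"status": "ok", "result": _jsonable(result)}
        except Exception as exc:  # noqa: BLE001 - stage isolation contract
            logger.exception("stage %s failed", name)
            report["stages"][name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            if config.fail_fast:
                raise

    def stage_amova():
        res = amova(table, n_permutations=config.n_permutations, seed=stage_seeds["amova"])
        out = {
            "fct": res.fct, "fsc": res.fsc, "fst": res.fst,
            "p_fct": res.p_fct, "p_fsc": res.p_fsc, "p_fst": res.p_fst,
            "percent_variance": res.percent_variance,
            "n_permutations": res.n_permutations,
            "within_group_fst": {},
        }
        for sub in table.subdivisions():
            if len(table.subset(sub)) >= 2:
                f, p = within_group_fst(
                    table, sub, n_permutations=config.n_permutations, seed=stage_seeds["amova"]
                )
                out["within_group_fst"][sub] = {"fst": f, "p": p}
        return out

    def stage_ttests():
        subs = table.subdivisions()
        out = {}
        for i, a in enumerate(subs):
            for b in subs[i + 1 :]:
                out[f"{a}_vs_{b}"] = subdivision_t_test(table, a, b)
        return out

    def stage_kimura():
        out = {}
        for label, pops in {
            "all_populations": None,
            "mesoamerican_agriculturalist": "mesoamerican_agriculturalist",
        }.items():
            if pops is None:
                import statistics

                from .popdata import allele_frequency

                p = statistics.mean(allele_frequency(r).p_alt for r in table)
            else:
                p = subdivision_mean_frequency(table, pops)
            est = kimura_ohta_age(p, config.demography)
            out[label] = {
                "p": p,
                "age_2N_units": est.age_2N_units,
                "age_generations": est.age_generations,
                "age_years": est.age_years,
            }
        out["total_n"] = total_sample_size(table)
        return out

    def stage_outlier():
        from .synthetic_data import DriftScenario, simulate_drift_locus_set

        cfg = IslandModelConfig(
            n_demes=100,
            n_groups=1,
            deme_size=50,
            target_fst=config.outlier_target_fst,
            sample_spec=tuple((d, 20) for d in range(3)),
        )
        null = build_null(cfg, n_sims=config.outlier_sims, seed=stage_seeds["outlier"])
        loci = simulate_drift_locus_set(
            DriftScenario(sample_n=20, seed=stage_seeds["outlier"] + 1), n_loci=20
        )
        rep = outlier_scan(loci, null)
        return {
            "n_sims": null.n_sims,
            "n_loci": len(rep.table),
            "n_outliers": int(rep.table.outlier.sum()),
            "p_values": rep.table.p_value.tolist(),
        }

    def stage_neutral_fit():
        demo = SettlementDemography()
        seed0 = stage_seeds["neutral_fit"]
        ensemble = [
            summarize_loci(
                simulate_settlement_region(demo, seed=seed0 + i),
                deme_names=["meso", "andes", "sahg"],
            )
            for i in range(config.neutral_sims)
        ]
        observed = summarize_loci(
            simulate_settlement_region(demo, seed=seed0 + config.neutral_sims),
            deme_names=["meso", "andes", "sahg"],
        )
        fit = neutrality_fit(observed, ensemble, keep_distances=False)
        return {
            "mean_distance": fit.mean_distance,
            "median_distance": fit.median_distance,
            "min_distance": fit.min_distance,
            "n_sims": fit.n_sims,
            "standardization": fit.standardization,
        }

    def stage_correlation():
        pollen = (
            read_pollen_table(config.pollen_table) if config.pollen_table else fx.table2
        )
        rep = frequency_vs_age_report(table, pollen)
        return {
            "rho": rep.correlation.rho,
            "p_value": rep.correlation.p_value,
            "n": rep.correlation.n,
            "data": rep.data.to_dict(orient="records"),
        }

    run_stage("amova", stage_amova)
    run_stage("t_tests", stage_ttests)
    run_stage("kimura_ohta", stage_kimura)
    run_stage("outlier", stage_outlier)
    run_stage("neutral_fit", stage_neutral_fit)
    run_stage("correlation", stage_correlation)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _write_tsvs(report, outdir)
    return report


def _write_tsvs(report: dict, outdir: Path) -> None:
    stages = report["stages"]
    if stages.get("amova", {}).get("status") == "ok":
        r = stages["amova"]["result"]
        lines = ["statistic\tvalue\tp"]
        for k in ("fct", "fsc", "fst"):
            lines.append(f"{k}\t{r[k]}\t{r['p_' + k]}")
        for sub, v in r["within_group_fst"].items():
            lines.append(f"fst[{sub}]\t{v['fst']}\t{v['p']}")
        (outdir / "amova.tsv").write_text("\n".join(lines) + "\n")
    if stages.get("correlation", {}).get("status") == "ok":
        r = stages["correlation"]["result"]
        lines = ["population\tsite\tcalendar_years\tfrequency"]
        for row in r["data"]:
            lines.append(
                f"{row['population']}\t{row['site']}\t{row['calendar_years']}\t{row['frequency']}"
            )
        (outdir / "correlation.tsv").write_text("\n".join(lines) + "\n")


def exit_code(report: dict) -> int:
    """0 only if every enabled stage succeeded."""
    return 0 if all(s["status"] == "ok" for s in report["stages"].values()) else 1
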