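"""Config-driven pipeline: table CSV exports, run manifest, logging.

Rounding conventions live here and only here: pounds to 2 dp, QALYs to
6 dp, ICERs to the nearest pound (with 'Dominant'/'Dominated' literals in
the ICER column).  Internals stay at full precision; two runs with the same
configuration and master seed produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import format_icer, nmb
from .config import AnalysisConfig, ConfigError, build_bundle, load_config, default_config
from .epidemiology import IncidenceInput, annual_rate, pool
from .synthetic import SyntheticConfig, generate_dataset, write_dataset
from .uncertainty import PSAConfig, run_psa, threshold_search, univariate_sweep

__all__ = ["RunManifest", "run", "SUBCOMMANDS", "config_hash"]

SUBCOMMANDS = ("basecase", "psa", "tornado", "threshold", "scenario", "synth", "all")

log = logging.getLogger("vitdcea")

# Table-layout thresholds analysed per parameter: (registry name, bracket)
THRESHOLD_PARAMS = (
    ("rickets_duration", (0.01, 60.0)),
    ("admin_budget_per_year", (0.0, 500_000.0)),
    ("rickets_or", (1e-4, 0.9999)),
    ("uptake_increase_woman", (0.0, 1.0)),
    ("uptake_increase_child", (0.0, 1.0)),
)


def _money(x: float) -> float:
    return round(float(x), 2)


def _qaly(x: float) -> float:
    return round(float(x), 6)


def config_hash(raw: dict) -> str:
    """sha256 of the canonical JSON form; stable under key reordering."""
    clean = {k: v for k, v in raw.items() if not k.startswith("_")}
    blob = json.dumps(clean, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    timestamp: str
    outputs: list[str]

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "master_seed": self.master_seed,
                    "version": self.version,
                    "timestamp": self.timestamp,
                    "outputs": sorted(self.outputs),
                },
                indent=2,
            )
            + "\n"
        )


def _log_parameters(cfg: AnalysisConfig) -> None:
    for spec in cfg.registry:
        log.info(
            "parameter %s: point=%g dist=%s(%g, %g) source=%s",
            spec.name,
            spec.point,
            spec.dist.family,
            spec.dist.a,
            spec.dist.b,
            spec.source or cfg.registry.provenance,
        )


def _write(df: pd.DataFrame, path: Path, outputs: list[str]) -> None:
    df.to_csv(path, index=False)
    outputs.append(path.name)
    log.info("wrote %s (%d rows)", path, len(df))


def _rates_table(cfg: AnalysisConfig) -> pd.DataFrame:
    inputs = [
        IncidenceInput(s.label, s.cases_total, s.window_years, s.census_count)
        for s in cfg.subgroups.values()
    ]
    rows = []
    for inp in inputs + [pool(inputs, "general")]:
        est = annual_rate(inp)
        rows.append(
            {
                "subgroup": inp.subgroup,
                "cases_per_year": round(inp.cases_total / inp.window_years, 2),
                "population_at_risk": int(inp.population_at_risk),
                "per_100k_children": round(est.per_100k, 2),
                "annual_risk": est.annual_risk,
                "cumulative_4yr_risk": est.cumulative_4yr,
            }
        )
    return pd.DataFrame(rows)


def _basecase_table(cfg: AnalysisConfig, scenario: bool = False) -> pd.DataFrame:
    rows = []
    for label in cfg.subgroups:
        bundle = build_bundle(cfg, label, scenario=scenario)
        comp, interv = bundle.evaluate()
        res = bundle.cea()
        for arm, out in (("comparator", comp), ("intervention", interv)):
            rows.append(
                {
                    "subgroup": label,
                    "arm": arm,
                    "cost": _money(out.expected_cost),
                    "qalys": _qaly(out.expected_qalys),
                    "delta_cost": _money(res.delta_cost) if arm == "intervention" else "",
                    "delta_qalys": _qaly(res.delta_qalys) if arm == "intervention" else "",
                    "icer": format_icer(res) if arm == "intervention" else "",
                }
            )
    return pd.DataFrame(rows)


def _run_psa_tables(cfg: AnalysisConfig, outdir: Path, outputs: list[str]) -> None:
    rows = []
    psa_cfg = PSAConfig(
        n_samples=cfg.psa_n_samples,
        master_seed=cfg.master_seed,
        lambda_grid=cfg.lambda_grid,
    )
    for label in cfg.subgroups:
        bundle = build_bundle(cfg, label)
        res = run_psa(bundle, cfg.registry, psa_cfg)
        mean = res.mean_result()
        row = {
            "subgroup": label,
            "n_samples": res.n,
            "mean_delta_cost": _money(res.mean_delta_cost),
            "mean_delta_qalys": _qaly(res.mean_delta_qalys),
            "icer_of_means": format_icer(mean),
        }
        for pt in res.ceac:
            row[f"p_ce_lambda_{int(pt.lam)}"] = round(pt.probability_ce, 4)
        lo, hi = res.nmb_interval(cfg.lambda_grid[0])
        row["nmb_ci_low"] = _money(lo)
        row["nmb_ci_high"] = _money(hi)
        rows.append(row)
        _write(
            pd.DataFrame(
                {
                    "delta_cost": np.round(res.delta_cost, 6),
                    "delta_qalys": np.round(res.delta_qalys, 9),
                }
            ),
            outdir / f"ce_plane_{label}.csv",
            outputs,
        )
        lambdas = np.linspace(0.0, 50_000.0, 101)
        from .cea import ceac as _ceac

        dense = _ceac(res.delta_cost, res.delta_qalys, lambdas)
        _write(
            pd.DataFrame(
                {
                    "lambda": [p.lam for p in dense],
                    "probability_ce": [round(p.probability_ce, 4) for p in dense],
                }
            ),
            outdir / f"ceac_{label}.csv",
            outputs,
        )
    _write(pd.DataFrame(rows), outdir / "table_psa.csv", outputs)


def _tornado_table(cfg: AnalysisConfig, label: str) -> pd.DataFrame:
    bundle = build_bundle(cfg, label)
    lam = cfg.lambda_grid[0]
    rows = []
    for reg_name in sorted(bundle.registry_map):
        spec = cfg.registry[reg_name]
        if spec.dist.family == "fixed":
            continue
        sw = univariate_sweep(bundle, cfg.registry, reg_name, lam=lam)
        rows.append(
            {
                "parameter": reg_name,
                "value_low": sw.value_low,
                "value_high": sw.value_high,
                "icer_low": format_icer(sw.result_low),
                "icer_high": format_icer(sw.result_high),
                "nmb_low": _money(nmb(sw.result_low, lam)),
                "nmb_high": _money(nmb(sw.result_high, lam)),
                "decision_changed": sw.decision_changed,
            }
        )
    return pd.DataFrame(rows)


def _threshold_table(cfg: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for label in cfg.subgroups:
        bundle = build_bundle(cfg, label)
        for reg_name, bracket in THRESHOLD_PARAMS:
            override = bundle.registry_map.get(reg_name, reg_name)
            for lam in cfg.lambda_grid:
                tr = threshold_search(bundle, override, lam, bracket)
                rows.append(
                    {
                        "subgroup": label,
                        "parameter": reg_name,
                        "lambda": lam,
                        "base_value": cfg.registry.point(reg_name)
                        if reg_name in cfg.registry
                        else getattr(cfg.costcfg, reg_name),
                        "crossing_value": tr.crossing_value
                        if isinstance(tr.crossing_value, str)
                        else round(tr.crossing_value, 4),
                        "direction": tr.direction,
                    }
                )
    return pd.DataFrame(rows)


def _scenario_table(cfg: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for label in cfg.subgroups:
        base = build_bundle(cfg, label).cea()
        scen = build_bundle(cfg, label, scenario=True).cea()
        rows.append(
            {
                "subgroup": label,
                "basecase_icer": format_icer(base),
                "scenario_icer": format_icer(scen),
                "basecase_delta_cost": _money(base.delta_cost),
                "scenario_delta_cost": _money(scen.delta_cost),
                "basecase_delta_qalys": _qaly(base.delta_qalys),
                "scenario_delta_qalys": _qaly(scen.delta_qalys),
            }
        )
    return pd.DataFrame(rows)


def _synth_outputs(cfg: AnalysisConfig, outdir: Path, outputs: list[str]) -> None:
    obs = cfg.raw.get("observational", {})
    syn_cfg = SyntheticConfig(
        seed=cfg.master_seed,
        window_years=next(iter(cfg.subgroups.values())).window_years,
        subgroup_populations={s.label: s.census_count for s in cfg.subgroups.values()},
        subgroup_annual_per_100k={
            s.label: s.annual_risk * 1e5 for s in cfg.subgroups.values()
        },
        onset_mean_months=float(obs.get("onset_mean_months", 21.16)),
        cost_means={s.label: s.treatment_cost_mean for s in cfg.subgroups.values()},
        cost_sds={s.label: s.treatment_cost_sd_observed for s in cfg.subgroups.values()},
        sex_male_prob=float(obs.get("sex_male_prob", 0.6316)),
    )
    for name, path in write_dataset(*generate_dataset(syn_cfg), outdir).items():
        outputs.append(path.name)
        log.info("wrote %s", path)


def run(
    config_path: str | Path | None,
    output_dir: str | Path,
    subcommand: str,
    master_seed: int | None = None,
    log_file: str | Path | None = None,
) -> list[str]:
    """Execute one pipeline subcommand; returns the list of files written.

    Raises :class:`~vitdcea.config.ConfigError` on invalid configuration
    (the CLI converts that into a non-zero exit status).
    """
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {subcommand!r}; expected one of {SUBCOMMANDS}")
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True)

    cfg = load_config(config_path) if config_path else default_config()
    if master_seed is not None:
        cfg.raw["master_seed"] = int(master_seed)
        cfg = dataclasses.replace(cfg, master_seed=int(master_seed))
    _log_parameters(cfg)

    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    if subcommand in ("basecase", "all"):
        _write(_rates_table(cfg), outdir / "table_rates.csv", outputs)
        _write(_basecase_table(cfg), outdir / "table_basecase.csv", outputs)
    if subcommand in ("psa", "all"):
        _run_psa_tables(cfg, outdir, outputs)
    if subcommand in ("tornado", "all"):
        for label in cfg.subgroups:
            _write(_tornado_table(cfg, label), outdir / f"tornado_{label}.csv", outputs)
    if subcommand in ("threshold", "all"):
        _write(_threshold_table(cfg), outdir / "table_threshold.csv", outputs)
    if subcommand in ("scenario", "all"):
        _write(_scenario_table(cfg), outdir / "table_scenario.csv", outputs)
    if subcommand in ("synth", "all"):
        _synth_outputs(cfg, outdir, outputs)

    manifest = RunManifest(
        config_hash=config_hash(cfg.raw),
        master_seed=cfg.master_seed,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        outputs=outputs,
    )
    manifest.write(outdir / "manifest.json")
    log.info("run complete: %d output files in %s", len(outputs), outdir)
    return outputs
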