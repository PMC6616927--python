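"""End-to-end orchestration: simulate -> pretreat -> fit -> sensitivity ->
generate -> tradeoff.

A single master seed drives the whole run; every stage derives its own named
substream (SHA-256 of ``"{master}:{stage}"`` reduced below 2**31), so a stage
can be re-run in isolation with unchanged randomness.  All stage outputs are
plain CSV plus a JSON manifest echoing the configuration, the derived seeds
and per-stage runtimes; two runs with the same master seed produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as bio
from .modelsel import ModelReport, select_and_fit_all
from .pretreat import IndicatorTable, pretreat_herd
from .sensitivity import oat_profile, sensitivity_table
from .synthdata import HerdTable, default_config, generate_herd
from .tradeoff import TradeoffResult, WeightScheme, default_weights, run_tradeoff
from .virtualgen import VirtualPopulation, generate_population

STAGES = ("simulate", "pretreat", "fit", "sensitivity", "generate", "tradeoff")

__all__ = ["STAGES", "PipelineConfig", "PipelineResult", "stage_seed", "run_pipeline"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed, below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All tunable parameters of a run, with the analysis defaults."""

    seed: int = 0
    # simulate
    n_animals: int = 30
    rho_nq_oq: float = -0.3
    noise_sd: float = 1.0
    herd_csv: str | None = None  # read a real herd instead of simulating
    group_map_csv: str | None = None
    # pretreat
    cluster_counts: dict = field(default_factory=lambda: {"CP": 6, "NQ": 6, "OQ": 5})
    # fit
    n_splits: int = 50
    B: int = 100
    rf_trees: int = 500
    compute_quality: bool = True
    # sensitivity
    n_base: int = 10_000
    # generate
    anchor_group: str = "CP"
    n_virtual: int = 500
    rounds: int = 10
    level: float = 0.95
    interval: str = "prediction"
    # tradeoff
    k_select: int = 30
    targets: tuple = ((2.0, 2.0), (-2.0, -2.0))
    restandardize: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.targets, list):
            cfg.targets = tuple(tuple(t) for t in cfg.targets)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    herd: HerdTable | None = None
    indicators: IndicatorTable | None = None
    report: ModelReport | None = None
    sensitivities: pd.DataFrame | None = None
    population: VirtualPopulation | None = None
    tradeoff: TradeoffResult | None = None
    manifest: dict | None = None


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] | list[str] = STAGES,
    weights: WeightScheme | None = None,
) -> PipelineResult:
    """Run the requested stages, reading any missing inputs from ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    res = PipelineResult()
    seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    runtimes: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                runtimes[stage] = round(time.perf_counter() - self.t0, 3)

        return _T()

    # --- simulate (or load a provided herd)
    if "simulate" in stages:
        with timed("simulate"):
            if config.herd_csv:
                res.herd = bio.read_herd(config.herd_csv, config.group_map_csv)
            else:
                cfg = default_config(
                    n_animals=config.n_animals,
                    rho_nq_oq=config.rho_nq_oq,
                    noise_sd=config.noise_sd,
                    seed=seeds["simulate"],
                )
                res.herd = generate_herd(cfg)
            bio.write_herd(res.herd, out / "herd.csv", out / "group_map.csv")

    # --- pretreat
    if "pretreat" in stages:
        with timed("pretreat"):
            herd = res.herd or bio.read_herd(out / "herd.csv", out / "group_map.csv")
            res.indicators, solutions = pretreat_herd(herd, cluster_counts=config.cluster_counts)
            bio.write_indicators(res.indicators, out / "indicators.csv", out / "indicator_groups.csv")
            rows = []
            for group, sol in solutions.items():
                for var, cid in sol.membership.items():
                    rows.append(
                        {"group": group, "variable": var, "cluster": cid,
                         "loading": sol.loadings[var],
                         "homogeneity_pct": sol.homogeneity_pct}
                    )
            pd.DataFrame(rows).to_csv(out / "cluster_report.csv", index=False)

    def _indicators() -> IndicatorTable:
        if res.indicators is None:
            res.indicators = bio.read_indicators(
                out / "indicators.csv", out / "indicator_groups.csv"
            )
        return res.indicators

    # --- fit
    if "fit" in stages:
        with timed("fit"):
            data = _indicators()
            res.report = select_and_fit_all(
                data, n_splits=config.n_splits, B=config.B, seed=seeds["fit"],
                rf_trees=config.rf_trees, compute_quality=config.compute_quality,
            )
            res.report.quality.to_csv(out / "model_quality.csv", index=False)
            pd.DataFrame(
                [{"indicator": k, "predictor": p}
                 for k, m in res.report.models.items() for p in m.predictors]
            ).to_csv(out / "selected_predictors.csv", index=False)
            bio.write_model_bundle(
                res.report.models, out / "models.pkl",
                meta={"seed": seeds["fit"], "n_splits": config.n_splits},
            )

    def _models() -> dict:
        if res.report is not None:
            return res.report.models
        models, _meta = bio.read_model_bundle(out / "models.pkl")
        return models

    # --- sensitivity
    if "sensitivity" in stages:
        with timed("sensitivity"):
            models = _models()
            res.sensitivities = sensitivity_table(
                models, n_base=config.n_base, seed=seeds["sensitivity"]
            )
            res.sensitivities.to_csv(out / "sensitivity.csv", index=False)
            prof_rows = []
            for name, model in models.items():
                for pred in model.predictors:
                    curve = oat_profile(model, pred)
                    for g, v in zip(curve.grid, curve.prediction):
                        prof_rows.append(
                            {"model": name, "predictor": pred, "x": g, "prediction": v}
                        )
            pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)

    # --- generate
    if "generate" in stages:
        with timed("generate"):
            data = _indicators()
            res.population = generate_population(
                _models(), data, anchor_group=config.anchor_group,
                n=config.n_virtual, rounds=config.rounds, seed=seeds["generate"],
                level=config.level, interval=config.interval,
            )
            vp = res.population.values.copy()
            vp.to_csv(out / "virtual_population.csv")
            meta = {
                "anchor_group": res.population.anchor_group,
                "rounds": res.population.rounds,
                "seed": res.population.seed,
                "max_last_change_max": float(res.population.max_last_change.max()),
            }
            (out / "virtual_population_meta.json").write_text(json.dumps(meta, indent=1))

    # --- tradeoff
    if "tradeoff" in stages:
        with timed("tradeoff"):
            if res.population is not None:
                values = res.population.values
            else:
                values = pd.read_csv(
                    out / "virtual_population.csv", index_col=0,
                    float_precision="round_trip",
                )
            res.tradeoff = run_tradeoff(
                values, weights=weights or default_weights(), k=config.k_select,
                targets=config.targets, restandardize=config.restandardize,
            )
            res.tradeoff.indexes.to_csv(out / "indexes.csv")
            res.tradeoff.comparison.to_csv(out / "comparison.csv", index=False)
            (out / "tradeoff_summary.json").write_text(
                json.dumps({"r": res.tradeoff.r, "p": res.tradeoff.p,
                            "k": res.tradeoff.k}, indent=1)
            )

    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stage_seeds": seeds,
        "stages_run": list(stages),
        "runtimes_s": runtimes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    res.manifest = manifest
    return res
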