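"""End-to-end workflow: frequencies → estimation → centrality/small-world →
stability → network comparison, with configuration, per-stage seeding and a
reproducible output manifest.

Every random stage derives its seed deterministically from the master seed,
so a fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .comparison import nct
from .datasets import SymptomDataset, read_cohorts, write_cohorts
from .estimation import EstimatorConfig, fit_ising, fr_layout, pearson_matrix
from .frequency import adjusted_comparison, symptom_frequencies
from .metrics import METRICS, centrality_table, small_world
from .simulate import paper_like_cohorts
from .stability import DEFAULT_GRID, case_drop_bootstrap

logger = logging.getLogger("symptomnet")

STAGES = ("frequencies", "estimation", "metrics", "stability", "comparison")


def _from_dict(cls, d: dict, where: str):
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class SimulateSettings:
    n_per_group: dict[str, int] = field(default_factory=lambda: {"MDE": 871, "PPD": 486})
    dsm_constraint: bool = True


@dataclass
class MetricSettings:
    n_random: int = 1000
    metrics: list[str] = field(default_factory=lambda: list(METRICS))


@dataclass
class StabilitySettings:
    n_boot: int = 250
    proportions: list[float] = field(default_factory=lambda: list(DEFAULT_GRID))


@dataclass
class ComparisonSettings:
    n_perm: int = 1000
    edge_tests: bool = False


@dataclass
class AnalysisConfig:
    """Full pipeline configuration; round-trips through YAML/JSON."""

    seed: int = 0
    input: str | None = None  # cohort CSV with a group column; None = simulate
    output_dir: str = "symptomnet_output"
    simulate: SimulateSettings = field(default_factory=SimulateSettings)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    metrics: MetricSettings = field(default_factory=MetricSettings)
    stability: StabilitySettings = field(default_factory=StabilitySettings)
    comparison: ComparisonSettings = field(default_factory=ComparisonSettings)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        parts = {}
        for key, sub in (
            ("simulate", SimulateSettings),
            ("estimator", EstimatorConfig),
            ("metrics", MetricSettings),
            ("stability", StabilitySettings),
            ("comparison", ComparisonSettings),
        ):
            if key in d:
                parts[key] = _from_dict(sub, d.pop(key), key)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d, **parts)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        # identifies the analysis, not where it is written
        d = self.to_dict()
        d.pop("output_dir", None)
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _stage_seeds(master_seed: int) -> dict[str, int]:
    words = np.random.SeedSequence(master_seed).generate_state(len(STAGES) + 1)
    names = ("simulate",) + STAGES
    return {name: int(w % 2**31) for name, w in zip(names, words)}


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full comparative analysis; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "stages": {},
    }
    t_start = time.time()

    def record(stage: str, outputs: list[str]) -> None:
        manifest["stages"][stage] = {
            "outputs": outputs,
            "wall_time_s": round(time.time() - record.t0, 3),
        }
        logger.info("stage %s done in %.2fs", stage, time.time() - record.t0)

    # --- input -----------------------------------------------------------
    record.t0 = time.time()
    if config.input is not None:
        cohorts = read_cohorts(config.input)
    else:
        sim = config.simulate
        cohorts = paper_like_cohorts(
            n_mde=sim.n_per_group.get("MDE", 871),
            n_ppd=sim.n_per_group.get("PPD", 486),
            seed=seeds["simulate"],
            dsm_constraint=sim.dsm_constraint,
        )
        write_cohorts(cohorts, out / "cohorts.csv")
    groups = sorted(cohorts)
    if len(groups) != 2:
        raise RuntimeError(
            f"stage 'input' failed: pipeline compares exactly two groups, got {groups}"
        )
    ga, gb = groups
    logger.info("groups: %s (n=%d) vs %s (n=%d)",
                ga, cohorts[ga].n, gb, cohorts[gb].n)

    def run_stage(stage, fn):
        record.t0 = time.time()
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, outputs)

    # --- frequencies -----------------------------------------------------
    def _frequencies():
        freq = {g: symptom_frequencies(cohorts[g]) for g in groups}
        freq_df = (
            freq[ga].to_frame(ga).join(freq[gb].to_frame(gb)).rename_axis("symptom")
        )
        freq_df.to_csv(out / "frequencies.csv")
        table = adjusted_comparison(cohorts[ga], cohorts[gb])
        table.to_csv(out / "adjusted_comparison.csv", index=False)
        return ["frequencies.csv", "adjusted_comparison.csv"]

    run_stage("frequencies", _frequencies)

    # --- estimation ------------------------------------------------------
    networks = {}

    def _estimation():
        outputs = []
        for g in groups:
            net = fit_ising(cohorts[g], config=config.estimator)
            networks[g] = net
            net.to_json(out / f"network_{g}.json")
            net.to_edgelist_tsv(out / f"edges_{g}.tsv")
            pearson_matrix(cohorts[g]).to_dataframe().to_csv(out / f"pearson_{g}.csv")
            layout = fr_layout(net, seed=seeds["estimation"])
            np.savetxt(
                out / f"layout_{g}.csv",
                layout.xy,
                delimiter=",",
                header="x,y",
                comments="",
            )
            outputs += [
                f"network_{g}.json",
                f"edges_{g}.tsv",
                f"pearson_{g}.csv",
                f"layout_{g}.csv",
            ]
        return outputs

    run_stage("estimation", _estimation)

    # --- centrality & small world ---------------------------------------
    def _metrics():
        outputs = []
        for g in groups:
            centrality_table(networks[g], tuple(config.metrics.metrics)).to_csv(
                out / f"centrality_{g}.csv"
            )
            sw = small_world(
                networks[g],
                n_random=config.metrics.n_random,
                seed=seeds["metrics"],
            )
            _dump_json(sw.to_dict(), out / f"smallworld_{g}.json")
            outputs += [f"centrality_{g}.csv", f"smallworld_{g}.json"]
        return outputs

    run_stage("metrics", _metrics)

    # --- stability -------------------------------------------------------
    def _stability():
        outputs = []
        for g in groups:
            # metrics constant across nodes have no stability correlation
            cent = centrality_table(networks[g], tuple(config.metrics.metrics))
            usable = tuple(
                m
                for m in config.metrics.metrics
                if cent.raw[m].std() > 0
            )
            if len(usable) < len(config.metrics.metrics):
                dropped = sorted(set(config.metrics.metrics) - set(usable))
                logger.warning(
                    "group %s: metric(s) %s constant across nodes; "
                    "skipped in stability", g, dropped,
                )
            res = case_drop_bootstrap(
                cohorts[g],
                metrics=usable,
                n_boot=config.stability.n_boot,
                proportions=tuple(config.stability.proportions),
                seed=seeds["stability"],
                config=config.estimator,
            )
            res.to_csv(out / f"stability_{g}.csv")
            _dump_json(res.summary(), out / f"stability_{g}.json")
            outputs += [f"stability_{g}.csv", f"stability_{g}.json"]
        return outputs

    run_stage("stability", _stability)

    # --- comparison ------------------------------------------------------
    def _comparison():
        res = nct(
            cohorts[ga],
            cohorts[gb],
            n_perm=config.comparison.n_perm,
            seed=seeds["comparison"],
            config=config.estimator,
            edge_tests=config.comparison.edge_tests,
        )
        res.to_json(out / "nct.json")
        res.null_to_csv(out / "nct_null.csv")
        outputs = ["nct.json", "nct_null.csv"]
        if res.edge_p_values is not None:
            res.edge_p_values.to_csv(out / "nct_edges.csv", index=False)
            outputs.append("nct_edges.csv")
        return outputs

    run_stage("comparison", _comparison)

    manifest["total_wall_time_s"] = round(time.time() - t_start, 3)
    _dump_json(manifest, out / "manifest.json")
    return manifest
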