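"""End-to-end orchestration of the two analysis arms.

The network arm simulates (or loads) a cohort, screens symptom pairs by
mutual information, decomposes the association network into k-cores and
labels the core symptoms with syndromes. The mode arm fits a CHAID
identification mode for a target syndrome and judges it by stratified
cross-validation. A master seed deterministically spawns per-stage seeds so
each arm can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chaid, cores, network, validation, vocab
from .cohort import (
    Cohort,
    ConfigurationError,
    GeneratorConfig,
    generate_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

_STAGES = ("generator", "network", "validation")


def spawn_stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (kept below 2**31) from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(_STAGES))
    return {
        stage: int(s % (2**31)) for stage, s in zip(_STAGES, state)
    }


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    chaid: chaid.ChaidConfig = field(default_factory=chaid.ChaidConfig)
    validation: validation.ValidationConfig = field(
        default_factory=validation.ValidationConfig
    )
    output_dir: Path = Path("zhengmine_out")
    log_level: str = "INFO"

    @classmethod
    def with_master_seed(cls, master_seed: int, **overrides) -> "PipelineConfig":
        seeds = spawn_stage_seeds(master_seed)
        config = cls(**overrides)
        config.generator = dataclasses.replace(
            config.generator, random_seed=seeds["generator"]
        )
        config.network = dataclasses.replace(
            config.network, random_seed=seeds["network"]
        )
        config.validation = dataclasses.replace(
            config.validation, random_seed=seeds["validation"]
        )
        return config

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as f:
            raw = yaml.safe_load(f) or {}
        kwargs = {}
        if "generator" in raw:
            gen = dict(raw["generator"])
            if "biomarker_specs" in gen:
                from .cohort import BiomarkerSpec

                gen["biomarker_specs"] = tuple(
                    BiomarkerSpec(**s) for s in gen["biomarker_specs"]
                )
            if "symptom_names" in gen:
                gen["symptom_names"] = tuple(gen["symptom_names"])
            kwargs["generator"] = GeneratorConfig(**gen)
        if "network" in raw:
            kwargs["network"] = network.NetworkConfig(**raw["network"])
        if "chaid" in raw:
            kwargs["chaid"] = chaid.ChaidConfig(**raw["chaid"])
        if "validation" in raw:
            kwargs["validation"] = validation.ValidationConfig(**raw["validation"])
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        if "log_level" in raw:
            kwargs["log_level"] = raw["log_level"]
        if "master_seed" in raw:
            return cls.with_master_seed(raw["master_seed"], **kwargs)
        return cls(**kwargs)

    def config_digest(self) -> str:
        import hashlib

        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            return str(o)

        payload = dataclasses.asdict(self)
        # run environment, not scientific configuration
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name: str):
    """Wrap a stage so failures carry the stage name and context."""
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_network_arm(
    config: PipelineConfig, cohort: Cohort | None = None
) -> dict:
    """Simulate → MI network → k-core → syndrome labels; write all artifacts.

    Returns the summary dict (also written as JSON): node/edge counts,
    degree range, k-core shell sizes, syndrome groups at k=3.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = _stage("generate_cohort")(generate_cohort)(config.generator)
        write_cohort(cohort, out / "cohort.csv")
    net = _stage("build_association_network")(network.build_association_network)(
        cohort, config.network
    )
    network.write_pajek(net, out / "network.net")
    network.write_adjacency_tsv(net, out / "adjacency.tsv")
    core_table = _stage("kcore_decompose")(cores.kcore_decompose)(net)
    cores.write_core_table(core_table, out / "cores.tsv")
    groups = cores.label_core_syndromes(core_table, k=3)
    shell_sizes = (
        core_table["core"].value_counts().sort_index().to_dict()
    )
    summary = {
        "config_digest": config.config_digest(),
        "n_patients": cohort.n_patients,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "degree_min": int(core_table["degree"].min()),
        "degree_max": int(core_table["degree"].max()),
        "degree_sum": int(core_table["degree"].sum()),
        "core_shell_sizes": {int(k): int(v) for k, v in shell_sizes.items()},
        "n_core_ge_3": int((core_table["core"] >= 3).sum()),
        "syndrome_groups_k3": groups,
    }
    with open(out / "syndrome_summary.json", "w", encoding="utf-8") as f:
        json.dump(summary, f, indent=1)
    return summary


def run_mode_arm(
    config: PipelineConfig,
    target: str = "qi deficiency",
    cohort: Cohort | None = None,
    predictors: list[str] | None = None,
) -> validation.CrossValidationReport:
    """Simulate → CHAID fit → stratified CV → reports for one syndrome."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = _stage("generate_cohort")(generate_cohort)(config.generator)
    if target not in cohort.labels.columns:
        raise ConfigurationError(
            f"target {target!r} not among generated syndromes "
            f"{list(cohort.labels.columns)}"
        )
    prevalence = cohort.labels[target].mean()
    if prevalence in (0.0, 1.0):
        raise ConfigurationError(
            f"target {target!r} is degenerate (prevalence {prevalence}); "
            "cannot fit an identification mode"
        )
    report = _stage("cross_validate")(validation.cross_validate)(
        cohort, target, config.chaid, config.validation, predictors
    )
    slug = target.replace(" ", "_").replace("-", "_")
    chaid.export_tree(report.final_tree, out / f"tree_{slug}.json")
    payload = report.to_json_dict() | {"config_digest": config.config_digest()}
    with open(out / f"cv_report_{slug}.json", "w", encoding="utf-8") as f:
        json.dump(payload, f, indent=1)
    text = report.render_text() + "\n" + chaid.render_tree(report.final_tree)
    (out / f"report_{slug}.txt").write_text(text, encoding="utf-8")
    return report


def verify_fixtures(
    core_table: pd.DataFrame | None = None,
    confusions: dict | None = None,
) -> dict:
    """Run every consistency check on the packaged published tables.

    Network property table: 69 rows, handshake sum 240 (=2 x 120 edges),
    max degree 11, exactly 31 core-3 rows, core <= degree everywhere.
    Confusion tables: all printed percentages and correct counts recompute.
    Arguments exist so fault-injected copies can be checked in tests.
    """
    if core_table is None:
        core_table = cores.load_reference_core_table()
    checks: list[dict] = []

    def check(name: str, ok: bool, detail: str = "") -> None:
        checks.append({"name": name, "passed": bool(ok), "detail": detail})

    check("table1_rows_69", len(core_table) == 69, f"rows={len(core_table)}")
    deg_sum = int(core_table["degree"].sum())
    check("table1_handshake_240", deg_sum == 240, f"sum={deg_sum}")
    check(
        "table1_implies_120_edges", deg_sum // 2 == 120, f"edges={deg_sum // 2}"
    )
    dmax = int(core_table["degree"].max())
    check("table1_max_degree_11", dmax == 11, f"max={dmax}")
    n3 = int((core_table["core"] == 3).sum())
    check("table1_core3_count_31", n3 == 31, f"core3={n3}")
    bad = core_table[core_table["core"] > core_table["degree"]]
    check(
        "table1_core_le_degree", bad.empty,
        "" if bad.empty else f"violations={bad['node'].tolist()}",
    )

    table_report = validation.reproduce_paper_tables(confusions)
    for cohort_name, entries in table_report.items():
        for syndrome, entry in entries.items():
            check(
                f"{cohort_name}/{syndrome}_metrics_recompute",
                not entry["mismatches"],
                f"mismatches={entry['mismatches']}" if entry["mismatches"] else "",
            )
    return {
        "passed": all(c["passed"] for c in checks),
        "checks": checks,
        "tables": table_report,
    }
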