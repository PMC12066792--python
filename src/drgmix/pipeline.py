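"""End-to-end orchestration: clean -> stage 1 -> stage 2 -> evaluation.

The pipeline functions operate on claim records and return in-memory
artifacts; :mod:`drgmix.cli` is a thin shell over them that also writes the
artifacts to disk.  Every run is fully determined by its configuration and
seed, and emitted artifacts carry a hash of that configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .benchmark import RuleTable, RuleTableGrouper, load_rule_table
from .evaluation import SchemeReport, evaluate_grouping, projected_savings
from .io import CleaningConfig, clean_claims, claims_to_frame
from .stage1 import CCSeverityClassifier, add_strata_columns
from .stage2 import DecisionTreeGrouper, TreeParams
from .synthetic import SimParams, default_sim_params, generate_cohort, load_sim_params

__all__ = [
    "PipelineConfig",
    "TwoStageResult",
    "default_rule_table",
    "default_synthetic_params",
    "run_two_stage",
    "run_benchmark",
    "run_comparison",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable, hashable, seed-stamped."""

    seed: int = 0
    alpha: float = 0.05
    cut_major: float = 0.30
    cut_moderate: float = 0.60
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    tree: TreeParams = field(default_factory=TreeParams)
    currency: str = "USD"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cleaning = CleaningConfig(**raw.pop("cleaning", {}))
        tree_raw = raw.pop("tree", {})
        if "factors" in tree_raw:
            tree_raw["factors"] = tuple(tree_raw["factors"])
        tree = TreeParams(**tree_raw)
        return cls(cleaning=cleaning, tree=tree, **raw)

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "alpha": self.alpha,
            "cut_major": self.cut_major,
            "cut_moderate": self.cut_moderate,
            "cleaning": self.cleaning.__dict__,
            "tree": {**self.tree.__dict__, "factors": list(self.tree.factors)},
            "currency": self.currency,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_synthetic_params(n: int | None = None, seed: int | None = None) -> SimParams:
    """The bundled synthetic-cohort configuration."""
    path = resources.files("drgmix.data").joinpath("default_synthetic.yaml")
    params = load_sim_params(str(path))
    if n is not None:
        params.n = n
    if seed is not None:
        params.seed = seed
    return params


def default_rule_table() -> RuleTable:
    """The bundled benchmark rule fixture (severity x hospital x insurance)."""
    return load_rule_table(resources.files("drgmix.data").joinpath("default_rules.yaml"))


@dataclass
class TwoStageResult:
    """All artifacts of one two-stage run."""

    audit: object
    classifier: CCSeverityClassifier
    grouper: DecisionTreeGrouper
    frame: pd.DataFrame  # cleaned claims + patient_type/strata + group_id
    stats: pd.DataFrame
    overuse: pd.DataFrame
    report: SchemeReport
    savings: float
    config_hash: str


def run_two_stage(records, config: PipelineConfig | None = None) -> TwoStageResult:
    """Clean, tier CCs, type patients, grow the grouping tree, evaluate."""
    config = config or PipelineConfig()
    cleaned, audit = clean_claims(records, config.cleaning)
    logger.info("cleaning: %d -> %d records", audit.n_input, audit.n_output)
    if not cleaned:
        raise ValueError("cleaning stage left no records to group")
    df = add_strata_columns(claims_to_frame(cleaned))

    clf = CCSeverityClassifier(
        alpha=config.alpha, cut_major=config.cut_major, cut_moderate=config.cut_moderate
    ).fit(df)
    df["patient_type"] = clf.predict(df)
    logger.info(
        "stage 1: %d significant CCs tiered", len(clf.severity_table_.entries)
    )

    tree = config.tree
    grouper = DecisionTreeGrouper(
        factors=tree.factors,
        min_leaf=tree.min_leaf,
        min_gain=tree.min_gain,
        max_depth=tree.max_depth,
        train_fraction=tree.train_fraction,
        n_trials=tree.n_trials,
        random_state=tree.seed if tree.seed else config.seed,
    ).fit(df, df["cost"].to_numpy())
    df["group_id"] = grouper.predict(df)
    logger.info("stage 2: %d final groups", grouper.n_groups_)

    stats, overuse, report = evaluate_grouping(df, df["group_id"])
    savings = projected_savings(
        overuse["n_overuse"], overuse["mean_overuse"], stats["upper_limit"]
    )
    return TwoStageResult(
        audit=audit,
        classifier=clf,
        grouper=grouper,
        frame=df,
        stats=stats,
        overuse=overuse,
        report=report,
        savings=savings,
        config_hash=config.config_hash(),
    )


@dataclass
class BenchmarkResult:
    frame: pd.DataFrame
    stats: pd.DataFrame
    overuse: pd.DataFrame
    report: SchemeReport
    savings: float


def run_benchmark(
    records, rule_table: RuleTable, config: PipelineConfig | None = None
) -> BenchmarkResult:
    """Group the same cohort with the rule-table benchmark and evaluate."""
    config = config or PipelineConfig()
    cleaned, _ = clean_claims(records, config.cleaning)
    if not cleaned:
        raise ValueError("cleaning stage left no records to group")
    df = add_strata_columns(claims_to_frame(cleaned))
    df["group_id"] = RuleTableGrouper(rule_table).fit().predict(df)
    stats, overuse, report = evaluate_grouping(df, df["group_id"])
    savings = projected_savings(
        overuse["n_overuse"], overuse["mean_overuse"], stats["upper_limit"]
    )
    return BenchmarkResult(frame=df, stats=stats, overuse=overuse, report=report, savings=savings)


def run_comparison(
    records, rule_table: RuleTable | None = None, config: PipelineConfig | None = None
) -> dict:
    """Side-by-side scheme reports and savings, benchmark vs two-stage."""
    config = config or PipelineConfig()
    rule_table = rule_table or default_rule_table()
    two = run_two_stage(records, config)
    bench = run_benchmark(records, rule_table, config)
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "benchmark": {**bench.report.to_dict(), "savings": bench.savings},
        "two_stage": {**two.report.to_dict(), "savings": two.savings},
        "_results": {"benchmark": bench, "two_stage": two},
    }


def simulate_records(n: int, seed: int, params_path=None):
    """Generate a synthetic cohort from the bundled or a user config."""
    if params_path:
        params = load_sim_params(params_path)
        params.n, params.seed = n, seed
    else:
        params = default_sim_params(n=n, seed=seed)
    return generate_cohort(params)
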