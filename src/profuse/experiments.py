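"""Experiment protocols: ablations, modality sweep, and regime comparison.

Two ablation readings are implemented. ``sequential_prefix`` truncates the
fused chain from the deep end, scoring depths 1..T of a single fitted chain.
``single_removal`` deletes one block at a time and retrains with the
surviving order intact. Both report held-out accuracy per configuration
against the full chain's reference accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .baselines import REGIMES, BaselineConfig, run_regime, split_cohort
from .data_model import CohortTable, ModalityPartition
from .fusion import FittedChain, fit_chain
from .metrics import compute_report

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "AblationResult",
    "chain_holdout_accuracy",
    "ablate_sequential",
    "ablate_single",
    "modality_sweep",
    "compare_chain_with_regimes",
]


@dataclass
class ExperimentConfig:
    """Shared configuration schema for the CLI subcommands.

    Keys mirror the CLI option names, so a saved config can preset any
    command via ``--config``. Every stochastic component's seed is explicit.
    """

    data: str | None = None
    partition: str | None = None
    generator: dict | None = None
    outcome: str = "outcome"
    families: str = "gbt"
    residual_mode: str = "logit_residual"
    rule: str = "all"
    inner_folds: int = 5
    depths: str = "2,3,4,5"
    resamples: int = 500
    seed: int = 0
    split_seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class AblationResult:
    protocol: str  # 'sequential_prefix' | 'single_removal'
    accuracies: dict[str, float]
    removed: dict[str, list[str]]
    reference_accuracy: float
    n_test: int

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "accuracies": self.accuracies,
            "removed": self.removed,
            "reference_accuracy": self.reference_accuracy,
            "n_test": self.n_test,
        }


def _accuracy_at_depth(pred, truth: np.ndarray, d: int) -> float:
    """Held-out accuracy when the chain is truncated at depth d.

    Each sample is scored at min(d, its achieved depth); samples with no
    block-1 data are excluded.
    """
    ok = pred.predictable
    eff = np.minimum(pred.depth, d)
    p = pred.trace[np.arange(len(eff)), np.maximum(eff, 1) - 1]
    lab = (p >= pred.threshold).astype(int)
    return float(np.mean(lab[ok] == truth[ok]))


def chain_holdout_accuracy(
    table: CohortTable,
    partition: ModalityPartition,
    families="gbt",
    residual_mode: str = "logit_residual",
    seed: int = 0,
    split_seed: int = 0,
    stratified: bool = True,
    rule: str = "all",
) -> tuple[float, FittedChain, object, np.ndarray]:
    """Fit on the 70% fold, return test accuracy, chain, prediction, labels."""
    train_ids, test_ids = split_cohort(table, split_seed=split_seed, stratified=stratified)
    chain = fit_chain(table.subset(train_ids), partition, families=families,
                      residual_mode=residual_mode, seed=seed, rule=rule)
    pred = chain.predict(table.subset(test_ids))
    truth = table.outcome.loc[test_ids].to_numpy(dtype=int)
    ok = pred.predictable
    acc = float(np.mean(pred.label[ok] == truth[ok])) if ok.any() else float("nan")
    return acc, chain, pred, truth


def ablate_sequential(
    table: CohortTable,
    partition: ModalityPartition,
    families="gbt",
    residual_mode: str = "logit_residual",
    seed: int = 0,
    split_seed: int = 0,
    rule: str = "all",
) -> AblationResult:
    """Prefix-truncation ablation: accuracy of depths 1..T of one chain."""
    acc_full, chain, pred, truth = chain_holdout_accuracy(
        table, partition, families, residual_mode, seed, split_seed, rule=rule)
    names = partition.block_names
    accuracies, removed = {}, {}
    for d in range(1, chain.depth + 1):
        key = f"depth_{d}"
        accuracies[key] = _accuracy_at_depth(pred, truth, d)
        removed[key] = names[d:]
    return AblationResult(
        protocol="sequential_prefix", accuracies=accuracies, removed=removed,
        reference_accuracy=acc_full, n_test=int(pred.predictable.sum()),
    )


def ablate_single(
    table: CohortTable,
    partition: ModalityPartition,
    families="gbt",
    residual_mode: str = "logit_residual",
    seed: int = 0,
    split_seed: int = 0,
    rule: str = "all",
    include_first: bool = False,
) -> AblationResult:
    """Remove one block at a time, keep the surviving order, retrain."""
    if partition.T < 2:
        raise ValueError("single-removal ablation needs at least two blocks")
    acc_full, _, pred_full, _ = chain_holdout_accuracy(
        table, partition, families, residual_mode, seed, split_seed, rule=rule)
    start = 0 if include_first else 1
    accuracies, removed = {}, {}
    for name in partition.block_names[start:]:
        reduced = partition.drop_block(name)
        fams = families if isinstance(families, str) else \
            [f for f, b in zip(families, partition.block_names) if b != name]
        acc, _, _, _ = chain_holdout_accuracy(
            table, reduced, fams, residual_mode, seed, split_seed, rule=rule)
        accuracies[f"-{name}"] = acc
        removed[f"-{name}"] = [name]
    return AblationResult(
        protocol="single_removal", accuracies=accuracies, removed=removed,
        reference_accuracy=acc_full, n_test=int(pred_full.predictable.sum()),
    )


def compare_chain_with_regimes(
    table: CohortTable,
    partition: ModalityPartition,
    families="gbt",
    residual_mode: str = "logit_residual",
    configs: list[BaselineConfig] | None = None,
    seed: int = 0,
    split_seed: int = 0,
    rule: str = "all",
    regimes=REGIMES,
    impute_kwargs: dict | None = None,
    resamples: int = 500,
) -> dict:
    """Full head-to-head: fitted chain vs every baseline family per regime."""
    acc, chain, pred, truth = chain_holdout_accuracy(
        table, partition, families, residual_mode, seed, split_seed, rule=rule)
    ok = pred.predictable
    chain_report = compute_report(pred.probability[ok], truth[ok],
                                  resamples=resamples, seed=split_seed)
    out = {
        "chain": {"accuracy": acc, "report": chain_report,
                  "n_test": int(ok.sum()), "depth": chain.depth},
        "regimes": {},
    }
    for regime in regimes:
        out["regimes"][regime] = run_regime(
            table, partition, regime, configs=configs, split_seed=split_seed,
            rule=rule, impute_kwargs=impute_kwargs, resamples=resamples,
        )
    return out


def modality_sweep(
    table: CohortTable,
    partition: ModalityPartition,
    depths,
    families="gbt",
    residual_mode: str = "logit_residual",
    configs: list[BaselineConfig] | None = None,
    seed: int = 0,
    split_seed: int = 0,
    rule: str = "all",
    regimes=REGIMES,
    impute_kwargs: dict | None = None,
    resamples: int = 200,
) -> dict[int, dict]:
    """Chain-vs-regimes comparison restricted to the first ``depth`` blocks."""
    depths = sorted(set(int(d) for d in depths))
    if any(d < 1 or d > partition.T for d in depths):
        raise ValueError(f"depths must lie in 1..{partition.T}")
    results = {}
    for d in depths:
        sub_partition = partition.prefix(d)
        sub_table = table.select_variables(list(sub_partition.variable_names))
        fams = families if isinstance(families, str) else families[:d]
        results[d] = compare_chain_with_regimes(
            sub_table, sub_partition, fams, residual_mode, configs=configs,
            seed=seed, split_seed=split_seed, rule=rule, regimes=regimes,
            impute_kwargs=impute_kwargs, resamples=resamples,
        )
        logger.info("sweep depth %d done", d)
    return results
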