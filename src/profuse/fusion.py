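"""Progressive residual-fusion chain.

A chain is a sequence of stage models over an ordered modality partition.
Stage 1 is a plain probabilistic classifier on the first block. Every later
stage consumes the features of blocks 1..t plus the previous stage's
prediction and refines it, either by regressing the logit-scale residual and
adding the correction (``logit_residual``, the default) or by reclassifying
the outcome with the prior prediction as an extra feature (``stacking``).
Stage t trains only on samples observed for all blocks 1..t, so eligible sets
shrink monotonically with depth; at inference each sample is pushed to the
deepest stage its observed block prefix allows.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.model_selection import StratifiedKFold

from ._families import NEEDS_STANDARDIZATION, make_classifier, make_regressor
from .data_model import (
    CohortTable,
    DesignMatrix,
    Encoder,
    ModalityPartition,
    ProfuseError,
    SingleClassError,
    VariableSpec,
    block_presence,
    oversample_indices,
    stage_eligible,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StageModel",
    "FittedChain",
    "ChainPrediction",
    "EmptyStageError",
    "fit_stage1",
    "fit_residual_stage",
    "fit_chain",
    "predict",
    "order_modalities",
]

RESIDUAL_MODES = ("logit_residual", "stacking")
DEFAULT_EPS = 1e-6


class EmptyStageError(ProfuseError):
    """Raised when a stage has no eligible training samples."""


@dataclass
class StageModel:
    """One fitted link of the chain."""

    t: int
    family: str
    model: object
    mode: str  # 'classify' (stage 1 / stacking) or 'residual'
    encoder: Encoder | None = None
    feature_columns: list[str] = field(default_factory=list)
    train_ids: list = field(default_factory=list)
    fill_values: pd.Series | None = None
    seed: int = 0

    @property
    def uses_prior(self) -> bool:
        return self.t > 1


@dataclass
class ChainPrediction:
    """Variable-depth predictions with the per-stage probability trace."""

    sample_ids: list
    depth: np.ndarray
    probability: np.ndarray
    trace: np.ndarray  # n x T, NaN past each sample's depth
    threshold: float = 0.5

    @property
    def label(self) -> np.ndarray:
        """Hard labels at the threshold; -1 flags unpredictable samples."""
        lab = np.where(self.probability >= self.threshold, 1, 0)
        return np.where(self.depth == 0, -1, lab)

    @property
    def predictable(self) -> np.ndarray:
        return self.depth > 0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "depth": self.depth,
                "probability": self.probability,
                f"label_at_{self.threshold:g}": self.label,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        for t in range(self.trace.shape[1]):
            frame[f"stage_{t + 1}"] = self.trace[:, t]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep="NA")


@dataclass
class FittedChain:
    """Sequence of stage models plus everything needed to predict."""

    partition: ModalityPartition
    stages: list[StageModel]
    variables: list[VariableSpec]
    residual_mode: str = "logit_residual"
    eps: float = DEFAULT_EPS
    rule: str = "all"
    seed: int = 0

    @property
    def depth(self) -> int:
        return len(self.stages)

    def predict(self, table: CohortTable) -> ChainPrediction:
        return predict(self, table)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "FittedChain":
        with open(path, "rb") as fh:
            chain = pickle.load(fh)
        if not isinstance(chain, cls):
            raise TypeError(f"{path} does not contain a FittedChain")
        return chain


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _stage_seed(seed: int, t: int) -> int:
    # stage 1 reuses the chain seed so a 1-block chain is bitwise identical to
    # the standalone baseline fitted with the same seed
    return seed + (t - 1)


def _clip(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def _design(stage: StageModel, table: CohortTable) -> np.ndarray:
    X = stage.encoder.transform(table).frame
    if stage.fill_values is not None:
        X = X.fillna(stage.fill_values)
    return X.to_numpy(dtype=float)


def _stage_apply(stage: StageModel, X: np.ndarray, prior: np.ndarray | None, eps: float) -> np.ndarray:
    """Probability emitted by one stage given its design rows and prior."""
    if stage.t == 1:
        p = stage.model.predict_proba(X)[:, 1]
    else:
        feats = np.column_stack([X, prior])
        if stage.mode == "residual":
            correction = stage.model.predict(feats)
            p = expit(logit(_clip(prior, eps)) + correction)
        else:
            p = stage.model.predict_proba(feats)[:, 1]
    p = _clip(np.asarray(p, dtype=float), eps)
    if not np.all(np.isfinite(p)):
        raise ProfuseError("non-finite stage probabilities despite clipping")
    return p


def _forward(chain: FittedChain, table: CohortTable, upto: int) -> np.ndarray:
    """Run stages 1..upto on every row of ``table`` (rows must be eligible)."""
    p = None
    for stage in chain.stages[:upto]:
        X = _design(stage, table)
        p = _stage_apply(stage, X, p, chain.eps)
    return p


def _fit_estimator(family: str, mode: str, X: np.ndarray, target: np.ndarray,
                   balance_labels: np.ndarray, seed: int, do_oversample: bool):
    """Oversample (by outcome label) then fit a classifier or regressor."""
    if do_oversample:
        idx = oversample_indices(balance_labels, seed)
        X, target = X[idx], target[idx]
    est = make_classifier(family, seed) if mode == "classify" else make_regressor(family, seed)
    est.fit(X, target)
    return est


def fit_stage1(
    matrix: DesignMatrix,
    labels,
    family: str = "gbt",
    seed: int = 0,
    do_oversample: bool = True,
) -> StageModel:
    """Fit the stage-1 baseline classifier on an encoded block-1 matrix."""
    if matrix.frame.empty:
        raise EmptyStageError("stage 1 has no eligible training samples")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError("stage 1 requires both outcome classes")
    est = _fit_estimator(family, "classify", matrix.to_numpy(), y, y, seed, do_oversample)
    return StageModel(
        t=1, family=family, model=est, mode="classify",
        feature_columns=matrix.column_names, train_ids=matrix.sample_ids, seed=seed,
    )


def fit_residual_stage(
    chain_so_far: FittedChain,
    table: CohortTable,
    t: int,
    family: str = "gbt",
    seed: int = 0,
    do_oversample: bool = True,
) -> StageModel:
    """Fit stage t >= 2 on the eligible samples, correcting the prior stage.

    In ``logit_residual`` mode the stage regresses
    r = logit(clip(y)) - logit(yhat(t-1)) on [blocks 1..t, yhat(t-1)] and the
    stage prediction adds the fitted correction on the logit scale. In
    ``stacking`` mode the stage reclassifies y on the same feature set.
    """
    if t < 2 or t > chain_so_far.partition.T:
        raise ValueError(f"residual stage index must be in [2, {chain_so_far.partition.T}]")
    if len(chain_so_far.stages) != t - 1:
        raise ValueError(f"chain must have stages 1..{t - 1} before fitting stage {t}")
    eps = chain_so_far.eps
    ids = stage_eligible(table, chain_so_far.partition, t, rule=chain_so_far.rule)
    if not ids:
        raise EmptyStageError(
            f"stage {t} ({chain_so_far.partition.block_names[t - 1]!r}) has no eligible samples"
        )
    sub = table.subset(ids)
    y = sub.outcome.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError(f"stage {t} eligible samples contain a single class")

    prior = _forward(chain_so_far, sub, upto=t - 1)

    specs = [table.spec(v) for v in chain_so_far.partition.variables_upto(t)]
    standardize = family in NEEDS_STANDARDIZATION
    enc = Encoder(specs, standardize=standardize).fit(sub, ids)
    Xf = enc.transform(sub).frame
    fill = None
    if chain_so_far.rule == "any" and Xf.isna().any().any():
        fill = Xf.mean()
        Xf = Xf.fillna(fill)
    X = Xf.to_numpy(dtype=float)
    feats = np.column_stack([X, prior])

    if chain_so_far.residual_mode == "logit_residual":
        target = logit(_clip(y.astype(float), eps)) - logit(_clip(prior, eps))
        if not np.all(np.isfinite(target)):
            raise ProfuseError("non-finite residual targets despite clipping")
        mode = "residual"
    else:
        target, mode = y, "classify"

    est = _fit_estimator(family, mode, feats, target, y, seed, do_oversample)
    return StageModel(
        t=t, family=family, model=est, mode=mode, encoder=enc,
        feature_columns=list(Xf.columns) + ["prior_prediction"],
        train_ids=ids, fill_values=fill, seed=seed,
    )


def fit_chain(
    table: CohortTable,
    partition: ModalityPartition,
    families: str | list[str] = "gbt",
    residual_mode: str = "logit_residual",
    seed: int = 0,
    do_oversample: bool = True,
    rule: str = "all",
    eps: float = DEFAULT_EPS,
) -> FittedChain:
    """Train the full progressive chain, stage by stage.

    Stage t is trained only on samples observed for blocks 1..t; preprocessing
    is refit on each stage's own training rows. A stage whose eligible set is
    empty (or single-class) truncates the chain with a warning rather than
    failing.
    """
    if residual_mode not in RESIDUAL_MODES:
        raise ValueError(f"residual_mode must be one of {RESIDUAL_MODES}")
    fam_list = _normalize_families(families, partition.T)

    chain = FittedChain(
        partition=partition, stages=[], variables=list(table.variables),
        residual_mode=residual_mode, eps=eps, rule=rule, seed=seed,
    )

    ids1 = stage_eligible(table, partition, 1, rule=rule)
    if not ids1:
        raise EmptyStageError(
            f"stage 1 ({partition.block_names[0]!r}) has no eligible samples"
        )
    sub1 = table.subset(ids1)
    specs1 = [table.spec(v) for v in partition.variables_upto(1)]
    enc1 = Encoder(specs1, standardize=fam_list[0] in NEEDS_STANDARDIZATION).fit(sub1, ids1)
    X1f = enc1.transform(sub1).frame
    fill1 = None
    if rule == "any" and X1f.isna().any().any():
        fill1 = X1f.mean()
        X1f = X1f.fillna(fill1)
    stage1 = fit_stage1(
        DesignMatrix(frame=X1f, fit_state=enc1.state_),
        sub1.outcome.to_numpy(),
        family=fam_list[0],
        seed=_stage_seed(seed, 1),
        do_oversample=do_oversample,
    )
    stage1.encoder, stage1.fill_values = enc1, fill1
    chain.stages.append(stage1)
    logger.info("stage 1 (%s): %d eligible samples", partition.block_names[0], len(ids1))

    for t in range(2, partition.T + 1):
        try:
            stage = fit_residual_stage(
                chain, table, t, family=fam_list[t - 1],
                seed=_stage_seed(seed, t), do_oversample=do_oversample,
            )
        except (EmptyStageError, SingleClassError) as err:
            logger.warning("chain truncated at depth %d: %s", t - 1, err)
            break
        chain.stages.append(stage)
        logger.info(
            "stage %d (%s): %d eligible samples",
            t, partition.block_names[t - 1], len(stage.train_ids),
        )
    return chain


def _normalize_families(families: str | list[str], T: int) -> list[str]:
    if isinstance(families, str):
        return [families] * T
    if len(families) != T:
        raise ValueError(f"need one family per stage ({T}), got {len(families)}")
    return list(families)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _align(table: CohortTable, chain: FittedChain) -> CohortTable:
    """Reindex a prediction table to cover every chain variable (NaN-filled)."""
    needed = chain.partition.variable_names
    missing_cols = [v for v in needed if v not in table.values.columns]
    if not missing_cols:
        return table
    values = table.values.copy()
    for v in missing_cols:
        values[v] = np.nan
    spec_by_name = {s.name: s for s in chain.variables}
    keep = [v for v in table.values.columns if v in spec_by_name] + missing_cols
    return CohortTable(
        values=values[keep],
        outcome=table.outcome.copy(),
        variables=[spec_by_name[v] for v in keep],
    )


def predict(chain: FittedChain, table: CohortTable) -> ChainPrediction:
    """Variable-depth inference.

    Each sample is scored to depth d = the longest observed *prefix* of blocks
    (a gap stops the chain: stage t consumes all of blocks 1..t). Samples
    missing block 1 are flagged unpredictable (depth 0, NaN probability) —
    no imputation is attempted.
    """
    table = _align(table, chain)
    presence = block_presence(table, chain.partition, rule=chain.rule)
    pres = presence.to_numpy(dtype=bool)
    # longest all-True prefix per row
    cum = np.cumprod(pres, axis=1).astype(bool)
    depth = cum.sum(axis=1)
    depth = np.minimum(depth, chain.depth)

    n, T = len(table.values), chain.partition.T
    trace = np.full((n, T), np.nan)
    if depth.max() == 0:
        logger.warning("no sample has block 1 observed; all flagged unpredictable")
    for stage in chain.stages:
        t = stage.t
        rows = np.flatnonzero(depth >= t)
        if rows.size == 0:
            break
        sub = table.subset([table.sample_ids[i] for i in rows])
        X = _design(stage, sub)
        prior = trace[rows, t - 2] if t > 1 else None
        trace[rows, t - 1] = _stage_apply(stage, X, prior, chain.eps)

    probability = np.full(n, np.nan)
    has = depth > 0
    probability[has] = trace[np.flatnonzero(has), depth[has] - 1]
    return ChainPrediction(
        sample_ids=table.sample_ids, depth=depth.astype(int),
        probability=probability, trace=trace,
    )


# ---------------------------------------------------------------------------
# modality ordering
# ---------------------------------------------------------------------------


def order_modalities(
    table: CohortTable,
    partition: ModalityPartition,
    families: str | list[str] = "gbt",
    inner_folds: int = 5,
    seed: int = 0,
    residual_mode: str = "logit_residual",
    rule: str = "all",
) -> ModalityPartition:
    """Greedy forward ordering of the non-fixed blocks by inner validation.

    The first ``fixed_prefix`` blocks stay pinned. At each open position every
    remaining candidate is appended in turn, a chain of that depth is scored
    by stratified k-fold accuracy within ``table`` (never any outside rows),
    and the best candidate is fixed. Ties keep declaration order.
    """
    if inner_folds < 2:
        raise ValueError(f"inner_folds must be >= 2, got {inner_folds}")
    lookup = dict(partition.blocks)
    chosen = list(partition.block_names[: partition.fixed_prefix])
    remaining = list(partition.block_names[partition.fixed_prefix :])

    while remaining:
        if len(remaining) == 1:
            chosen.append(remaining.pop())
            break
        best_name, best_score = None, -np.inf
        for cand in remaining:
            trial_names = chosen + [cand]
            trial = ModalityPartition(
                tuple((n, lookup[n]) for n in trial_names),
                fixed_prefix=min(partition.fixed_prefix, len(trial_names)),
            )
            score = _inner_cv_accuracy(
                table, trial, families, inner_folds, seed, residual_mode, rule
            )
            if score > best_score:
                best_name, best_score = cand, score
        logger.info("position %d: chose %r (inner accuracy %.4f)",
                    len(chosen) + 1, best_name, best_score)
        chosen.append(best_name)
        remaining.remove(best_name)

    return partition.reorder(chosen)


def _inner_cv_accuracy(table, trial_partition, families, inner_folds, seed,
                       residual_mode, rule) -> float:
    fam = families if isinstance(families, str) else families[: trial_partition.T]
    y = table.outcome.to_numpy(dtype=int)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        train_ids = [table.sample_ids[i] for i in train_idx]
        val_ids = [table.sample_ids[i] for i in val_idx]
        try:
            chain = fit_chain(
                table.subset(train_ids), trial_partition, families=fam,
                residual_mode=residual_mode, seed=seed, rule=rule,
            )
        except (EmptyStageError, SingleClassError):
            continue
        pred = chain.predict(table.subset(val_ids))
        ok = pred.predictable
        if not ok.any():
            continue
        truth = table.outcome.loc[val_ids].to_numpy(dtype=int)
        accs.append(float(np.mean(pred.label[ok] == truth[ok])))
    return float(np.mean(accs)) if accs else -np.inf
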