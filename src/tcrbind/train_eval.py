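"""Training, model selection, evaluation metrics and attention export.

Training follows the protocol used for the cross-validated pairing tasks:
for each fold the model is trained ``n_restarts`` times independently from
distinct derived seeds, and the restart with the highest validation AUC is
selected.  Evaluation reports accuracy, recall, precision, F1 and the
rank-based ROC AUC, with normal-approximation 95% confidence intervals
across folds/repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import PairRecord, PairTable, SplitSpec
from .encoding import (
    EmbeddingTable,
    EncodedBatch,
    build_vocabulary,
    encode_batch,
    init_random_embeddings,
)
from .model import (
    Adam,
    ModelConfig,
    ModelError,
    ModelParams,
    forward,
    init_model,
    loss_and_grads,
    predict_proba,
)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "AggregateReport",
    "EvalError",
    "train_model",
    "confusion_counts",
    "compute_metrics",
    "compute_auc",
    "aggregate",
    "run_task",
    "export_attention",
]


class EvalError(ValueError):
    """Fatal evaluation-protocol error."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (Adam, mean BCE objective)."""

    epochs: int = 10
    learning_rate: float = 0.001
    batch_size: int = 64
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.n_restarts < 1 or self.batch_size < 1:
            raise EvalError("epochs, n_restarts and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise EvalError("learning_rate must be positive")


@dataclass
class MetricsReport:
    """Confusion counts and threshold metrics for one evaluated set."""

    TP: int
    FP: int
    TN: int
    FN: int
    ACC: float
    REC: float
    PRE: float
    F1: float
    AUC: float
    n: int
    undefined: tuple[str, ...] = ()  # metrics reported as 0 for a zero denominator

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "ACC": self.ACC, "REC": self.REC, "PRE": self.PRE,
            "F1": self.F1, "AUC": self.AUC, "n": self.n,
            "undefined": list(self.undefined),
        }


@dataclass
class AggregateReport:
    """Per-metric mean and 95% CI half-width over folds/repeats."""

    mean: dict[str, float]
    ci95: dict[str, float]
    folds: list[MetricsReport] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci95": self.ci95,
            "folds": [f.to_dict() for f in self.folds],
        }


# ---------------------------------------------------------------------------
# Metrics


def confusion_counts(labels, scores, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with the strict decision rule score > threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.shape != scores.shape:
        raise EvalError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise EvalError("labels must be binary")
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, fp, tn, fn


def compute_auc(labels, scores) -> float:
    """Rank-based ROC AUC: P(random positive outscores random negative), ties 1/2.

    Equivalent to trapezoidal integration of the ROC curve.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvalError("AUC requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """ACC/REC/PRE/F1 from the confusion counts plus rank-based AUC.

    A metric whose denominator is zero is reported as 0 and flagged in
    ``undefined`` so aggregate arithmetic stays total.
    """
    tp, fp, tn, fn = confusion_counts(labels, scores, threshold)
    n = tp + fp + tn + fn
    undefined: list[str] = []

    acc = (tp + tn) / n if n else 0.0
    if tp + fn:
        rec = tp / (tp + fn)
    else:
        rec, undefined = 0.0, undefined + ["REC"]
    if tp + fp:
        pre = tp / (tp + fp)
    else:
        pre, undefined = 0.0, undefined + ["PRE"]
    if pre + rec:
        f1 = 2.0 * pre * rec / (pre + rec)
    else:
        f1, undefined = 0.0, undefined + ["F1"]
    auc = compute_auc(labels, scores)
    return MetricsReport(
        TP=tp, FP=fp, TN=tn, FN=fn,
        ACC=acc, REC=rec, PRE=pre, F1=f1, AUC=auc,
        n=n, undefined=tuple(undefined),
    )


def aggregate(reports: list[MetricsReport]) -> AggregateReport:
    """Mean and 1.96 * SE/sqrt(n) half-width per metric over fold reports."""
    if len(reports) < 2:
        raise EvalError("aggregation needs at least 2 fold reports")
    mean: dict[str, float] = {}
    ci: dict[str, float] = {}
    for metric in ("ACC", "REC", "PRE", "F1", "AUC"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=np.float64)
        mean[metric] = float(vals.mean())
        ci[metric] = float(1.96 * vals.std(ddof=1) / np.sqrt(len(vals)))
    return AggregateReport(mean=mean, ci95=ci, folds=list(reports))


# ---------------------------------------------------------------------------
# Training


def _val_auc(params: ModelParams, val: EncodedBatch) -> float:
    return compute_auc(val.labels.astype(int), predict_proba(params, val))


def train_model(
    train: EncodedBatch,
    val: EncodedBatch,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    tcr_emb: EmbeddingTable,
    pep_emb: EmbeddingTable,
) -> tuple[ModelParams, pd.DataFrame]:
    """Train with independent restarts and return the best-validating model.

    Each restart re-initialises every weight (including random-origin
    embedding tables, which are redrawn) from a seed derived from
    ``tcfg.seed``, runs ``epochs`` of minibatch Adam on the mean BCE, and is
    scored by its final validation AUC; the best restart wins.  The returned
    history has one row per (restart, epoch) with the mean train loss and
    validation AUC.  A restart whose loss turns non-finite is discarded with
    a warning; losing all restarts is fatal.
    """
    if len(train) == 0 or len(val) == 0:
        raise EvalError("empty train or validation set")
    restart_seeds = np.random.default_rng(tcfg.seed).integers(
        0, 2**31 - 1, size=tcfg.n_restarts
    )
    best: tuple[float, ModelParams] | None = None
    rows = []
    for r, rseed in enumerate(restart_seeds):
        rseed = int(rseed)
        t_emb = (
            init_random_embeddings(tcr_emb.vocab, tcr_emb.dim, seed=rseed + 1)
            if tcr_emb.origin == "random"
            else tcr_emb
        )
        p_emb = (
            init_random_embeddings(pep_emb.vocab, pep_emb.dim, seed=rseed + 2)
            if pep_emb.origin == "random"
            else pep_emb
        )
        params = init_model(
            ModelConfig(**{**mcfg.__dict__, "seed": rseed}), t_emb, p_emb
        )
        opt = Adam(params, learning_rate=tcfg.learning_rate)
        rng = np.random.default_rng(rseed + 3)
        diverged = False
        try:
            for epoch in range(tcfg.epochs):
                order = rng.permutation(len(train))
                losses = []
                for start in range(0, len(train), tcfg.batch_size):
                    mb = train.subset(order[start : start + tcfg.batch_size])
                    loss, grads = loss_and_grads(params, mb, training=True, rng=rng)
                    if not np.isfinite(loss):
                        raise ModelError("non-finite loss")
                    opt.step(params, grads)
                    losses.append(loss)
                rows.append(
                    {
                        "restart": r,
                        "epoch": epoch,
                        "train_loss": float(np.mean(losses)),
                        "val_auc": _val_auc(params, val),
                    }
                )
        except ModelError:
            warnings.warn(f"restart {r} diverged and was discarded", stacklevel=2)
            diverged = True
        if diverged:
            continue
        auc = rows[-1]["val_auc"]
        if best is None or auc > best[0]:
            best = (auc, params)
    if best is None:
        raise EvalError("all restarts diverged")
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Task runner


def run_task(
    table: PairTable,
    split: SplitSpec,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    granularity: str = "residue",
    return_models: bool = False,
):
    """Encode, train and evaluate every fold/repeat of a split.

    Residue-granularity vocabularies are fixed; triplet vocabularies are
    built from the train-side sequences of each fold so no test token leaks
    into the vocabulary.  Index-set disjointness (and, for TPP-II, CDR3
    disjointness between train side and test side) is asserted before each
    fold.  Returns an :class:`AggregateReport` (plus the per-fold selected
    models when ``return_models``).
    """
    n = len(table)
    reports: list[MetricsReport] = []
    models: list[ModelParams] = []
    for fold_i, (tr, va, te) in enumerate(split.folds):
        tr, va, te = (np.asarray(x, dtype=np.intp) for x in (tr, va, te))
        if max(x.max(initial=-1) for x in (tr, va, te)) >= n:
            raise EvalError("split indices exceed table size")
        if (
            np.intersect1d(tr, va).size
            or np.intersect1d(tr, te).size
            or np.intersect1d(va, te).size
        ):
            raise EvalError(f"fold {fold_i}: index sets overlap")
        if split.task == "TPP-II":
            side = {table.records[i].cdr3 for i in np.concatenate([tr, va])}
            if side & {table.records[i].cdr3 for i in te}:
                raise EvalError(f"repeat {fold_i}: test CDR3 seen during training")

        train_recs = [table.records[i] for i in tr]
        if granularity == "triplet":
            corpus = sorted({r.cdr3 for r in train_recs})
            vocab_t = build_vocabulary("triplet", corpus)
            vocab_p = build_vocabulary("triplet", sorted({r.peptide for r in train_recs}))
        else:
            vocab_t = build_vocabulary("residue")
            vocab_p = build_vocabulary("residue")
        tcr_emb = init_random_embeddings(vocab_t, mcfg.embed_dim, seed=tcfg.seed)
        pep_emb = init_random_embeddings(vocab_p, mcfg.embed_dim, seed=tcfg.seed + 1)

        enc = lambda idx: encode_batch(  # noqa: E731
            [table.records[i] for i in idx], vocab_t, vocab_p
        )
        fold_tcfg = TrainConfig(
            epochs=tcfg.epochs,
            learning_rate=tcfg.learning_rate,
            batch_size=tcfg.batch_size,
            n_restarts=tcfg.n_restarts,
            seed=tcfg.seed + 1000 * fold_i,
        )
        params, _hist = train_model(
            enc(tr), enc(va), mcfg, fold_tcfg, tcr_emb, pep_emb
        )
        test_batch = enc(te)
        scores = predict_proba(params, test_batch)
        reports.append(
            compute_metrics(
                test_batch.labels.astype(int), scores, mcfg.decision_threshold
            )
        )
        if return_models:
            models.append(params)
    agg = aggregate(reports) if len(reports) >= 2 else AggregateReport(
        mean={m: getattr(reports[0], m) for m in ("ACC", "REC", "PRE", "F1", "AUC")},
        ci95={m: 0.0 for m in ("ACC", "REC", "PRE", "F1", "AUC")},
        folds=reports,
    )
    return (agg, models) if return_models else agg


# ---------------------------------------------------------------------------
# Attention export


def export_attention(
    params: ModelParams, records: list[PairRecord], record_ids: list | None = None
) -> pd.DataFrame:
    """Per-position attention weights aligned to the padded CDR3 tokens.

    Returns a tidy table with one row per (record, position):
    ``record_id, position, token, weight``; each record's weights sum to 1.
    """
    from .encoding import max_len_for, pad_or_truncate, tokenize

    batch = encode_batch(records, params.vocab_t, params.vocab_p)
    traces = forward(params, batch)
    L = max_len_for("cdr3", params.vocab_t.granularity)
    ids = record_ids if record_ids is not None else list(range(len(records)))
    rows = []
    for rid, rec, trace in zip(ids, records, traces):
        tokens = pad_or_truncate(
            tokenize(rec.cdr3, params.vocab_t.granularity), L, params.vocab_t.placeholder
        )
        for pos, (tok, w) in enumerate(zip(tokens, trace.attention.weights)):
            rows.append(
                {"record_id": rid, "position": pos, "token": tok, "weight": float(w)}
            )
    return pd.DataFrame(rows)
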