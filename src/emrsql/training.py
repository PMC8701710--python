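"""Teacher-forced maximum-likelihood training of the encoder-decoder.

The objective is the factorized sequence likelihood: the negative sum of
log-probabilities of the gold actions under the admissible-set-masked
distributions (value actions contribute log p_start + log p_end). Adam with
global-norm gradient clipping at 5.0 optimizes all parameters jointly;
model selection keeps the weights with the best validation logic-form
accuracy.

A reference deployment fine-tuning a large pretrained encoder would use a
learning rate of 1e-6 over ~100 epochs at batch size 8; the defaults here
target the small from-scratch backend on a CPU and are plain config fields,
never hard-coded.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .errors import EmrSqlError, InputError
from .grammar import (
    Action,
    SelectValue,
    action_from_json,
    action_to_json,
    productions,
)
from .linking import MarkedQuestion, link, tokenize
from .model import (
    ActionDistribution,
    ModelConfig,
    ModelParams,
    Vocab,
    collate,
    infer,
    preprocess_example,
    teacher_forced_loss,
)
from .schema import Database, DatabaseSchema, schema_from_dict, schema_to_dict
from .sqlgen import canonicalize

__all__ = [
    "TrainConfig",
    "TrainExample",
    "TrainResult",
    "sequence_loss",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (desk-scale defaults; see module docstring)."""

    learning_rate: float = 3e-3
    epochs: int = 18
    batch_size: int = 32
    clip_norm: float = 5.0
    max_actions: int = 128
    seed: int = 0
    val_every: int = 1
    val_limit: Optional[int] = 200  # questions per validation pass
    lr_decay: str = "cosine"  # "cosine" to 10% of base, or "none"
    early_stop_acc: Optional[float] = None  # stop once val acc reaches this

    def __post_init__(self):
        if min(self.learning_rate, self.epochs, self.batch_size,
               self.clip_norm, self.max_actions) <= 0:
            raise InputError("all training settings must be positive")


@dataclass
class TrainExample:
    """One question-SQL pair with its gold action serialization."""

    question: str
    sql: str
    marked_question: MarkedQuestion
    actions: list[Action]
    split: str = "train"

    def to_json(self) -> str:
        return json.dumps(
            {
                "question": self.question,
                "sql": self.sql,
                "actions": [action_to_json(a) for a in self.actions],
                "split": self.split,
            }
        )

    @classmethod
    def from_json(cls, line: str, schema: DatabaseSchema) -> "TrainExample":
        d = json.loads(line)
        mq = link(tokenize(d["question"]), schema)
        return cls(
            question=d["question"],
            sql=d["sql"],
            marked_question=mq,
            actions=[action_from_json(a) for a in d["actions"]],
            split=d.get("split", "train"),
        )


@dataclass
class TrainResult:
    params: ModelParams
    log: list[dict]
    best_val_acc: float
    best_epoch: int


def sequence_loss(
    gold: Sequence[Action], step_dists: Sequence[ActionDistribution]
) -> float:
    """Negative sum of gold-action log-probabilities for one sequence."""
    if len(gold) != len(step_dists):
        raise InputError("gold/step-distribution length mismatch")
    total = 0.0
    for action, dist in zip(gold, step_dists):
        if isinstance(action, SelectValue):
            if dist.kind != "value":
                raise EmrSqlError("gold value action at non-value frontier")
            starts = {r[0]: i for i, r in enumerate(dist.span_ranges)}
            ends = {r[1]: i for i, r in enumerate(dist.span_ranges)}
            if action.start not in starts or action.end not in ends:
                raise EmrSqlError("gold value span misaligned with spans")
            s, e = starts[action.start], ends[action.end]
            ps = float(dist.p_start[s])
            pe = float(dist.p_end(s)[e])
            if ps <= 0.0 or pe <= 0.0:
                raise EmrSqlError("gold value span outside admissible set")
            total -= np.log(ps) + np.log(pe)
        else:
            p = dist.prob(action)
            if p <= 0.0:
                raise EmrSqlError(
                    f"gold action {action!r} outside the admissible set"
                )
            total -= np.log(p)
    return float(total)


def _validation_acc(
    params: ModelParams,
    examples: Sequence[TrainExample],
    db: Optional[Database],
    limit: Optional[int],
) -> float:
    subset = examples[:limit] if limit else examples
    if not subset:
        return 0.0
    n_match = 0
    for ex in subset:
        try:
            pred = infer(ex.question, params.schema, db, params,
                         max_len=params.config.max_actions)
        except EmrSqlError:
            continue
        if canonicalize(pred) == canonicalize(ex.sql):
            n_match += 1
    return n_match / len(subset)


def train(
    corpus: Sequence[TrainExample],
    cfg: TrainConfig,
    params: ModelParams,
    val: Sequence[TrainExample] = (),
    db: Optional[Database] = None,
    verbose: bool = False,
    start_epoch: int = 0,
) -> TrainResult:
    """Optimize ``params`` in place; return the best-validation snapshot.

    Batches are bucketed by action-sequence length (less padding waste) and
    the bucket order reshuffled each epoch under the config seed, so a
    fixed seed reproduces the run exactly.
    """
    if not corpus:
        raise InputError("training corpus is empty")
    schema = params.schema
    rng = np.random.default_rng(cfg.seed)
    pre = [
        preprocess_example(ex.marked_question, ex.actions, schema,
                           params.vocab, params.config)
        for ex in corpus
    ]
    n_cols, n_tabs = len(schema.columns), len(schema.tables)
    order0 = np.argsort([len(p["steps"]) for p in pre], kind="stable")

    opt = ad.Adam(params.tensors, lr=cfg.learning_rate)
    log: list[dict] = []
    best_acc, best_epoch = -1.0, -1
    best_weights = params.copy_weights()
    for epoch in range(cfg.epochs):
        if cfg.lr_decay == "cosine":
            frac = epoch / max(cfg.epochs - 1, 1)
            opt.lr = cfg.learning_rate * (0.1 + 0.9 * 0.5 *
                                          (1 + np.cos(np.pi * frac)))
        # length-bucketed batches, shuffled batch order
        starts = np.arange(0, len(pre), cfg.batch_size)
        rng.shuffle(starts)
        epoch_loss, n_seen = 0.0, 0
        for s in starts:
            idx = order0[s : s + cfg.batch_size]
            batch = collate([pre[i] for i in idx], n_cols, n_tabs)
            opt.zero_grad()
            loss, per_example = teacher_forced_loss(params, batch)
            if not np.isfinite(loss.item()):
                raise EmrSqlError(
                    f"divergent loss at epoch {epoch}: {loss.item()!r}"
                )
            loss.backward()
            ad.clip_grads_(params.tensors, cfg.clip_norm)
            opt.step()
            epoch_loss += float(per_example.sum())
            n_seen += len(idx)
        mean_loss = epoch_loss / n_seen
        row = {"epoch": epoch + start_epoch, "train_loss": mean_loss,
               "val_acc_lf": ""}
        if val and (epoch + 1) % cfg.val_every == 0:
            acc = _validation_acc(params, val, db, cfg.val_limit)
            row["val_acc_lf"] = acc
            if acc > best_acc:
                best_acc, best_epoch = acc, epoch + start_epoch
                best_weights = params.copy_weights()
        log.append(row)
        if verbose:
            print(f"epoch {epoch}: loss {mean_loss:.4f} "
                  f"val_acc_lf {row['val_acc_lf']}", flush=True)
        if (cfg.early_stop_acc is not None and val
                and best_acc >= cfg.early_stop_acc):
            break
    if val:
        params.load_weights(best_weights)
    else:
        best_acc, best_epoch = 0.0, cfg.epochs - 1
    return TrainResult(params=params, log=log,
                       best_val_acc=max(best_acc, 0.0), best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(directory, result_or_params, train_cfg: TrainConfig = None,
                    log: list[dict] = None):
    """Write params.npz + config.json (+ training log CSV) to a directory."""
    os.makedirs(directory, exist_ok=True)
    params = (
        result_or_params.params
        if isinstance(result_or_params, TrainResult)
        else result_or_params
    )
    if log is None and isinstance(result_or_params, TrainResult):
        log = result_or_params.log
    np.savez(os.path.join(directory, "params.npz"),
             **{k: t.data for k, t in params.tensors.items()})
    meta = {
        "model_config": asdict(params.config),
        "train_config": asdict(train_cfg) if train_cfg else None,
        "grammar_fingerprint": params.grammar_fingerprint,
        "schema": schema_to_dict(params.schema),
        "vocab": json.loads(params.vocab.to_json()),
    }
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(meta, fh)
    if log:
        with open(os.path.join(directory, "log.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
            writer.writeheader()
            writer.writerows(log)


def load_checkpoint(directory) -> ModelParams:
    with open(os.path.join(directory, "config.json")) as fh:
        meta = json.load(fh)
    if meta["grammar_fingerprint"] != productions().fingerprint():
        raise InputError(
            "checkpoint grammar fingerprint does not match this build"
        )
    schema = schema_from_dict(meta["schema"])
    vocab = Vocab.from_json(json.dumps(meta["vocab"]))
    cfg = ModelConfig(**meta["model_config"])
    params = ModelParams.init(cfg, vocab, schema, seed=0)
    with np.load(os.path.join(directory, "params.npz")) as data:
        params.load_weights({k: data[k] for k in data.files})
    return params
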