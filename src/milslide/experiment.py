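"""Cohort management, label derivation, splits, training and evaluation.

The prediction task mirrors the standard slide-level molecular setup: a
continuous per-slide marker (e.g. FPKM gene expression) is binarized at the
cohort median ("high" vs "low" expressers), slides with too few tissue
patches are dropped, and the cohort is split 80/20 into train and test —
stratified by label and grouped by patient so no patient's slides span
splits. Models train one bag per micro-step with gradients accumulated over
several bags (the large-bag regime forces batch size 1), monitored by
validation AUROC with early stopping.

AUROC is computed as the Mann-Whitney rank statistic: the fraction of
(positive, negative) pairs in which the positive outscores the negative,
ties counted half. 0.5 is chance, 1.0 is perfect separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .errors import (DegenerateInputError, NumericError, ParameterError,
                     StratificationError, UndefinedMetricError)
from .mil import Bag, create_model
from .fixtures import BagSpec, make_bags

__all__ = [
    "TrainConfig",
    "TrainResult",
    "derive_labels",
    "filter_cohort",
    "split_cohort",
    "sample_bag",
    "auroc",
    "train_model",
    "evaluate",
    "split_bags",
    "run_witness_benchmark",
]


# ---------------------------------------------------------------------------
# cohort operations

def derive_labels(cohort: pd.DataFrame, marker_col: str = "marker_value"
                  ) -> pd.DataFrame:
    """Median-split binarization: label 1 iff marker strictly above the median."""
    values = cohort[marker_col].to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        raise ParameterError(f"{marker_col} contains missing values")
    med = float(np.median(values))
    labels = (values > med).astype(int)
    if labels.min() == labels.max():
        raise DegenerateInputError(
            "degenerate labels: median split leaves one class empty")
    out = cohort.copy()
    out["label"] = labels
    return out


def filter_cohort(cohort: pd.DataFrame, min_patches: int = 1000) -> pd.DataFrame:
    """Keep slides with strictly more than `min_patches` tissue patches."""
    kept = cohort[cohort["n_patches"] > min_patches].copy()
    if kept.empty:
        warnings.warn(f"no slide has more than {min_patches} patches")
    return kept.reset_index(drop=True)


def split_cohort(cohort: pd.DataFrame, test_fraction: float = 0.2,
                 k_folds: int | None = None, seed: int = 0,
                 group_col: str = "patient_id") -> pd.DataFrame:
    """Assign a split column, stratified by label and grouped by `group_col`.

    Proportional mode: each label stratum contributes round(test_fraction x
    stratum size) groups to the test set, remainder to train. K-fold mode:
    groups of each stratum are dealt round-robin into folds `fold_0..k-1`.
    All slides of one group (patient, or site with group_col='site') land in
    the same split.
    """
    if "label" not in cohort.columns:
        raise ParameterError("cohort has no labels; run derive_labels first")
    rng = np.random.default_rng(seed)
    # one row per group; group label = label of its first slide
    groups = cohort.groupby(group_col, sort=True)["label"].first()
    out = cohort.copy()
    out["split"] = ""
    for lab in sorted(groups.unique()):
        members = groups.index[groups == lab].to_numpy()
        if len(members) < 2 and k_folds is None:
            raise StratificationError(
                f"label class {lab} has fewer than 2 {group_col} groups")
        members = members[rng.permutation(len(members))]
        if k_folds is None:
            n_test = int(round(test_fraction * len(members)))
            test_groups = set(members[:n_test])
            assign = {g: ("test" if g in test_groups else "train")
                      for g in members}
        else:
            assign = {g: f"fold_{i % k_folds}" for i, g in enumerate(members)}
        out.loc[out[group_col].isin(assign), "split"] = \
            out.loc[out[group_col].isin(assign), group_col].map(assign)
    return out


def sample_bag(bag: Bag, n: int, seed: int = 0) -> Bag:
    """Uniform without-replacement subsample of min(n, N) instances.

    Selected indices are kept in their original order, so `n >= N` returns
    the bag unchanged. Deterministic given the seed.
    """
    if n < 1:
        raise ParameterError("sample size must be >= 1")
    N = bag.n_instances
    if n >= N:
        return bag
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(N, size=n, replace=False))
    return Bag(slide_id=bag.slide_id, H=bag.H[idx], coords=bag.coords[idx],
               label=bag.label)


# ---------------------------------------------------------------------------
# metric

def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) with half credit for ties."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: only one class present")
    ranks = rankdata(scores)           # average ranks handle ties -> 0.5 credit
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    """Trainer contract: one bag per micro-step, accumulated gradients,
    early stopping on validation AUROC."""

    method: str = "abmil"
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 1                # fixed: whole bags do not batch
    accumulate_grad_batches: int = 8
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    instances_per_bag: int | None = None
    seed: int = 0
    model_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.batch_size != 1:
            raise ParameterError("batch_size is fixed at 1 bag")
        if self.accumulate_grad_batches < 1:
            raise ParameterError("accumulate_grad_batches must be >= 1")


@dataclass
class TrainResult:
    model: object
    history: pd.DataFrame              # epoch, train_loss, val_auroc
    best_epoch: int
    best_val_auroc: float


def train_model(train_bags: list[Bag], val_bags: list[Bag] | None,
                config: TrainConfig, model=None) -> TrainResult:
    """Train a MIL head with gradient accumulation and early stopping.

    Per epoch: bags are shuffled (seeded), grouped into accumulation windows
    of `accumulate_grad_batches`; each window takes one optimizer step on
    the mean bag loss. With validation bags, validation AUROC is computed
    every epoch, training stops after `early_stop_patience` epochs without
    improvement, and the best-epoch parameters are restored. Without them
    (val_bags=None) the full epoch budget runs and the final parameters are
    kept.
    """
    if not train_bags:
        raise ParameterError("need a non-empty training bag list")
    d = train_bags[0].d
    if model is None:
        model = create_model(config.method, d=d, seed=config.seed,
                             **config.model_kwargs)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)

    best_auroc, best_epoch, best_params, wait = -np.inf, -1, None, 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_bags))
        epoch_losses = []
        k = config.accumulate_grad_batches
        for start in range(0, len(order), k):
            window = order[start:start + k]
            opt.zero_grad()
            for bi in window:
                bag = train_bags[bi]
                if config.instances_per_bag is not None:
                    bag = sample_bag(bag, config.instances_per_bag,
                                     seed=int(rng.integers(2 ** 31)))
                loss = model.loss(bag) * (1.0 / len(window))
                if not np.isfinite(loss.data):
                    raise NumericError(
                        f"non-finite loss at epoch {epoch}, slide {bag.slide_id}")
                loss.backward()
                epoch_losses.append(loss.item() * len(window))
            opt.step()
        if val_bags:
            val_scores = [model.predict(b).bag_prob for b in val_bags]
            val_auroc = auroc(val_scores, [b.label for b in val_bags])
        else:
            val_auroc = float("nan")
        rows.append({"epoch": epoch,
                     "train_loss": float(np.mean(epoch_losses)),
                     "val_auroc": val_auroc})
        if not val_bags:
            best_epoch = epoch
            continue
        if val_auroc > best_auroc:
            best_auroc, best_epoch, wait = val_auroc, epoch, 0
            best_params = model.state_arrays()
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break
    if best_params is not None:
        model.load_state_arrays(best_params)
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val_auroc=float(best_auroc))


def evaluate(model, bags: list[Bag]) -> tuple[np.ndarray, float]:
    """Score bags with a trained model; returns (bag probabilities, AUROC)."""
    scores = np.array([model.predict(b).bag_prob for b in bags])
    return scores, auroc(scores, [b.label for b in bags])


# ---------------------------------------------------------------------------
# witness-bag benchmark plumbing

def split_bags(bags: list[Bag], test_fraction: float = 0.2,
               val_fraction: float = 0.1, seed: int = 0
               ) -> tuple[list[Bag], list[Bag], list[Bag]]:
    """Stratified train/val/test partition of a list of labeled bags.

    The test set takes round(test_fraction x stratum) bags per class; the
    validation set is carved out of the remaining training bags the same way.
    """
    rng = np.random.default_rng(seed)
    labels = np.array([b.label for b in bags])
    train_idx, val_idx, test_idx = [], [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = idx[rng.permutation(len(idx))]
        n_test = int(round(test_fraction * len(idx)))
        n_val = int(round(val_fraction * (len(idx) - n_test)))
        test_idx.extend(idx[:n_test])
        val_idx.extend(idx[n_test:n_test + n_val])
        train_idx.extend(idx[n_test + n_val:])
    pick = lambda ids: [bags[i] for i in sorted(ids)]
    return pick(train_idx), pick(val_idx), pick(test_idx)


#: Per-method training settings for the frozen witness-bag benchmark. The
#: models are tiny and the bags short, so each method gets a fixed modest
#: epoch budget (no validation carve-out: a handful of validation bags gives
#: an AUROC too granular to select checkpoints by) with a learning rate and
#: weight decay that converge on a CPU in seconds to minutes per model.
BENCHMARK_PROTOCOL: dict[str, dict] = {
    "abmil": dict(max_epochs=20, learning_rate=1e-3, weight_decay=1e-3,
                  model_kwargs={"hidden": 64}),
    "dsmil": dict(max_epochs=10, learning_rate=1e-3, weight_decay=1e-2,
                  model_kwargs={"q": 32}),
    "transmil": dict(max_epochs=25, learning_rate=1e-3, weight_decay=1e-2,
                     model_kwargs={"token_dim": 64}),
    "tl": dict(max_epochs=10, learning_rate=1e-3, weight_decay=1e-2),
}


def run_witness_benchmark(methods=("abmil", "dsmil", "transmil", "tl"),
                          spec: BagSpec = BagSpec(), seeds=(0, 1, 2),
                          config_overrides: dict | None = None) -> pd.DataFrame:
    """Train each method on fresh witness bags per seed; report test AUROC.

    Per seed, 20% of the bags are held out (stratified) for testing and the
    rest train under :data:`BENCHMARK_PROTOCOL`. Returns a tidy frame
    (method, seed, test_auroc, best_epoch). The bags, splits and model
    initializations all derive from the given seeds, so the run is
    reproducible end to end.
    """
    rows = []
    for seed in seeds:
        bags, _, _ = make_bags(replace(spec, seed=seed))
        train, _, test = split_bags(bags, test_fraction=0.2, val_fraction=0.0,
                                    seed=seed)
        for method in methods:
            cfg_kwargs = dict(BENCHMARK_PROTOCOL[method])
            if config_overrides:
                cfg_kwargs.update(config_overrides)
            cfg = TrainConfig(method=method, seed=seed,
                              accumulate_grad_batches=8, **cfg_kwargs)
            result = train_model(train, None, cfg)
            _, test_auroc = evaluate(result.model, test)
            rows.append({"method": method, "seed": seed,
                         "test_auroc": test_auroc,
                         "best_epoch": result.best_epoch})
    return pd.DataFrame(rows)
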