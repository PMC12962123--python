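"""Time-resolved LDA decoding with leave-one-block-out cross-validation.

Two schemes are implemented:

* pairwise image decoding — for every unordered stimulus pair, a binary
  classifier per timepoint, trained on 11 blocks and tested on the held
  out block (12 folds); the mean over pairs indexes image specificity.
* class decoding with exemplar generalization — low vs high attribute
  classes; each fold holds out one exemplar of each class *and* one
  block, so above-chance accuracy requires generalization to novel
  stimuli.

The classifier is a two-class LDA with an analytically shrunk pooled
covariance (shrinkage toward scaled identity, OAS intensity), fitted
independently at every timepoint; all timepoints of a fold are solved in
one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .behavior import ClassSplit
from .containers import EpochSet


class SchedulingError(ValueError):
    pass


@dataclass
class DecodingTimecourse:
    """Accuracy per timepoint for one subject (or a group mean)."""

    times: np.ndarray
    accuracy: np.ndarray
    scheme: str
    chance: float = 0.5
    subject_stack: np.ndarray | None = None  # (n_subjects, n_times) for group views
    pair_accuracy: np.ndarray | None = None  # (n_pairs, n_times), pairwise scheme
    pair_ids: np.ndarray | None = None  # (n_pairs, 2) stimulus ids
    n_folds: int | None = None  # folds averaged per timepoint (class scheme)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.accuracy.shape != self.times.shape:
            raise ValueError("accuracy and times must align")


def oas_shrinkage(S: np.ndarray, n: int) -> np.ndarray:
    """Analytic shrinkage of covariance stack ``S`` (T, C, C) toward µI.

    The closed-form oracle-approximating intensity depends only on
    tr(S), tr(S^2), the sample count n and dimension C, and is clipped
    to [0, 1]."""
    S = np.asarray(S, dtype=float)
    T, C, _ = S.shape
    tr = np.einsum("tii->t", S)
    tr2 = np.einsum("tij,tij->t", S, S)
    mu = tr / C
    num = (1.0 - 2.0 / C) * tr2 + tr**2
    den = (n + 1.0 - 2.0 / C) * (tr2 - tr**2 / C)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, 1.0)
    rho = np.clip(rho, 0.0, 1.0)
    eye = np.eye(C)
    return (1 - rho)[:, None, None] * S + (rho * mu)[:, None, None] * eye[None]


def lda_fit(train: np.ndarray, labels: np.ndarray):
    """Fit per-timepoint shrinkage-LDA discriminants.

    ``train`` is trials x channels x timepoints (a single timepoint may
    be passed as trials x channels); ``labels`` is binary.  Returns
    ``(w, b)`` with ``w`` of shape (T, C): the model predicts class 1
    when ``x @ w[t] > b[t]`` — equivalently, when the class-1
    probability under the shared-covariance Gaussian model exceeds the
    class-0 probability (equal priors, balanced designs).
    """
    train = np.asarray(train, dtype=float)
    single = train.ndim == 2
    if single:
        train = train[:, :, None]
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    if min((~y).sum(), y.sum()) < 2:
        raise ValueError("need at least 2 training trials per class")
    n = train.shape[0]
    mu0 = train[~y].mean(axis=0)  # (C, T)
    mu1 = train[y].mean(axis=0)
    centered = train - np.where(y[:, None, None], mu1[None], mu0[None])
    S = np.einsum("nct,ndt->tcd", centered, centered) / (n - 2)
    S = oas_shrinkage(S, n)
    d = (mu1 - mu0).T  # (T, C)
    w = np.linalg.solve(S, d[:, :, None])[:, :, 0]  # (T, C)
    b = np.einsum("tc,ct->t", w, (mu0 + mu1) / 2.0)
    if single:
        return w[0], b[0]
    return w, b


def lda_predict(w: np.ndarray, b: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Predicted class (0/1) per trial and timepoint."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        return (X @ w > b).astype(int)
    return (np.einsum("nct,tc->nt", X, w) > b[None, :]).astype(int)


def _fold_accuracy(X: np.ndarray, y: np.ndarray, train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
    w, b = lda_fit(X[train_idx], y[train_idx])
    pred = lda_predict(w, b, X[test_idx])
    return (pred == y[test_idx].astype(int)[:, None]).mean(axis=0)


def cv_accuracy(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Leave-one-group-out CV accuracy per timepoint, averaged over folds."""
    groups = np.asarray(groups)
    folds = np.unique(groups)
    accs = [
        _fold_accuracy(X, y, np.flatnonzero(groups != g), np.flatnonzero(groups == g))
        for g in folds
    ]
    return np.mean(accs, axis=0)


def _check_block_design(epochs: EpochSet) -> None:
    counts = epochs.events.groupby(["block", "stimulus_id"]).size()
    n_blocks = epochs.events["block"].nunique()
    n_stims = epochs.events["stimulus_id"].nunique()
    if (counts != 1).any() or len(counts) != n_blocks * n_stims:
        bad = counts[counts != 1].index.tolist()[:5]
        raise SchedulingError(
            "each stimulus must appear exactly once per block; "
            f"{len(counts)} (block, stimulus) combinations for {n_blocks} x {n_stims}, offending: {bad}"
        )


def pairwise_image_decoding(epochs: EpochSet, store_pairs: bool = True) -> DecodingTimecourse:
    """Mean leave-one-block-out accuracy over all unordered stimulus pairs.

    Returns the pair-mean timecourse; with ``store_pairs`` the per-pair
    accuracy matrix (n_pairs x n_times) is retained — it doubles as the
    cross-validated-decoding neural RDM.
    """
    _check_block_design(epochs)
    stims = epochs.stimulus_ids()
    stim_col = epochs.events["stimulus_id"].to_numpy()
    block_col = epochs.events["block"].to_numpy()
    by_stim = {s: np.flatnonzero(stim_col == s) for s in stims}
    pairs = list(combinations(stims.tolist(), 2))
    T = epochs.n_times
    pair_acc = np.empty((len(pairs), T)) if store_pairs else None
    total = np.zeros(T)
    data = epochs.data.astype(np.float64, copy=False)
    for p, (i, j) in enumerate(pairs):
        idx = np.concatenate([by_stim[i], by_stim[j]])
        X = data[idx]
        y = stim_col[idx] == j
        acc = cv_accuracy(X, y, block_col[idx])
        total += acc
        if store_pairs:
            pair_acc[p] = acc
    mean = total / len(pairs)
    return DecodingTimecourse(
        times=epochs.times,
        accuracy=mean,
        scheme="pairwise_image",
        pair_accuracy=pair_acc,
        pair_ids=np.array(pairs) if pairs else None,
    )


def class_decoding(epochs: EpochSet, split: ClassSplit, pairing_seed: int = 0) -> DecodingTimecourse:
    """Exemplar-generalizing class decoding (low vs high attribute class).

    Low and high exemplars are paired after a seeded shuffle; each of
    the k exemplar pairs is held out in turn, crossed with each of the
    blocks (k x 12 folds).  Training uses the remaining k-1 exemplars
    per class in the 11 non-test blocks only, so test stimuli are never
    seen during training in any block.
    """
    _check_block_design(epochs)
    stim_col = epochs.events["stimulus_id"].to_numpy()
    block_col = epochs.events["block"].to_numpy()
    available = set(epochs.stimulus_ids().tolist())
    missing = (set(split.low_ids.tolist()) | set(split.high_ids.tolist())) - available
    if missing:
        raise SchedulingError(f"split stimuli missing from epochs: {sorted(missing)[:10]}")
    rng = np.random.default_rng(pairing_seed)
    low = rng.permutation(split.low_ids)
    high = rng.permutation(split.high_ids)
    blocks = np.unique(block_col)
    in_low = np.isin(stim_col, split.low_ids)
    in_high = np.isin(stim_col, split.high_ids)
    used = in_low | in_high
    y_all = in_high  # class 1 = high
    data = epochs.data.astype(np.float64, copy=False)

    T = epochs.n_times
    acc_sum = np.zeros(T)
    n_folds = 0
    for lo_ex, hi_ex in zip(low, high):
        ex_mask = (stim_col == lo_ex) | (stim_col == hi_ex)
        for b in blocks:
            test_idx = np.flatnonzero(ex_mask & (block_col == b))
            train_idx = np.flatnonzero(used & ~ex_mask & (block_col != b))
            acc_sum += _fold_accuracy(data, y_all, train_idx, test_idx)
            n_folds += 1
    return DecodingTimecourse(
        times=epochs.times,
        accuracy=acc_sum / n_folds,
        scheme="class_exemplar",
        n_folds=n_folds,
    )


def group_average(per_subject: list[DecodingTimecourse]) -> DecodingTimecourse:
    """Unweighted mean across subjects; the per-subject stack is retained
    for group-level inference."""
    if not per_subject:
        raise ValueError("no subjects to average")
    times = per_subject[0].times
    for tc in per_subject[1:]:
        if not np.array_equal(tc.times, times):
            raise ValueError("subjects must share an identical time grid")
    stack = np.stack([tc.accuracy for tc in per_subject])
    return DecodingTimecourse(
        times=times,
        accuracy=stack.mean(axis=0),
        scheme=per_subject[0].scheme,
        chance=per_subject[0].chance,
        subject_stack=stack,
    )
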