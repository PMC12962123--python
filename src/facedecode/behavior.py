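"""Rating aggregation, extreme-class selection, behavioral RDMs, reliability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RDM


class MissingDataError(ValueError):
    pass


def aggregate(table: pd.DataFrame, expected_ids=None) -> pd.DataFrame:
    """Group-mean rating per stimulus.

    Returns a frame with one row per stimulus: ``stimulus_id,
    mean_rating, n_raters, attribute``.  Raises if any expected stimulus
    is unrated.
    """
    if len(table) == 0:
        raise MissingDataError("empty rating table")
    grouped = table.groupby("stimulus_id")["rating"].agg(["mean", "count"]).reset_index()
    grouped.columns = ["stimulus_id", "mean_rating", "n_raters"]
    attrs = table["attribute"].unique()
    grouped["attribute"] = attrs[0] if len(attrs) == 1 else "mixed"
    if expected_ids is not None:
        missing = sorted(set(expected_ids) - set(grouped["stimulus_id"]))
        if missing:
            raise MissingDataError(f"stimuli without any rating: {missing[:20]}")
    return grouped.sort_values("stimulus_id").reset_index(drop=True)


@dataclass
class ClassSplit:
    """The k lowest- and k highest-rated stimuli for one attribute."""

    low_ids: np.ndarray
    high_ids: np.ndarray
    attribute: str = ""

    def __post_init__(self) -> None:
        self.low_ids = np.asarray(self.low_ids)
        self.high_ids = np.asarray(self.high_ids)
        if len(set(self.low_ids) & set(self.high_ids)):
            raise ValueError("low and high sets must be disjoint")
        if len(self.low_ids) != len(self.high_ids):
            raise ValueError("low and high sets must have equal size")

    @property
    def k(self) -> int:
        return len(self.low_ids)


def select_extremes(scores: pd.DataFrame, k: int) -> ClassSplit:
    """k smallest and k largest mean ratings; ties broken by ascending
    stimulus_id (deterministic)."""
    n = len(scores)
    if 2 * k > n:
        raise ValueError(f"cannot take 2x{k} extremes from {n} stimuli")
    ordered = scores.sort_values(["mean_rating", "stimulus_id"], kind="mergesort")
    low = ordered.head(k)["stimulus_id"].to_numpy()
    high = ordered.tail(k)["stimulus_id"].to_numpy()
    attr = scores["attribute"].iloc[0] if "attribute" in scores.columns else ""
    return ClassSplit(low_ids=np.sort(low), high_ids=np.sort(high), attribute=attr)


def behavioral_rdm(scores: pd.DataFrame) -> RDM:
    """Pairwise absolute difference of mean ratings (condensed layout)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 stimuli for an RDM")
    ordered = scores.sort_values("stimulus_id")
    means = ordered["mean_rating"].to_numpy(dtype=float)
    ids = ordered["stimulus_id"].to_numpy()
    iu, ju = np.triu_indices(len(means), k=1)
    return RDM(ids, np.abs(means[iu] - means[ju]), metric="abs_rating_difference")


def _half_rdm(table: pd.DataFrame, raters: np.ndarray) -> pd.DataFrame:
    sub = table[table["rater_id"].isin(raters)]
    return sub.groupby("stimulus_id")["rating"].mean()


def split_half_reliability(
    table: pd.DataFrame,
    n_iter: int = 100,
    seed: int | None = 0,
) -> dict:
    """Split-half reliability of the behavioral RDM.

    Raters are randomly divided into two equal groups; the Spearman
    correlation between the two group-averaged RDMs is recorded and the
    split repeated ``n_iter`` times.  Odd rater counts drop one rater at
    random per iteration.  Stimuli unrated within a half are excluded
    pairwise-complete for that iteration.
    """
    raters = np.unique(table["rater_id"].to_numpy())
    if len(raters) < 4:
        raise ValueError("split-half reliability needs at least 4 raters")
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(raters)
        if len(perm) % 2:
            perm = perm[:-1]  # drop one rater at random (perm is random)
        half = len(perm) // 2
        m1, m2 = _half_rdm(table, perm[:half]), _half_rdm(table, perm[half:])
        common = m1.index.intersection(m2.index)
        a, b = m1.loc[common].to_numpy(), m2.loc[common].to_numpy()
        iu, ju = np.triu_indices(len(common), k=1)
        rhos[it] = stats.spearmanr(np.abs(a[iu] - a[ju]), np.abs(b[iu] - b[ju])).statistic
    return {
        "rho": rhos,
        "mean": float(np.mean(rhos)),
        "median": float(np.median(rhos)),
        "range": (float(np.min(rhos)), float(np.max(rhos))),
    }


def correlate_attributes(valence: pd.DataFrame, sex: pd.DataFrame) -> tuple[float, float]:
    """Two-tailed Spearman correlation of mean valence vs mean sex ratings
    across stimuli (average ranks for ties)."""
    v = valence.sort_values("stimulus_id")
    s = sex.sort_values("stimulus_id")
    if not np.array_equal(v["stimulus_id"].to_numpy(), s["stimulus_id"].to_numpy()):
        raise ValueError("valence and sex scores must cover the same stimulus set")
    res = stats.spearmanr(v["mean_rating"].to_numpy(), s["mean_rating"].to_numpy())
    return float(res.statistic), float(res.pvalue)
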