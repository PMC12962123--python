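"""Representational similarity analysis and the noise ceiling.

Neural RDMs are built per timepoint, either from cross-validated
pairwise decoding accuracies (default, reusing the pairwise decoding
engine) or from correlation distances between per-condition mean
patterns.  Neural RDMs are compared to behavioral RDMs with Spearman
rank correlation, per subject, then averaged across the group.  The
leave-one-participant-out lower-bound noise ceiling rank-transforms
each subject's RDM and Spearman-correlates it with the mean
rank-transformed RDM of all other subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import RDM, EpochSet
from .decoding import pairwise_image_decoding

METRICS = ("cv_decoding", "corr_distance")


@dataclass
class RSATimecourse:
    times: np.ndarray
    rho: np.ndarray  # group mean per timepoint
    subject_stack: np.ndarray  # (n_subjects, n_times)
    attribute: str = ""
    subset: str = "all"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.subject_stack = np.atleast_2d(np.asarray(self.subject_stack, dtype=float))


def _corr_distance_condensed(patterns: np.ndarray) -> np.ndarray:
    """1 - Pearson r between condition patterns; condensed (i<j) order."""
    X = np.asarray(patterns, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    norm = np.where(norm == 0, 1.0, norm)
    R = (Xc / norm[:, None]) @ (Xc / norm[:, None]).T
    iu, ju = np.triu_indices(len(X), k=1)
    return 1.0 - R[iu, ju]


def neural_rdm_timecourse(epochs: EpochSet, metric: str = "cv_decoding") -> tuple[np.ndarray, np.ndarray]:
    """Condensed neural RDM at every timepoint.

    Returns ``(condition_ids, rdm_tc)`` where ``rdm_tc`` has shape
    (n_times, n_pairs) in condensed lexicographic order of the sorted
    condition ids.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    ids = epochs.stimulus_ids()
    if metric == "cv_decoding":
        tc = pairwise_image_decoding(epochs, store_pairs=True)
        return ids, tc.pair_accuracy.T.copy()
    stim_col = epochs.events["stimulus_id"].to_numpy()
    means = np.stack([epochs.data[stim_col == s].mean(axis=0) for s in ids])  # (n, C, T)
    T = epochs.n_times
    out = np.empty((T, len(ids) * (len(ids) - 1) // 2))
    for t in range(T):
        out[t] = _corr_distance_condensed(means[:, :, t])
    return ids, out


def neural_rdm(epochs: EpochSet, t_index: int, metric: str = "cv_decoding") -> RDM:
    """The neural RDM at a single timepoint."""
    ids, tc = neural_rdm_timecourse(epochs, metric=metric)
    return RDM(ids, tc[t_index], metric=metric)


def _spearman_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of A against b (vectorized)."""
    ra = rankdata(A, axis=1)
    rb = rankdata(b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum())
    denom = np.where(denom == 0, np.inf, denom)
    return (ra @ rb) / denom


def rsa_timecourse(
    subject_rdm_tcs: list[np.ndarray],
    behavioral: RDM,
    times: np.ndarray,
    condition_ids: np.ndarray,
    attribute: str = "",
    subset: str = "all",
) -> RSATimecourse:
    """Spearman correspondence between neural and behavioral RDMs.

    ``subject_rdm_tcs`` holds one (n_times, n_pairs) condensed array per
    subject with pairs ordered by the sorted ``condition_ids``.
    """
    ids = np.sort(np.asarray(condition_ids))
    if not np.array_equal(np.sort(behavioral.condition_ids), ids):
        extra = sorted(set(ids.tolist()) ^ set(behavioral.condition_ids.tolist()))
        raise ValueError(f"condition mismatch between neural and behavioral RDMs: {extra[:10]}")
    behav = behavioral if np.array_equal(behavioral.condition_ids, ids) else behavioral.subset(ids)
    stack = []
    for tc in subject_rdm_tcs:
        if tc.shape != (len(times), len(behav.condensed)):
            raise ValueError("subject RDM timecourse shape does not match times/conditions")
        stack.append(_spearman_rows(tc, behav.condensed))
    stack = np.stack(stack)
    return RSATimecourse(
        times=times,
        rho=stack.mean(axis=0),
        subject_stack=stack,
        attribute=attribute,
        subset=subset,
    )


def condensed_subset_indices(condition_ids: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Indices into a condensed vector selecting pairs within ``keep``."""
    ids = np.asarray(condition_ids)
    keep_set = set(np.asarray(keep).tolist())
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.array([(ids[a] in keep_set) and (ids[b] in keep_set) for a, b in zip(iu, ju)])
    return np.flatnonzero(mask)


def subset_rsa(
    subject_rdm_tcs: list[np.ndarray],
    behavioral: RDM,
    times: np.ndarray,
    condition_ids: np.ndarray,
    keep_ids: np.ndarray,
    attribute: str = "",
    subset: str = "subset",
) -> RSATimecourse:
    """RSA restricted to a condition subset (e.g., human faces only)."""
    keep = np.sort(np.asarray(keep_ids))
    if len(keep) < 2:
        raise ValueError("subset must keep at least 2 conditions")
    sel = condensed_subset_indices(np.sort(np.asarray(condition_ids)), keep)
    behav_sub = behavioral.subset(keep)
    sub_tcs = [tc[:, sel] for tc in subject_rdm_tcs]
    return rsa_timecourse(sub_tcs, behav_sub, times, keep, attribute=attribute, subset=subset)


def noise_ceiling_lower(subject_rdm_tcs: list[np.ndarray], times: np.ndarray) -> np.ndarray:
    """Leave-one-participant-out lower-bound noise ceiling per timepoint.

    Each subject's condensed RDM is rank-transformed; the subject is
    Spearman-correlated with the mean rank-transformed RDM of all other
    subjects, and the correlations are averaged across subjects.
    """
    S = len(subject_rdm_tcs)
    if S < 3:
        raise ValueError("noise ceiling needs at least 3 subjects")
    ranked = np.stack([rankdata(tc, axis=1) for tc in subject_rdm_tcs])  # (S, T, P)
    total = ranked.sum(axis=0)
    T = ranked.shape[1]
    out = np.zeros(T)
    for s in range(S):
        others_mean = (total - ranked[s]) / (S - 1)
        rho = np.array(
            [_spearman_rows(ranked[s, t][None, :], others_mean[t])[0] for t in range(T)]
        )
        out += rho
    return out / S
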