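"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

EVENT_COLUMNS = ["trial", "sequence", "block", "stimulus_id"]


def time_grid(lo_ms: float, hi_ms: float, sample_rate: float) -> np.ndarray:
    """Sample times (ms) of the stimulus-onset-aligned grid inside a window.

    The grid contains every integer multiple of the sample period
    ``1000 / sample_rate`` lying in ``[lo_ms, hi_ms]``; t = 0 is a grid
    point whenever the window straddles the onset.  At 256 Hz the window
    [-100, 1000] ms yields 282 samples spaced 3.90625 ms apart.
    """
    period = 1000.0 / sample_rate
    k_lo = int(np.ceil(lo_ms / period - 1e-9))
    k_hi = int(np.floor(hi_ms / period + 1e-9))
    if k_hi < k_lo:
        raise ValueError(f"window [{lo_ms}, {hi_ms}] ms contains no samples at {sample_rate} Hz")
    return np.arange(k_lo, k_hi + 1) * period


@dataclass
class EpochSet:
    """Per-subject epoched multichannel time series with event metadata.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Epoched signal in µV-scale arbitrary units.
    times : ndarray of ms, 0 at stimulus onset, uniformly spaced.
    sample_rate : sampling rate in Hz.
    channels : channel labels.
    events : DataFrame with one row per trial
        (columns ``trial, sequence, block, stimulus_id``).
    bad_channels : labels flagged (and interpolated) during preprocessing.
    """

    data: np.ndarray
    times: np.ndarray
    sample_rate: float
    channels: list[str]
    events: pd.DataFrame
    bad_channels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n_trials, n_channels, n_times = self.data.shape
        if len(self.channels) != n_channels:
            raise ValueError(f"{len(self.channels)} channel labels for {n_channels} channels")
        if len(self.times) != n_times:
            raise ValueError(f"{len(self.times)} time stamps for {n_times} samples")
        if len(self.events) != n_trials:
            raise ValueError(f"events has {len(self.events)} rows for {n_trials} trials")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events table missing columns {missing}")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("times must be strictly increasing and uniformly spaced")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def time_zero_index(self) -> int:
        idx = int(np.argmin(np.abs(self.times)))
        return idx

    def stimulus_ids(self) -> np.ndarray:
        return np.unique(self.events["stimulus_id"].to_numpy())


def condensed_index_pairs(n: int) -> np.ndarray:
    """The (i, j), i < j, pairs in lexicographic (condensed) order."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


@dataclass
class RDM:
    """Symmetric condition x condition dissimilarity structure.

    Stored as the condensed upper-triangle vector in lexicographic
    (i < j) order, the same layout as :func:`scipy.spatial.distance.pdist`.
    """

    condition_ids: np.ndarray
    condensed: np.ndarray
    metric: str = "unspecified"

    def __post_init__(self) -> None:
        self.condition_ids = np.asarray(self.condition_ids)
        self.condensed = np.asarray(self.condensed, dtype=float)
        n = len(self.condition_ids)
        expect = n * (n - 1) // 2
        if self.condensed.shape != (expect,):
            raise ValueError(
                f"condensed length {self.condensed.shape} does not match {n} conditions (expected {expect})"
            )

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_square(self) -> np.ndarray:
        return squareform(self.condensed, checks=False)

    @classmethod
    def from_square(cls, square: np.ndarray, condition_ids, metric: str = "unspecified") -> "RDM":
        square = np.asarray(square, dtype=float)
        if square.ndim != 2 or square.shape[0] != square.shape[1]:
            raise ValueError("square RDM must be a 2-D square matrix")
        if not np.allclose(square, square.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        return cls(np.asarray(condition_ids), squareform(square, checks=False), metric)

    def subset(self, keep_ids) -> "RDM":
        """Row/column-subset to the given condition ids (original order kept)."""
        keep = np.asarray(keep_ids)
        pos = {cid: i for i, cid in enumerate(self.condition_ids.tolist())}
        missing = [k for k in keep.tolist() if k not in pos]
        if missing:
            raise KeyError(f"conditions not in RDM: {missing[:10]}")
        idx = np.array([pos[k] for k in keep.tolist()])
        sq = self.to_square()[np.ix_(idx, idx)]
        return RDM(keep, squareform(sq, checks=False), self.metric)
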