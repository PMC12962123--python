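"""Bayes-factor time-series inference and latency estimation.

One-sample Bayes factors use a Jeffreys–Zellner–Siow setup: a Cauchy
prior (default scale 0.707) on the standardized effect size delta, with
the marginal likelihood of the observed t-statistic obtained by
integrating the noncentral-t density over the prior.  Interval nulls
follow the truncated-prior reading: the null hypothesis places the
(truncated, renormalized) Cauchy prior on delta inside ``[lo, hi]`` and
the alternative places it on the complement of the interval within the
admissible region (the half-line [0, inf) for one-sided tests, the full
line for two-sided tests); BF10 is the ratio of the two marginal
likelihoods.  A point null (``lo == hi``) reduces to the classic JZS
t-test Bayes factor.

Decisions require contiguity: strong evidence at a single timepoint is
inconclusive unless at least ``min_consecutive`` neighbouring samples
agree in direction.  Onset latency is the first post-stimulus timepoint
whose decision favors the alternative; confidence intervals come from a
percentile bootstrap over subjects with onsets re-derived per resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats

FAVOR_ALT, INCONCLUSIVE, FAVOR_NULL = 1, 0, -1

_GAUSS_NODES = 120  # per integration segment; integrands are smooth in delta
_T_CAP = 38.0  # |t| beyond this is clamped: scipy's noncentral-t pdf loses
               # convergence there and the Bayes factor is already decisive


@dataclass
class BFConfig:
    """Prior and decision settings for the Bayes-factor analyses."""

    prior_scale: float = 0.707
    null_interval: tuple[float, float] | None = (0.0, 0.5)
    direction: str = "above_chance_one_sided"  # or "two_sided"
    alt_threshold: float = 10.0
    null_threshold: float = 0.1
    min_consecutive: int = 2

    def validate(self) -> None:
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.null_interval is not None:
            lo, hi = self.null_interval
            if lo > hi:
                raise ValueError("null_interval bounds must be ordered")
        if self.direction not in ("above_chance_one_sided", "two_sided"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not np.isclose(self.alt_threshold * self.null_threshold, 1.0):
            raise ValueError("alt and null thresholds must be reciprocal")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")

    @classmethod
    def for_accuracy(cls) -> "BFConfig":
        """One-sided above-chance test, null effect sizes in [0, 0.5]."""
        return cls(null_interval=(0.0, 0.5), direction="above_chance_one_sided")

    @classmethod
    def for_correlation(cls) -> "BFConfig":
        """Two-sided test, null effect sizes in [-0.5, 0.5]."""
        return cls(null_interval=(-0.5, 0.5), direction="two_sided")


@dataclass
class BFSeries:
    times: np.ndarray
    bf10: np.ndarray
    direction: str
    decisions: np.ndarray  # FAVOR_ALT / INCONCLUSIVE / FAVOR_NULL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bf10 = np.asarray(self.bf10, dtype=float)
        self.decisions = np.asarray(self.decisions, dtype=int)


@dataclass
class LatencyEstimate:
    onset_ms: float | None
    peak_ms: float
    peak_value: float
    ci95_onset: tuple[float, float] | None
    ci95_peak: tuple[float, float]
    n_boot: int
    onset_defined: bool = True
    n_boot_onset_undefined: int = 0


# ---------------------------------------------------------------- quadrature

def _segments(lo: float | None, hi: float | None, scale: float):
    """Finite integration segments covering (lo, hi) after tan-substitution
    of infinite tails (Cauchy-scale parametrization keeps them smooth)."""
    if lo is None and hi is None:  # full line: split at 0
        return [("tail_lo", 0.0), ("tail_hi", 0.0)]
    if lo is None:
        return [("tail_lo", hi)]
    if hi is None:
        return [("tail_hi", lo)]
    return [("finite", (lo, hi))]


def _marginal(t: np.ndarray, df: int, sqrt_n: float, lo: float | None, hi: float | None,
              scale: float, nodes: int = _GAUSS_NODES) -> np.ndarray:
    """∫ f_nct(t; df, delta*sqrt_n) Cauchy(delta; 0, scale) ddelta over (lo, hi).

    Not normalized by the prior mass of the region.  Vectorized over t.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    x, w = leggauss(nodes)
    total = np.zeros_like(t)
    for kind, payload in _segments(lo, hi, scale):
        if kind == "finite":
            a, b = payload
            if b <= a:
                continue
            delta = 0.5 * (b - a) * x + 0.5 * (a + b)
            jac = 0.5 * (b - a) * np.ones_like(delta)
        elif kind == "tail_hi":
            a = payload
            u = 0.25 * np.pi * (x + 1.0)  # (0, pi/2)
            delta = a + scale * np.tan(u)
            jac = 0.25 * np.pi * scale / np.cos(u) ** 2
        else:  # tail_lo: (-inf, payload)
            b = payload
            u = 0.25 * np.pi * (x + 1.0)
            delta = b - scale * np.tan(u)
            jac = 0.25 * np.pi * scale / np.cos(u) ** 2
        dens = stats.cauchy.pdf(delta, scale=scale)
        like = stats.nct.pdf(t[:, None], df, delta[None, :] * sqrt_n)
        total = total + (like * (dens * jac * w)[None, :]).sum(axis=1)
    return total


def _prior_mass(lo: float | None, hi: float | None, scale: float) -> float:
    cdf = lambda v: stats.cauchy.cdf(v, scale=scale)
    a = cdf(lo) if lo is not None else 0.0
    b = cdf(hi) if hi is not None else 1.0
    return b - a


def bf10_from_t(t, n: int, cfg: BFConfig):
    """Interval-null (or point-null) JZS Bayes factor from a t-statistic.

    Vectorized over ``t``.  One-sided tests restrict the admissible
    effect sizes to [0, inf); the alternative region is the admissible
    complement of the null interval.
    """
    cfg.validate()
    if n < 2:
        raise ValueError("need n >= 2")
    t_arr = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), -_T_CAP, _T_CAP)
    df = n - 1
    sqrt_n = np.sqrt(n)
    r = cfg.prior_scale
    one_sided = cfg.direction == "above_chance_one_sided"
    domain_lo = 0.0 if one_sided else None

    if cfg.null_interval is None or cfg.null_interval[0] == cfg.null_interval[1]:
        # point null: classic JZS BF10 (prior truncated to the domain)
        num = _marginal(t_arr, df, sqrt_n, domain_lo, None, r)
        num /= _prior_mass(domain_lo, None, r)
        den = stats.t.pdf(t_arr, df)
        out = num / den
    else:
        lo, hi = cfg.null_interval
        if one_sided:
            lo = max(lo, 0.0)
            alt = _marginal(t_arr, df, sqrt_n, hi, None, r) / _prior_mass(hi, None, r)
            if lo > 0.0:
                alt_below = _marginal(t_arr, df, sqrt_n, 0.0, lo, r) / _prior_mass(0.0, lo, r)
                # alternative = admissible complement; combine by prior mass
                m_above = _prior_mass(hi, None, r)
                m_below = _prior_mass(0.0, lo, r)
                alt = (alt * m_above + alt_below * m_below) / (m_above + m_below)
            null = _marginal(t_arr, df, sqrt_n, lo, hi, r) / _prior_mass(lo, hi, r)
        else:
            m_lo = _prior_mass(None, lo, r)
            m_hi = _prior_mass(hi, None, r)
            alt = (
                _marginal(t_arr, df, sqrt_n, None, lo, r)
                + _marginal(t_arr, df, sqrt_n, hi, None, r)
            ) / (m_lo + m_hi)
            null = _marginal(t_arr, df, sqrt_n, lo, hi, r) / _prior_mass(lo, hi, r)
        out = alt / np.maximum(null, 1e-300)
    return out if np.ndim(t) else float(out[0])


def jzs_bf_onesample(values: np.ndarray, null_value: float, cfg: BFConfig) -> float:
    """Bayes factor that the population mean of ``values`` exceeds (or, for
    two-sided configs, differs from) ``null_value`` beyond the null interval.

    Zero sample variance is a documented limit: BF -> inf when the mean
    differs from the null value, and the t = 0 Bayes factor otherwise.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D sample with n >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    sd = v.std(ddof=1)
    if sd == 0:
        if v.mean() != null_value:
            return float("inf")
        return bf10_from_t(0.0, len(v), cfg)
    t = (v.mean() - null_value) / (sd / np.sqrt(len(v)))
    return bf10_from_t(t, len(v), cfg)


# ------------------------------------------------------------- time series

def _t_series(stack: np.ndarray, null_value: float) -> np.ndarray:
    stack = np.atleast_2d(stack)
    n = stack.shape[0]
    diff = stack.mean(axis=0) - null_value
    sd = stack.std(axis=0, ddof=1)
    t = np.zeros_like(diff)
    ok = sd > 0
    t[ok] = diff[ok] / (sd[ok] / np.sqrt(n))
    t[~ok & (diff > 0)] = np.inf
    t[~ok & (diff < 0)] = -np.inf
    return t


class _BFFromT:
    """BF10 as a function of t for fixed n — exact quadrature with a
    monotone interpolator fast path for bootstrap-sized workloads."""

    def __init__(self, n: int, cfg: BFConfig, t_range: tuple[float, float] = (-40.0, 40.0), grid: int = 321):
        self.n, self.cfg = n, cfg
        tg = np.linspace(*t_range, grid)
        self._tg = tg
        with np.errstate(over="ignore"):
            self._log_bf = np.log(np.maximum(bf10_from_t(tg, n, cfg), 1e-300))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        clipped = np.clip(t, self._tg[0], self._tg[-1])
        log_bf = np.interp(clipped, self._tg, self._log_bf)
        out = np.exp(log_bf)
        out = np.where(np.isposinf(t), np.inf, out)
        return out


def bf_timecourse(stack: np.ndarray, times: np.ndarray, null_value: float, cfg: BFConfig,
                  fast: bool = False) -> BFSeries:
    """Per-timepoint one-sample Bayes factors on a subject x time stack."""
    cfg.validate()
    stack = np.atleast_2d(np.asarray(stack, dtype=float))
    n = stack.shape[0]
    t = _t_series(stack, null_value)
    finite = np.isfinite(t)
    bf = np.empty_like(t)
    if fast:
        bf[finite] = _BFFromT(n, cfg)(t[finite])
    else:
        bf[finite] = bf10_from_t(t[finite], n, cfg)
    bf[~finite] = np.inf
    return BFSeries(times=times, bf10=bf, direction=cfg.direction, decisions=flag_reliable(bf, cfg))


def bf_paired_contrast(stack_a: np.ndarray, stack_b: np.ndarray, times: np.ndarray,
                       cfg: BFConfig | None = None) -> BFSeries:
    """Evidence that values for condition a exceed those for condition b:
    one-sample BF on the paired differences (a - b) against 0."""
    a = np.atleast_2d(np.asarray(stack_a, dtype=float))
    b = np.atleast_2d(np.asarray(stack_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"paired stacks must match; got {a.shape} vs {b.shape}")
    if cfg is None:
        cfg = BFConfig.for_accuracy()
    return bf_timecourse(a - b, times, 0.0, cfg)


def flag_reliable(bf10: np.ndarray, cfg: BFConfig) -> np.ndarray:
    """Contiguity-filtered decisions: strong evidence must persist for at
    least ``min_consecutive`` consecutive samples to count."""
    cfg.validate()
    bf10 = np.asarray(bf10, dtype=float)
    out = np.full(bf10.shape, INCONCLUSIVE, dtype=int)
    for value, mask in ((FAVOR_ALT, bf10 > cfg.alt_threshold), (FAVOR_NULL, bf10 < cfg.null_threshold)):
        run = 0
        for i, m in enumerate(mask):
            run = run + 1 if m else 0
            if run >= cfg.min_consecutive:
                out[i - run + 1 : i + 1] = value
    return out


def _onset_from_decisions(times: np.ndarray, decisions: np.ndarray) -> float | None:
    post = (times > 0) & (decisions == FAVOR_ALT)
    idx = np.flatnonzero(post)
    return float(times[idx[0]]) if len(idx) else None


def _peak(times: np.ndarray, mean_tc: np.ndarray) -> tuple[float, float]:
    post = times > 0
    idx = np.flatnonzero(post)
    k = idx[np.argmax(mean_tc[idx])]
    return float(times[k]), float(mean_tc[k])


def latency(
    stack: np.ndarray,
    times: np.ndarray,
    null_value: float,
    cfg: BFConfig,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> LatencyEstimate:
    """Onset and peak latency with percentile-bootstrap 95% CIs.

    Onset: first post-stimulus sample whose contiguity-filtered decision
    favors the alternative.  Peak: post-stimulus argmax of the group
    mean.  Bootstrap resamples subjects with replacement and re-derives
    the group mean, the Bayes-factor series, and both latencies per
    resample (Bayes factors via the fixed-n interpolator fast path).
    """
    cfg.validate()
    stack = np.atleast_2d(np.asarray(stack, dtype=float))
    times = np.asarray(times, dtype=float)
    n = stack.shape[0]
    series = bf_timecourse(stack, times, null_value, cfg)
    onset = _onset_from_decisions(times, series.decisions)
    peak_ms, peak_val = _peak(times, stack.mean(axis=0))

    rng = np.random.default_rng(seed)
    bf_fast = _BFFromT(n, cfg)
    onsets, peaks = [], []
    undefined = 0
    for _ in range(n_boot):
        res = stack[rng.integers(0, n, size=n)]
        t = _t_series(res, null_value)
        bf = np.where(np.isfinite(t), bf_fast(np.where(np.isfinite(t), t, 0.0)), np.inf)
        dec = flag_reliable(bf, cfg)
        o = _onset_from_decisions(times, dec)
        if o is None:
            undefined += 1
        else:
            onsets.append(o)
        peaks.append(_peak(times, res.mean(axis=0))[0])
    ci_peak = tuple(np.percentile(peaks, [2.5, 97.5])) if peaks else (np.nan, np.nan)
    ci_onset = tuple(np.percentile(onsets, [2.5, 97.5])) if onsets else None
    return LatencyEstimate(
        onset_ms=onset,
        peak_ms=peak_ms,
        peak_value=peak_val,
        ci95_onset=ci_onset,
        ci95_peak=(float(ci_peak[0]), float(ci_peak[1])),
        n_boot=n_boot,
        onset_defined=onset is not None,
        n_boot_onset_undefined=undefined,
    )
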