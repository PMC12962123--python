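"""Low-level stimulus controls: luminance, contrast, radial spatial
frequency bands, and two-group comparisons.

Spatial frequency content is quantified from the 2-D DFT amplitude
spectrum: components (DC excluded) are binned by integer radial
frequency, the distinct radial frequencies are median-split into a low
and a high band, and the radial profile (per-radius mean amplitude) is
averaged within each band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


def basic_stats(image: np.ndarray) -> tuple[float, float]:
    """Mean pixel intensity (luminance) and population SD (contrast)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError("expected a grayscale 2-D image")
    return float(image.mean()), float(image.std())


def radial_sf_bands(image: np.ndarray, use_power: bool = False) -> tuple[float, float]:
    """Mean low-band and high-band radial spatial-frequency content.

    ``use_power=True`` averages the power spectrum instead of the
    amplitude spectrum.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square 2-D image")
    n = image.shape[0]
    if n < 8:
        raise ValueError("image side must be at least 8 px")
    spectrum = np.abs(np.fft.fft2(image)) / image.size
    if use_power:
        spectrum = spectrum**2
    fx = np.fft.fftfreq(n) * n  # integer cycles per image
    radius = np.round(np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)).astype(int)
    r_flat, s_flat = radius.ravel(), spectrum.ravel()
    keep = r_flat > 0  # exclude DC: that's luminance, measured separately
    profile_sum = np.bincount(r_flat[keep], weights=s_flat[keep])
    profile_n = np.bincount(r_flat[keep])
    radii = np.nonzero(profile_n)[0]
    profile = profile_sum[radii] / profile_n[radii]
    cut = np.median(radii)
    low = profile[radii <= cut]
    high = profile[radii > cut]
    return float(low.mean()), float(high.mean())


def image_stat_table(images: dict[int, np.ndarray], use_power: bool = False) -> pd.DataFrame:
    rows = []
    for sid in sorted(images):
        lum, con = basic_stats(images[sid])
        lo, hi = radial_sf_bands(images[sid], use_power=use_power)
        rows.append((sid, lum, con, lo, hi))
    return pd.DataFrame(rows, columns=["stimulus_id", "luminance", "contrast", "low_sf", "high_sf"])


def load_images(directory: str | Path) -> dict[int, np.ndarray]:
    import imageio.v3 as iio

    directory = Path(directory)
    images = {}
    for f in sorted(directory.glob("stim_*.png")):
        sid = int(f.stem.split("_")[1])
        images[sid] = iio.imread(f)
    if not images:
        raise FileNotFoundError(f"no stim_*.png images in {directory}")
    return images


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    infinite: bool = False


def compare_groups(values_low: np.ndarray, values_high: np.ndarray) -> TTestResult:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2, two-tailed).

    Zero pooled variance: equal means give t = 0, p = 1; unequal means
    are flagged as an infinite t.
    """
    a = np.asarray(values_low, dtype=float)
    b = np.asarray(values_high, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=float(np.sign(diff)) * np.inf, df=df, p=0.0, infinite=True)
    from scipy import stats

    t = diff / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p))


def compare_split(stats_table: pd.DataFrame, split, measures=("luminance", "contrast", "low_sf", "high_sf")) -> pd.DataFrame:
    """Run the independent-samples comparisons for a low/high class split."""
    lo = stats_table[stats_table["stimulus_id"].isin(split.low_ids)]
    hi = stats_table[stats_table["stimulus_id"].isin(split.high_ids)]
    rows = []
    for m in measures:
        res = compare_groups(lo[m].to_numpy(), hi[m].to_numpy())
        rows.append((m, res.t, res.df, res.p, res.infinite))
    return pd.DataFrame(rows, columns=["measure", "t", "df", "p", "infinite"])
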