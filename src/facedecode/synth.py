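"""Synthetic rating tables, stimulus images, and epoched EEG with ground truth.

The generator emulates the structure of a rapid serial visual
presentation face-EEG experiment: 900 square grayscale stimuli (840
human faces, 60 non-face images), two 9-point rating dimensions
(emotional valence and perceived masculinity) with a small negative
latent correlation, a 72-sequence x 150-trial presentation schedule in
which every 6-sequence block shows each stimulus exactly once, and
epoched 64-channel EEG at 256 Hz spanning -100..1000 ms around onset.

Evoked signal model (per trial, channel c, time t, stimulus s):

    x = noise + a_img * P_img[s, c] * g_img(t)
              + sum_attr a_attr * z_attr[s] * p_attr[c] * g_attr(t)

where ``noise`` is spatially mixed Gaussian noise, ``P_img`` are fixed
per-stimulus patterns (image specificity), ``z_attr`` is the stimulus's
standardized latent attribute value (so the class signal scales with the
rated attribute, and pairwise neural dissimilarity grows with the rating
gap), and each temporal gate ``g`` is zero before its onset, rises as a
half-Gaussian to its peak, and then decays exponentially.  Pre-stimulus
samples therefore contain noise only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, time_grid

ATTRIBUTES = ("valence", "sex")


class ConfigError(ValueError):
    pass


class CoverageError(ValueError):
    """Raised when the rater design cannot cover every stimulus."""


@dataclass
class ClassEffect:
    """Timing and strength of one attribute's injected evoked component.

    onset_ms/peak_ms: where the temporal gate turns on and reaches 1.
    amplitude: pattern scale in noise-SD units (0 disables the effect).
    decay_tau_ms: exponential decay constant after the peak.
    spatial_pattern_seed: seeds the fixed across-channel pattern.
    """

    onset_ms: float = 80.0
    peak_ms: float = 120.0
    amplitude: float = 1.0
    decay_tau_ms: float = 150.0
    spatial_pattern_seed: int = 11

    def validate(self) -> None:
        if self.onset_ms < 0:
            raise ConfigError(f"class-effect onset must be >= 0 ms, got {self.onset_ms}")
        if self.onset_ms >= self.peak_ms:
            raise ConfigError(
                f"class-effect onset ({self.onset_ms} ms) must precede peak ({self.peak_ms} ms)"
            )


@dataclass
class ImageConfig:
    """Controls for the synthetic stimulus images (8-bit grayscale, square)."""

    size: int = 64
    class_luminance: dict = field(default_factory=lambda: {"human": 118.0, "nonhuman": 112.0})
    class_contrast: dict = field(default_factory=lambda: {"human": 40.0, "nonhuman": 40.0})
    class_lowfreq_amplitude: dict = field(default_factory=lambda: {"human": 0.0, "nonhuman": 0.0})
    lowfreq_cycles: int = 3

    def validate(self) -> None:
        if self.size < 32:
            raise ConfigError(f"image size must be >= 32 px, got {self.size}")


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    Defaults mirror the emulated experiment: 900 stimuli (840 human),
    60 valence raters and 72 sex raters each rating 300 stimuli on a
    1-9 scale, 12 presentations of every stimulus laid out as 72
    sequences x 150 trials with 6-sequence blocks, 40 subjects, 64
    channels at 256 Hz, epochs from -100 to 1000 ms.
    """

    n_stimuli: int = 900
    n_human: int = 840
    n_raters_valence: int = 60
    n_raters_sex: int = 72
    ratings_per_rater: int = 300
    latent_correlation: float = -0.1
    latent_scale: float = 1.8
    rater_noise_sd: float = 1.0
    n_subjects: int = 40
    n_channels: int = 64
    sample_rate: float = 256.0
    epoch_window: tuple[float, float] = (-100.0, 1000.0)
    trials_per_sequence: int = 150
    sequences_per_block: int = 6
    n_blocks: int = 12
    class_effect: dict = field(
        default_factory=lambda: {
            "valence": ClassEffect(onset_ms=80.0, peak_ms=120.0, amplitude=1.0, spatial_pattern_seed=11),
            "sex": ClassEffect(onset_ms=110.0, peak_ms=150.0, amplitude=1.0, spatial_pattern_seed=12),
        }
    )
    image_effect_amplitude: float = 0.5
    image_effect_onset_ms: float = 50.0
    image_effect_peak_ms: float = 100.0
    channel_cov_mixing: float = 0.5
    noise_sd: float = 1.0
    images: ImageConfig = field(default_factory=ImageConfig)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_stimuli": self.n_stimuli,
            "n_human": self.n_human,
            "n_raters_valence": self.n_raters_valence,
            "n_raters_sex": self.n_raters_sex,
            "ratings_per_rater": self.ratings_per_rater,
            "n_subjects": self.n_subjects,
            "n_channels": self.n_channels,
            "trials_per_sequence": self.trials_per_sequence,
            "sequences_per_block": self.sequences_per_block,
            "n_blocks": self.n_blocks,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if not -1 < self.latent_correlation < 1:
            raise ConfigError("latent_correlation must lie in (-1, 1)")
        if self.n_human > self.n_stimuli:
            raise ConfigError("n_human cannot exceed n_stimuli")
        lo, hi = self.epoch_window
        if not (lo < 0 < hi):
            raise ConfigError(f"epoch_window must straddle stimulus onset, got {self.epoch_window}")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        for eff in self.class_effect.values():
            eff.validate()
        if self.image_effect_onset_ms >= self.image_effect_peak_ms:
            raise ConfigError("image-effect onset must precede its peak")
        self.images.validate()

    @property
    def n_sequences(self) -> int:
        return self.sequences_per_block * self.n_blocks

    @classmethod
    def desk_scale(cls, **overrides) -> "SimConfig":
        """A reduced design for laptop-scale runs and tests.

        20 stimuli (18 human), 4 subjects, 16 channels, 12 blocks of
        2 sequences x 10 trials, epochs -100..400 ms at 256 Hz.
        """
        base = dict(
            n_stimuli=20,
            n_human=18,
            n_raters_valence=12,
            n_raters_sex=12,
            ratings_per_rater=15,
            n_subjects=4,
            n_channels=16,
            epoch_window=(-100.0, 400.0),
            trials_per_sequence=10,
            sequences_per_block=2,
            n_blocks=12,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Everything the generator injected, for parameter-recovery checks."""

    onset_ms: dict
    peak_ms: dict
    amplitude: dict
    class_patterns: dict
    image_patterns: np.ndarray
    latent: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "onset_ms": self.onset_ms,
                "peak_ms": self.peak_ms,
                "amplitude": self.amplitude,
                "class_patterns": {k: v.tolist() for k, v in self.class_patterns.items()},
                "image_patterns": self.image_patterns.tolist(),
                "latent": self.latent.to_dict(orient="list"),
            }
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


def _structural_rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # shared across subjects: stimulus-driven structure depends only on cfg.seed
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def make_catalog(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Stimulus catalog: id, category, and latent valence/masculinity.

    Latents are standard bivariate normal with the configured correlation.
    """
    cfg.validate()
    if rng is None:
        rng = _structural_rng(cfg, 0)
    rho = cfg.latent_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    latents = rng.multivariate_normal([0.0, 0.0], cov, size=cfg.n_stimuli)
    category = np.array(
        ["human"] * cfg.n_human + ["nonhuman"] * (cfg.n_stimuli - cfg.n_human)
    )
    return pd.DataFrame(
        {
            "stimulus_id": np.arange(cfg.n_stimuli),
            "category": category,
            "latent_valence": latents[:, 0],
            "latent_sex": latents[:, 1],
        }
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_ratings(
    catalog: pd.DataFrame,
    cfg: SimConfig,
    attribute: str,
    rng: np.random.Generator | None = None,
    max_resample: int = 1000,
) -> pd.DataFrame:
    """Long-format rating table for one attribute.

    Each rater scores ``ratings_per_rater`` stimuli drawn uniformly
    without replacement; subsets are rejection-resampled until every
    stimulus is rated at least once.  A rating is the latent value
    affine-mapped onto the 9-point scale (midpoint 5), plus Gaussian
    rater noise, clipped to [1, 9] and rounded half-away-from-zero.
    """
    if attribute not in ATTRIBUTES:
        raise ValueError(f"attribute must be one of {ATTRIBUTES}, got {attribute!r}")
    cfg.validate()
    n_raters = cfg.n_raters_valence if attribute == "valence" else cfg.n_raters_sex
    n_stim = len(catalog)
    if cfg.ratings_per_rater > n_stim:
        raise ConfigError("ratings_per_rater cannot exceed the number of stimuli")
    if n_raters * cfg.ratings_per_rater < n_stim:
        raise CoverageError(
            f"{n_raters} raters x {cfg.ratings_per_rater} ratings cannot cover {n_stim} stimuli"
        )
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(1, ATTRIBUTES.index(attribute)))
        )
    latent = catalog[f"latent_{attribute}"].to_numpy()
    ids = catalog["stimulus_id"].to_numpy()

    for _ in range(max_resample):
        subsets = [rng.choice(n_stim, size=cfg.ratings_per_rater, replace=False) for _ in range(n_raters)]
        covered = np.zeros(n_stim, dtype=bool)
        for s in subsets:
            covered[s] = True
        if covered.all():
            break
    else:  # pragma: no cover - essentially impossible at sane configs
        raise CoverageError("could not cover every stimulus after resampling")

    rows = []
    for rater, subset in enumerate(subsets):
        raw = 5.0 + cfg.latent_scale * latent[subset]
        if cfg.rater_noise_sd > 0:
            raw = raw + rng.normal(0.0, cfg.rater_noise_sd, size=len(subset))
        rating = _round_half_away(np.clip(raw, 1.0, 9.0))
        rows.append(
            pd.DataFrame(
                {
                    "stimulus_id": ids[subset],
                    "rater_id": rater,
                    "attribute": attribute,
                    "rating": rating.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_images(
    catalog: pd.DataFrame,
    cfg: SimConfig,
    out_dir: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> dict[int, np.ndarray]:
    """Square 8-bit grayscale images with class-controllable statistics.

    Per class the config sets mean luminance, pixel-intensity SD
    (white-noise texture), and the amplitude of an additive low-spatial-
    frequency horizontal sinusoid.  Returns ``{stimulus_id: array}``;
    if ``out_dir`` is given, also writes ``stim_<id>.png`` files.
    """
    cfg.validate()
    icfg = cfg.images
    if rng is None:
        rng = _structural_rng(cfg, 2)
    size = icfg.size
    xx = np.arange(size) / size
    sinus = np.sin(2 * np.pi * icfg.lowfreq_cycles * xx)[None, :] * np.ones((size, 1))
    images: dict[int, np.ndarray] = {}
    for _, row in catalog.iterrows():
        cat = row["category"]
        base = icfg.class_luminance[cat]
        contrast = icfg.class_contrast[cat]
        lf = icfg.class_lowfreq_amplitude[cat]
        img = base + contrast * rng.standard_normal((size, size)) + lf * sinus
        images[int(row["stimulus_id"])] = np.clip(img, 0, 255).astype(np.uint8)
    if out_dir is not None:
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, img in images.items():
            iio.imwrite(out_dir / f"stim_{sid:04d}.png", img)
    return images


def build_schedule(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trial schedule: 72 sequences x 150 trials in 6-sequence blocks.

    Every block is an independent random permutation of the full
    catalog, chopped into ``sequences_per_block`` sequences, so each
    stimulus appears exactly once per block and ``n_blocks`` times in
    total (12 presentations, 10,800 trials at default scale).
    """
    cfg.validate()
    per_block = cfg.trials_per_sequence * cfg.sequences_per_block
    if per_block != cfg.n_stimuli:
        raise ConfigError(
            f"trials_per_sequence x sequences_per_block = {per_block} must equal n_stimuli = {cfg.n_stimuli}"
        )
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(3,)))
    rows = []
    trial = 0
    for block in range(cfg.n_blocks):
        order = rng.permutation(cfg.n_stimuli)
        for s_in_block in range(cfg.sequences_per_block):
            seq = block * cfg.sequences_per_block + s_in_block
            chunk = order[s_in_block * cfg.trials_per_sequence : (s_in_block + 1) * cfg.trials_per_sequence]
            for stim in chunk:
                rows.append((trial, seq, block, int(stim)))
                trial += 1
    return pd.DataFrame(rows, columns=["trial", "sequence", "block", "stimulus_id"])


def response_gate(times_ms: np.ndarray, onset_ms: float, peak_ms: float,
                  decay_tau_ms: float = 150.0) -> np.ndarray:
    """Temporal gate: 0 before onset, half-Gaussian rise to 1 at the peak,
    exponential decay afterwards.  The rise SD is (peak - onset) / 3 so the
    gate is ~1% of its maximum at the onset sample."""
    t = np.asarray(times_ms, dtype=float)
    sigma = (peak_ms - onset_ms) / 3.0
    gate = np.zeros_like(t)
    rise = (t >= onset_ms) & (t <= peak_ms)
    gate[rise] = np.exp(-0.5 * ((t[rise] - peak_ms) / sigma) ** 2)
    fall = t > peak_ms
    gate[fall] = np.exp(-(t[fall] - peak_ms) / decay_tau_ms)
    return gate


def simulate_epochs(
    catalog: pd.DataFrame,
    schedule: pd.DataFrame,
    cfg: SimConfig,
    subject_seed: int,
) -> tuple[EpochSet, GroundTruth]:
    """Epoched EEG for one subject plus the injected ground truth.

    Noise is spatially mixed across channels; evoked components follow
    the module docstring's signal model.  Identical seeds give
    bit-identical output.
    """
    cfg.validate()
    if not set(schedule["stimulus_id"]).issubset(set(catalog["stimulus_id"])):
        raise ConfigError("schedule references stimuli missing from the catalog")
    rng = np.random.default_rng(subject_seed)
    times = time_grid(*cfg.epoch_window, cfg.sample_rate)
    n_trials = len(schedule)
    C, T = cfg.n_channels, len(times)

    # subject-independent structure
    mix_rng = _structural_rng(cfg, 4)
    m = cfg.channel_cov_mixing
    mixing = (1 - m) * np.eye(C) + m * mix_rng.standard_normal((C, C)) / np.sqrt(C)
    img_rng = _structural_rng(cfg, 5)
    image_patterns = img_rng.standard_normal((len(catalog), C))
    class_patterns = {}
    for attr, eff in cfg.class_effect.items():
        p_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(6, eff.spatial_pattern_seed)))
        pat = p_rng.standard_normal(C)
        class_patterns[attr] = pat / np.linalg.norm(pat) * np.sqrt(C)

    noise = rng.standard_normal((n_trials, C, T)).astype(np.float32)
    data = np.einsum("cd,ndt->nct", mixing.astype(np.float32), noise) * np.float32(cfg.noise_sd)

    stim = schedule["stimulus_id"].to_numpy()
    id_to_row = {sid: i for i, sid in enumerate(catalog["stimulus_id"].to_numpy())}
    stim_rows = np.array([id_to_row[s] for s in stim])

    if cfg.image_effect_amplitude != 0:
        g_img = response_gate(times, cfg.image_effect_onset_ms, cfg.image_effect_peak_ms)
        data += (
            np.float32(cfg.image_effect_amplitude)
            * image_patterns[stim_rows][:, :, None].astype(np.float32)
            * g_img[None, None, :].astype(np.float32)
        )

    latent_z = {}
    for attr, eff in cfg.class_effect.items():
        z = catalog[f"latent_{attr}"].to_numpy()
        z = (z - z.mean()) / z.std()
        latent_z[attr] = z
        if eff.amplitude == 0:
            continue
        gate = response_gate(times, eff.onset_ms, eff.peak_ms, eff.decay_tau_ms)
        data += (
            np.float32(eff.amplitude)
            * z[stim_rows][:, None, None].astype(np.float32)
            * class_patterns[attr][None, :, None].astype(np.float32)
            * gate[None, None, :].astype(np.float32)
        )

    channels = [f"CH{i:02d}" for i in range(C)]
    epochs = EpochSet(
        data=data,
        times=times,
        sample_rate=cfg.sample_rate,
        channels=channels,
        events=schedule.reset_index(drop=True),
    )
    truth = GroundTruth(
        onset_ms={a: e.onset_ms for a, e in cfg.class_effect.items()},
        peak_ms={a: e.peak_ms for a, e in cfg.class_effect.items()},
        amplitude={a: e.amplitude for a, e in cfg.class_effect.items()},
        class_patterns=class_patterns,
        image_patterns=image_patterns,
        latent=catalog[["stimulus_id", "latent_valence", "latent_sex"]].copy(),
    )
    return epochs, truth


def null_config(cfg: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of ``cfg`` (desk scale by default) with all evoked
    amplitudes set to zero — the signal-free calibration condition."""
    if cfg is None:
        cfg = SimConfig.desk_scale(**overrides)
    effects = {a: replace(e, amplitude=0.0) for a, e in cfg.class_effect.items()}
    return replace(cfg, class_effect=effects, image_effect_amplitude=0.0)


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    return d
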