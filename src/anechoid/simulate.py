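"""Ground-truth synthetic data: anechoic mixtures and gait-like marker fixtures.

The mixture generator emulates the statistical structure of joint-angle
recordings from a combined walk-and-reach task: every channel is a weighted
superposition of a small number of shared temporal sources, each reaching
the channel with its own circular time delay, plus white Gaussian noise.
Two stereotypical source shapes are provided -- a single bell-shaped bump
(the discrete, goal-directed component) and a periodic waveform with two
peaks per cycle (the rhythmic, locomotor component).  Per-trial delays are
drawn from Gaussian distributions around per-channel-group means.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from anechoid.io import GroundTruth, TrajectorySet


def make_discrete_source(n_samples: int, center: float = 0.5, width: float = 0.1) -> np.ndarray:
    """Unit-peak bell-shaped (Gaussian) bump.

    Parameters
    ----------
    center, width : float
        Peak position and bump width (two Gaussian sigmas), both as
        fractions of the cycle.  The bump must decay to <= 1e-3 of its
        peak at the window boundary, which bounds how wide or off-centre
        it may be.
    """
    if not 0.0 < width < 1.0:
        raise ValueError("width must lie in (0, 1)")
    if not 0.0 <= center <= 1.0:
        raise ValueError("center must lie in [0, 1]")
    u = np.arange(n_samples) / n_samples
    bump = np.exp(-0.5 * ((u - center) / (width / 2.0)) ** 2)
    if max(bump[0], bump[-1]) > 1e-3:
        raise ValueError("bump does not decay at the window boundary; reduce width or re-centre")
    return bump


def make_rhythmic_source(n_samples: int, phase: float = 0.0, peak_ratio: float = 0.45, sharpness: float = 3.0) -> np.ndarray:
    """Periodic waveform with exactly two local maxima per cycle, unit max.

    Built from two antipodal von-Mises-shaped lobes,
    ``exp(sharpness * (cos(theta) - 1))``, scaled so the second peak is
    ``peak_ratio`` times the first.  ``phase`` circularly shifts the cycle
    (fraction of the period).  Moderate ``sharpness`` keeps the waveform
    band-limited (>= 99.9 % of spectral energy within harmonics |k| <= 10).
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if peak_ratio <= 0:
        raise ValueError("peak_ratio must be > 0")
    theta = 2.0 * np.pi * (np.arange(n_samples) / n_samples - phase)
    lobe1 = np.exp(sharpness * (np.cos(theta) - 1.0))
    lobe2 = np.exp(sharpness * (np.cos(theta - np.pi) - 1.0))
    wave = lobe1 + peak_ratio * lobe2
    return wave / wave.max()


@dataclass
class SourceSpec:
    """One ground-truth source: ``kind`` is 'discrete' or 'rhythmic'."""

    kind: str
    params: dict = field(default_factory=dict)

    def render(self, n_samples: int) -> np.ndarray:
        if self.kind == "discrete":
            return make_discrete_source(n_samples, **self.params)
        if self.kind == "rhythmic":
            return make_rhythmic_source(n_samples, **self.params)
        raise ValueError(f"unknown source kind {self.kind!r}")


@dataclass
class ScenarioConfig:
    """Full description of a synthetic anechoic-mixture scenario.

    ``weight_pattern`` has one row per channel *group* and one column per
    source; each trial contributes ``n_channel_groups`` channels (so the
    data matrix has ``n_trials * n_channel_groups`` rows).  ``delay_mean``
    and ``delay_sd`` are per (group, source), in seconds.  ``noise_sigma``
    is the absolute SD of the additive Gaussian noise.
    """

    source_specs: list[SourceSpec]
    weight_pattern: np.ndarray
    delay_mean: np.ndarray
    delay_sd: np.ndarray
    group_labels: list[str] | None = None
    n_trials: int = 40
    n_samples: int = 350
    sample_rate: float = 120.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.weight_pattern = np.asarray(self.weight_pattern, dtype=float)
        self.delay_mean = np.asarray(self.delay_mean, dtype=float)
        self.delay_sd = np.asarray(self.delay_sd, dtype=float)
        g, n = self.weight_pattern.shape
        if len(self.source_specs) != n:
            raise ValueError("weight_pattern column count must equal the number of sources")
        if self.delay_mean.shape != (g, n) or self.delay_sd.shape != (g, n):
            raise ValueError("delay_mean/delay_sd must match weight_pattern's shape")
        if (self.delay_sd < 0).any() or self.noise_sigma < 0:
            raise ValueError("delay_sd and noise_sigma must be >= 0")
        if self.n_samples < 16:
            raise ValueError("n_samples must be >= 16")
        if self.group_labels is None:
            self.group_labels = [f"g{i}" for i in range(g)]
        elif len(self.group_labels) != g:
            raise ValueError("group_labels length must equal the number of channel groups")

    @property
    def n_channel_groups(self) -> int:
        return self.weight_pattern.shape[0]

    @property
    def n_sources(self) -> int:
        return self.weight_pattern.shape[1]


def gait_reach_config(
    n_trials: int = 40,
    noise_level: float = 0.05,
    seed: int = 0,
    n_samples: int = 350,
    sample_rate: float = 120.0,
) -> ScenarioConfig:
    """Default walk-and-reach template: 2 sources, 6 channel groups.

    The discrete (bell-shaped) source loads mainly on the right-shoulder
    group; the rhythmic (two-peaked) source increases in weight from the
    shoulders toward the hip and knee groups, with the left side in
    anti-phase (half-period mean delay).  ``noise_level`` is expressed as a
    fraction of the noiseless mixture's overall SD and converted into an
    absolute ``noise_sigma``.
    """
    groups = ["r_shoulder", "l_shoulder", "r_hip", "l_hip", "r_knee", "l_knee"]
    #               discrete rhythmic
    weights = np.array(
        [
            [1.00, 0.15],  # right shoulder: dominant reach component
            [0.30, 0.20],  # left shoulder: small co-movement
            [0.15, 0.55],
            [0.15, 0.50],
            [0.10, 0.85],
            [0.10, 0.90],
        ]
    )
    duration = n_samples / sample_rate
    half = duration / 2.0
    delay_mean = np.array(
        [
            [0.00, 0.00],
            [0.02, half],
            [0.03, 0.00],
            [0.03, half],
            [0.05, 0.12],
            [0.05, half + 0.12],
        ]
    )
    delay_sd = np.full((6, 2), 0.02 * duration)
    cfg = ScenarioConfig(
        source_specs=[
            SourceSpec("discrete", {"center": 0.45, "width": 0.16}),
            SourceSpec("rhythmic", {"phase": 0.1, "peak_ratio": 0.45}),
        ],
        weight_pattern=weights,
        delay_mean=delay_mean,
        delay_sd=delay_sd,
        group_labels=groups,
        n_trials=n_trials,
        n_samples=n_samples,
        sample_rate=sample_rate,
        noise_sigma=0.0,
        seed=seed,
    )
    if noise_level > 0:
        clean, _ = _render_noiseless(cfg)
        cfg.noise_sigma = float(noise_level * clean.std())
    return cfg


def _fractional_roll(signal: np.ndarray, shift_samples: float) -> np.ndarray:
    """Circularly delay a series by a (possibly fractional) number of samples.

    Band-limited interpolation through the FFT; exact for the smooth,
    band-limited sources used here and identical to the delay operator of
    the Fourier demixing model.
    """
    t = signal.shape[-1]
    k = np.fft.rfftfreq(t, d=1.0 / t)
    return np.fft.irfft(np.fft.rfft(signal) * np.exp(-2j * np.pi * k * shift_samples / t), n=t)


def _render_noiseless(cfg: ScenarioConfig) -> tuple[np.ndarray, GroundTruth]:
    """Draw delays and synthesize the noiseless mixture for a config."""
    rng = np.random.default_rng(cfg.seed)
    n_src = cfg.n_sources
    g = cfg.n_channel_groups
    m = cfg.n_trials * g
    sources = np.vstack([spec.render(cfg.n_samples) for spec in cfg.source_specs])
    weights = np.tile(cfg.weight_pattern, (cfg.n_trials, 1))
    delays = np.empty((m, n_src))
    for trial in range(cfg.n_trials):
        block = slice(trial * g, (trial + 1) * g)
        delays[block] = rng.normal(cfg.delay_mean, cfg.delay_sd)
    clean = np.zeros((m, cfg.n_samples))
    for j in range(n_src):
        tau_samples = delays[:, j] * cfg.sample_rate
        for i in range(m):
            if weights[i, j] != 0.0:
                clean[i] += weights[i, j] * _fractional_roll(sources[j], tau_samples[i])
    truth = GroundTruth(sources=sources, weights=weights, delays=delays, noise_sigma=cfg.noise_sigma)
    return clean, truth


def make_mixture_dataset(cfg: ScenarioConfig) -> tuple[TrajectorySet, GroundTruth]:
    """Generate an anechoic mixture dataset with known hidden parameters.

    Channel ``i`` is ``sum_j weights[i, j] * source_j`` circularly delayed
    by ``delays[i, j]`` plus ``N(0, noise_sigma)`` noise.  Channels are laid
    out trial-major: all groups of trial 0, then trial 1, ...  The same
    seed and config reproduce the output bit for bit.
    """
    clean, truth = _render_noiseless(cfg)
    # separate stream so the delay draws above are independent of the noise
    noise_rng = np.random.default_rng((cfg.seed, 1))
    data = clean + noise_rng.normal(0.0, cfg.noise_sigma, size=clean.shape) if cfg.noise_sigma > 0 else clean.copy()
    labels = [f"t{trial:03d}_{lab}" for trial in range(cfg.n_trials) for lab in cfg.group_labels]
    trial_ids = [trial for trial in range(cfg.n_trials) for _ in cfg.group_labels]
    ts = TrajectorySet(
        data=data,
        sample_rate=cfg.sample_rate,
        channel_labels=labels,
        trial_ids=trial_ids,
    )
    return ts, truth


def make_gait_marker_fixture(
    n_strides: int = 4,
    cadence: float = 1.25,
    noise_sigma: float = 0.0,
    seed: int = 0,
    sample_rate: float = 120.0,
    stance_fraction: float = 0.6,
    reach_stride: int = 1,
) -> tuple[TrajectorySet, dict]:
    """Marker-level fixture: heel/toe vertical positions + hand distance.

    Returns a 5-channel :class:`TrajectorySet` (``r_toe_z``, ``r_heel_z``,
    ``l_toe_z``, ``l_heel_z``, ``hand_dist``) and a dict of ground-truth
    event times in seconds: per-foot toe-lift and heel-strike lists, plus
    the single reach-peak time.  Toe lifts are upward zero crossings of the
    toe marker's vertical velocity; heel strikes are downward crossings of
    the heel marker's velocity.  Feet alternate with half-cycle offset;
    strikes precede same-foot lifts by ``(1 - stance_fraction)`` of a cycle
    ... i.e. stance (strike to next lift) spans ``stance_fraction`` of the
    gait cycle.  The hand-distance channel oscillates weakly and carries
    one dominant Gaussian bump (the reach) peaking mid-``reach_stride``.
    """
    if n_strides < 2:
        raise ValueError("n_strides must be >= 2")
    if cadence <= 0:
        raise ValueError("cadence must be > 0")
    rng = np.random.default_rng(seed)
    pad = 0.35 * cadence  # lead-in so no true event sits at the boundary
    # window chosen so each foot shows exactly n_strides lifts and strikes
    duration = pad + (n_strides - 0.05) * cadence
    t = np.arange(int(round(duration * sample_rate))) / sample_rate

    def _cos_marker(t0: float, amp: float) -> np.ndarray:
        # velocity ~ sin(2 pi (t - t0) / cadence): upward zero crossings at
        # t0 + k*cadence, downward at t0 + (k + 1/2)*cadence
        return amp * (1.0 - np.cos(2.0 * np.pi * (t - t0) / cadence))

    truth: dict = {}
    channels, labels = [], []
    for foot, offset in (("r", 0.0), ("l", cadence / 2.0)):
        lift0 = pad + offset
        lifts = lift0 + cadence * np.arange(n_strides)
        # stance runs strike -> next same-foot lift over stance_fraction of
        # the cycle, so strikes trail lifts by (1 - stance_fraction) cycles;
        # the heel marker is periodic, so the truth list carries *every*
        # in-window downward crossing, including one before the first lift
        strike0 = lift0 + (1.0 - stance_fraction) * cadence
        strikes = strike0 + cadence * np.arange(-2, n_strides + 2)
        strikes = strikes[(strikes > 2.0 / sample_rate) & (strikes < t[-1])]
        lifts = lifts[lifts < t[-1]]
        toe = _cos_marker(lift0, 0.05)
        heel = _cos_marker(strikes[0] - cadence / 2.0, 0.04)
        channels += [toe, heel]
        labels += [f"{foot}_toe_z", f"{foot}_heel_z"]
        truth[f"{foot}_toe_lifts"] = lifts
        truth[f"{foot}_heel_strikes"] = strikes
    reach_time = pad + (reach_stride + 0.5) * cadence
    hand = 0.9 + 0.05 * np.sin(2.0 * np.pi * t / cadence) + 0.35 * np.exp(-0.5 * ((t - reach_time) / 0.12) ** 2)
    channels.append(hand)
    labels.append("hand_dist")
    truth["reach_time"] = reach_time
    data = np.vstack(channels)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    return TrajectorySet(data=data, sample_rate=sample_rate, channel_labels=labels), truth
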