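"""Synthetic spike-train generator emulating head-fixed aldehyde-panel recordings.

The generator produces :class:`RecordingSession` objects whose statistical
structure mirrors the experimental design the analysis pipeline expects:
six monomolecular aldehydes identified by carbon chain length (C3..C8),
19 trials per odour presented in randomized order, 500 ms odour pulses, and
a pre-onset baseline long enough to cover the −2.5 to −0.5 s analysis window.

Each unit is an inhomogeneous Poisson process.  Its rate is a constant
baseline ``b`` modulated around odour onset by a peak-normalized Gaussian
bump ``g(t)`` (truncated at ±3σ so the kernel has finite support):

* excited units:   ``rate(t) = b * (1 + A_o * g(t))``
* inhibited units: ``rate(t) = b * (1 - s_o * g(t))`` with ``s_o ∈ [0, 1)``
* non-responsive:  ``rate(t) = b``

Amplitude is tuned to carbon chain length: ``A_o = A * exp(-|c_o - c_best| / λ)``
where λ is the tuning decay in chain-length units (λ = ∞ gives flat tuning,
the mutant preset).  Latency and width receive small per-odour jitter, so
odour identity carries information even under flat amplitude tuning, as in
cortical populations with homogeneous response magnitudes.

Ground truth per unit is returned alongside the session so parameter-recovery
tests can compare the downstream classification against what was injected.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

ODOUR_CARBONS = (3, 4, 5, 6, 7, 8)

__all__ = [
    "GeneratorConfig",
    "UnitGroundTruth",
    "Unit",
    "RecordingSession",
    "control_preset",
    "mutant_preset",
    "generate_session",
    "rate_profile",
    "sample_inhomogeneous_poisson",
    "synthesize_raw_traces",
    "default_spike_template",
]


class ConfigError(ValueError):
    """A generator configuration field violates its invariant."""


@dataclass
class GeneratorConfig:
    """All simulation parameters for one synthetic session.

    Genotype preset magnitudes are calibration constants chosen to produce
    realistic mitral/tufted-like statistics; see :func:`control_preset` and
    :func:`mutant_preset`.
    """

    n_units: int = 100
    region: str = "MOB"
    genotype: str = "control"
    n_trials_per_odour: int = 19
    odour_carbons: tuple[int, ...] = ODOUR_CARBONS
    odour_duration: float = 0.5
    pre_onset_baseline: float = 5.0
    inter_trial_interval: float = 10.0
    # lognormal baseline rate distribution (Hz on log scale); median 10 Hz,
    # the typical mitral/tufted baseline regime
    baseline_rate_log_mean: float = math.log(10.0)
    baseline_rate_log_sd: float = 0.5
    p_responsive: float = 0.5
    p_inhibited_given_responsive: float = 0.4
    # multiplicative response gain of the best odour
    amp_mean: float = 2.5
    amp_sd: float = 0.6
    latency_mean: float = 0.15
    latency_sd: float = 0.05
    # kernel width is full width at half maximum, seconds
    kernel_width_mean: float = 0.25
    kernel_width_sd: float = 0.08
    # amplitude decay per unit of |Δ chain length|; inf = flat tuning
    tuning_decay: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_responsive", "p_inhibited_given_responsive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "odour_duration",
            "pre_onset_baseline",
            "inter_trial_interval",
            "latency_mean",
            "kernel_width_mean",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.pre_onset_baseline < 2.5:
            raise ConfigError(
                "pre_onset_baseline must be >= 2.5 s to cover the baseline window"
            )
        if self.n_trials_per_odour < 2:
            raise ConfigError("n_trials_per_odour must be >= 2")
        if self.n_units < 1:
            raise ConfigError("n_units must be >= 1")
        if not self.tuning_decay > 0:
            raise ConfigError("tuning_decay must be > 0 (use math.inf for flat)")
        if self.inter_trial_interval <= self.odour_duration:
            raise ConfigError("inter_trial_interval must exceed odour_duration")
        if len(set(self.odour_carbons)) != len(self.odour_carbons):
            raise ConfigError("odour_carbons must be distinct")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def control_preset(**overrides) -> GeneratorConfig:
    """Control genotype: finite chain-length tuning, intact inhibition."""
    cfg = GeneratorConfig(genotype="control", **overrides)
    cfg.validate()
    return cfg


def mutant_preset(**overrides) -> GeneratorConfig:
    """Mutant genotype preset.

    Fewer responsive units, fewer inhibited responses, weaker and temporally
    blurred (wider, later) excitatory responses, flat chain-length tuning.
    Magnitudes are calibration constants, not measured values.
    """
    defaults = dict(
        genotype="mutant",
        p_responsive=0.35,
        p_inhibited_given_responsive=0.15,
        amp_mean=1.2,
        amp_sd=0.4,
        latency_mean=0.25,
        latency_sd=0.06,
        kernel_width_mean=0.35,
        kernel_width_sd=0.10,
        tuning_decay=math.inf,
    )
    defaults.update(overrides)
    cfg = GeneratorConfig(**defaults)
    cfg.validate()
    return cfg


@dataclass
class UnitGroundTruth:
    """Injected parameters of one unit, keyed by odour carbon number."""

    unit_id: str
    baseline_rate: float
    responsive: bool
    polarity: dict[int, str]  # carbon -> excited | inhibited | none
    best_odour_carbon: int
    amplitude: dict[int, float]  # A_o (excited) or suppression s_o (inhibited)
    latency: dict[int, float]
    width: dict[int, float]  # FWHM, seconds


@dataclass
class Unit:
    unit_id: str
    tetrode_id: int
    spike_times: np.ndarray  # seconds from session start, ascending

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Unit)
            and self.unit_id == other.unit_id
            and self.tetrode_id == other.tetrode_id
            and np.array_equal(self.spike_times, other.spike_times)
        )


@dataclass
class RecordingSession:
    """Sorted single-unit spike times plus the trial/odour event table."""

    session_id: str
    genotype: str
    region: str
    units: list[Unit]
    trials: pd.DataFrame  # trial_id, odour_carbon, onset_s, offset_s
    duration: float
    meta: dict = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RecordingSession)
            and self.session_id == other.session_id
            and self.genotype == other.genotype
            and self.region == other.region
            and self.units == other.units
            and self.trials.reset_index(drop=True).equals(
                other.trials.reset_index(drop=True)
            )
        )

    @property
    def odour_carbons(self) -> list[int]:
        return sorted(self.trials["odour_carbon"].unique())

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


# ---------------------------------------------------------------------------
# rate model


def _kernel(t, latency, sigma):
    """Peak-normalized Gaussian bump truncated at ±3σ around its peak."""
    t = np.asarray(t, dtype=float)
    g = np.exp(-0.5 * ((t - latency) / sigma) ** 2)
    g = np.where(np.abs(t - latency) <= 3.0 * sigma, g, 0.0)
    return g


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def rate_profile(gt: UnitGroundTruth, odour_carbon: int, t):
    """Firing rate (Hz) of a unit at time ``t`` relative to odour onset.

    Accepts scalar or array ``t``.  Outside the kernel support the rate is
    the baseline; rates are clamped at zero.
    """
    t = np.asarray(t, dtype=float)
    b = gt.baseline_rate
    pol = gt.polarity.get(odour_carbon, "none")
    if not gt.responsive or pol == "none":
        return np.broadcast_to(np.float64(b), t.shape).copy() if t.shape else float(b)
    sigma = gt.width[odour_carbon] * _FWHM_TO_SIGMA
    g = _kernel(t, gt.latency[odour_carbon], sigma)
    if pol == "excited":
        rate = b * (1.0 + gt.amplitude[odour_carbon] * g)
    else:
        rate = b * (1.0 - gt.amplitude[odour_carbon] * g)
    rate = np.maximum(rate, 0.0)
    return rate if rate.shape else float(rate)


def rate_max_of(gt: UnitGroundTruth) -> float:
    """Tight upper bound of the unit's rate over any trial."""
    b = gt.baseline_rate
    if not gt.responsive:
        return b
    amps = [
        gt.amplitude[c]
        for c, p in gt.polarity.items()
        if p == "excited"
    ]
    return b * (1.0 + max(amps)) if amps else b


# ---------------------------------------------------------------------------
# Poisson sampling


def sample_inhomogeneous_poisson(rate_fn, t0, t1, rate_max, seed):
    """Sample an inhomogeneous Poisson process on ``[t0, t1)`` by thinning.

    ``rate_fn`` must accept an array of times and return rates bounded by
    ``rate_max`` (a violation at any probed point raises ``ValueError``).
    ``seed`` may be an integer or a ``numpy.random.Generator``.
    Returns strictly increasing spike times.
    """
    if not t1 > t0:
        raise ValueError("t1 must exceed t0")
    if rate_max < 0:
        raise ValueError("rate_max must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate_max == 0:
        return np.empty(0)
    n = rng.poisson(rate_max * (t1 - t0))
    times = np.sort(rng.uniform(t0, t1, size=n))
    rates = np.asarray(rate_fn(times), dtype=float)
    if np.any(rates > rate_max * (1.0 + 1e-9)):
        raise ValueError("rate_fn exceeds rate_max at a probed point")
    keep = rng.uniform(0.0, rate_max, size=n) < rates
    return times[keep]


# ---------------------------------------------------------------------------
# session generation


def _draw_ground_truth(cfg: GeneratorConfig, rng: np.random.Generator,
                       unit_id: str) -> UnitGroundTruth:
    carbons = cfg.odour_carbons
    b = float(rng.lognormal(cfg.baseline_rate_log_mean, cfg.baseline_rate_log_sd))
    responsive = bool(rng.random() < cfg.p_responsive)
    inhibited = responsive and rng.random() < cfg.p_inhibited_given_responsive
    best = int(rng.choice(carbons))
    lam = cfg.tuning_decay

    amplitude, latency, width, polarity = {}, {}, {}, {}
    if responsive:
        if inhibited:
            # multiplicative suppression keeps rates non-negative; strong,
            # near-saturating suppression as typical for odour-inhibited M/Ts
            a_best = float(np.clip(rng.normal(0.9, 0.05), 0.6, 0.98))
        else:
            a_best = float(max(rng.normal(cfg.amp_mean, cfg.amp_sd), 0.05))
    else:
        a_best = 0.0
    # inhibited responses are sustained: earlier onset, ~2x wider kernel
    lat_mean = 0.1 if inhibited else cfg.latency_mean
    wid_mean = 2.5 * cfg.kernel_width_mean if inhibited else cfg.kernel_width_mean
    for c in carbons:
        decay = 1.0 if math.isinf(lam) else math.exp(-abs(c - best) / lam)
        if responsive:
            amplitude[c] = a_best * decay
            polarity[c] = "inhibited" if inhibited else "excited"
        else:
            amplitude[c] = 0.0
            polarity[c] = "none"
        latency[c] = float(max(rng.normal(lat_mean, cfg.latency_sd), 0.02))
        width[c] = float(max(rng.normal(wid_mean, cfg.kernel_width_sd), 0.05))
    return UnitGroundTruth(
        unit_id=unit_id,
        baseline_rate=b,
        responsive=responsive,
        polarity=polarity,
        best_odour_carbon=best,
        amplitude=amplitude,
        latency=latency,
        width=width,
    )


def _trial_table(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    sequence = np.repeat(cfg.odour_carbons, cfg.n_trials_per_odour)
    rng.shuffle(sequence)
    onsets = cfg.pre_onset_baseline + np.arange(sequence.size) * cfg.inter_trial_interval
    return pd.DataFrame(
        {
            "trial_id": np.arange(sequence.size),
            "odour_carbon": sequence.astype(int),
            "onset_s": onsets,
            "offset_s": onsets + cfg.odour_duration,
        }
    )


def generate_session(config: GeneratorConfig):
    """Generate one session and its per-unit ground truth.

    Deterministic given ``config.seed``.  Spike trains are drawn from the
    :func:`rate_profile` model via :func:`sample_inhomogeneous_poisson`,
    evaluated over the whole session timeline (odour order randomized per
    session).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials = _trial_table(config, rng)
    duration = float(
        config.pre_onset_baseline
        + len(trials) * config.inter_trial_interval
    )
    onsets = trials["onset_s"].to_numpy()
    trial_carbons = trials["odour_carbon"].to_numpy()

    units: list[Unit] = []
    truths: list[UnitGroundTruth] = []
    for i in range(config.n_units):
        unit_id = f"u{i:04d}"
        gt = _draw_ground_truth(config, rng, unit_id)

        def session_rate(t, gt=gt):
            t = np.asarray(t, dtype=float)
            idx = np.searchsorted(onsets, t, side="right") - 1
            idx = np.clip(idx, 0, len(onsets) - 1)
            t_rel = t - onsets[idx]
            rates = np.full(t.shape, gt.baseline_rate)
            if gt.responsive:
                for c in config.odour_carbons:
                    m = trial_carbons[idx] == c
                    if m.any():
                        rates[m] = rate_profile(gt, c, t_rel[m])
            # before the first onset, t_rel is negative -> kernel support
            # never reaches there; baseline applies automatically
            return rates

        spikes = sample_inhomogeneous_poisson(
            session_rate, 0.0, duration, rate_max_of(gt), rng
        )
        units.append(Unit(unit_id=unit_id, tetrode_id=i // 4, spike_times=spikes))
        truths.append(gt)

    session = RecordingSession(
        session_id=f"{config.genotype}-{config.region}-seed{config.seed}",
        genotype=config.genotype,
        region=config.region,
        units=units,
        trials=trials,
        duration=duration,
        meta={"config_hash": config.content_hash(), "seed": config.seed},
    )
    return session, truths


# ---------------------------------------------------------------------------
# raw voltage synthesis (fixture substrate for the detection stage)


def default_spike_template(fs: float, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic extracellular-like waveform, ~1.2 ms, negative main phase."""
    t = np.arange(int(round(1.2e-3 * fs))) / fs
    w = -np.exp(-((t - 3e-4) ** 2) / (2 * (1e-4) ** 2)) + 0.35 * np.exp(
        -((t - 7e-4) ** 2) / (2 * (2e-4) ** 2)
    )
    return amplitude * w / np.max(np.abs(w))


def synthesize_raw_traces(
    session: RecordingSession,
    channels_per_tetrode: int = 4,
    fs: float = 30000.0,
    waveform_template: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Render multichannel voltage traces with the session's spikes embedded.

    Each spike inserts the template on every channel of its unit's tetrode;
    overlapping insertions sum.  Additive white Gaussian noise of standard
    deviation ``noise_sd``.  Returns ``(traces, fs)`` with traces shaped
    ``(n_channels, n_samples)`` float32, channels grouped by tetrode.
    """
    if fs < 10000:
        raise ValueError("fs must be >= 10 kHz")
    if waveform_template is None:
        waveform_template = default_spike_template(fs)
    template = np.asarray(waveform_template, dtype=np.float64)
    if template.size / fs > 3e-3:
        raise ValueError("waveform template must be <= 3 ms long")
    rng = np.random.default_rng(seed)
    n_tet = max(u.tetrode_id for u in session.units) + 1
    n_ch = n_tet * channels_per_tetrode
    n_samp = int(math.ceil(session.duration * fs)) + template.size
    traces = np.zeros((n_ch, n_samp), dtype=np.float64)
    for u in session.units:
        ch0 = u.tetrode_id * channels_per_tetrode
        starts = np.round(u.spike_times * fs).astype(int)
        for s in starts:
            traces[ch0 : ch0 + channels_per_tetrode, s : s + template.size] += template
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=traces.shape)
    return traces.astype(np.float32), fs
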