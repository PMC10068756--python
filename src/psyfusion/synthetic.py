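"""Synthetic paired drug/placebo EEG-fMRI sessions with planted effects.

The generator emulates the study design the analysis chain was built for:
28-minute resting-state sessions (TR = 2 s, 840 volumes) with the drug
injected at the end of minute 8, parcel-level BOLD over 112 regions
(100 cortical split across the Yeo 7 networks + 12 subcortical), 31-channel
EEG at 250 Hz epoched in 2-s trials, and per-minute subjective intensity
ratings.

BOLD model
----------
Region ``i`` in network ``k`` mixes white latent factors

    x_i(t) = a(t) f_k(t) + c P_pole(i)(t; m(t)) + b_i(t) g(t) + sd * eps_i(t)

where ``f_k`` are per-network factors, ``g`` a global factor, and ``P`` one
of two cortical *pole* factors (unimodal: VIS/SM/DAN; transmodal:
SAL/FP/DMN) whose mixing parameter ``m`` controls how differentiated the
two ends of the principal gradient are.  The signal part is convolved with
a unit-energy canonical HRF before white measurement noise is added, so
the closed-form correlation implied by the mixing weights
(:func:`expected_correlation`) holds exactly in expectation.

Under the drug condition, after the injection, every coupling coefficient
is ramped by a latent *effect curve* ``e(t)`` (the subject's unquantized
intensity curve times a smooth stochastic modulation): within-network
coupling drops, global coupling of transmodal regions rises, pole mixing
rises (gradient compression), EEG alpha power drops and delta/gamma power
rise.  The same ``e(t)`` drives the BOLD and EEG effects of a session, so
multimodal coupling analyses have a true within-subject association to
find.  All randomness is keyed on ``(seed, subject, condition, stream)``
so any piece can be regenerated independently and deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as spsig

from .containers import (
    EEGRecording,
    IntensityTrace,
    NetworkPartition,
    ParcelTimeSeries,
    ReceptorMap,
    TRANSMODAL_NETWORKS,
)

CONDITIONS = ("drug", "placebo")

#: 31-channel 10-20 montage used by default (includes the midline chain
#: Oz, POz, Pz, Cz, FCz required by the traveling-wave analysis).
DEFAULT_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "Oz", "O2",
]

MIDLINE_CHAIN = ("Oz", "POz", "Pz", "Cz", "FCz")

#: Band oscillator center frequencies (Hz).
BAND_FREQS = {"delta": 2.5, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 37.0}

UNIMODAL_POLE = ("VIS", "SM", "DAN")

#: Pole-factor weight of bridge regions (LIM, SC) relative to pole members;
#: they load the average of the two pole factors, sitting mid-gradient.
BRIDGE_POLE_WEIGHT = 0.7

_NETWORK_SIZES = {
    "VIS": 14, "SM": 16, "DAN": 14, "SAL": 14,
    "LIM": 12, "FP": 14, "DMN": 16, "SC": 12,
}


def default_partition(n_regions: int = 112) -> NetworkPartition:
    """Region -> network map mirroring the 100-cortical + 12-subcortical atlas.

    For ``n_regions != 112`` the same network proportions are applied.
    """
    if n_regions == 112:
        sizes = dict(_NETWORK_SIZES)
    else:
        total = sum(_NETWORK_SIZES.values())
        sizes = {k: max(1, round(v * n_regions / total)) for k, v in _NETWORK_SIZES.items()}
        keys = list(sizes)
        i = 0
        while sum(sizes.values()) != n_regions:
            k = keys[i % len(keys)]
            sizes[k] += 1 if sum(sizes.values()) < n_regions else -1
            i += 1
    labels, networks = [], []
    for net, size in sizes.items():
        for j in range(size):
            labels.append(f"{net}_{j + 1:02d}")
            networks.append(net)
    return NetworkPartition(labels, networks)


@dataclass
class CouplingSpec:
    """Per-condition BOLD mixing coefficients (all dimensionless)."""

    within: float = 0.4          # within-network factor loading
    pole: float = 0.5            # pole factor loading (cortical regions)
    global_base: float = 0.25    # global factor loading, everyone
    within_loss: float = 0.5     # fractional within loss at full effect
    global_gain: float = 0.9     # fractional transmodal global gain at full effect
    pole_mix: float = 0.4        # pole mixing at full effect (0 = intact poles)
    pole_mix_floor: float = 0.0  # condition-independent baseline pole mixing
    receptor_coupled: bool = False  # scale the global gain by receptor density


@dataclass
class BandSpec:
    """EEG oscillator amplitudes (microvolts) and drug effects.

    ``changes`` are fractional amplitude changes at full effect
    (alpha suppressed; delta and gamma enhanced).
    """

    amplitudes: dict = field(default_factory=lambda: {
        "delta": 4.0, "theta": 3.0, "alpha": 8.0, "beta": 2.5, "gamma": 1.5})
    changes: dict = field(default_factory=lambda: {
        "delta": 0.8, "theta": 0.0, "alpha": -0.6, "beta": -0.2, "gamma": 0.8})


@dataclass
class WaveSpec:
    """Planted midline traveling wave."""

    direction: str = "none"        # forward | backward | none
    freq_hz: float = 10.0
    amplitude: float = 0.0         # microvolts; 0 disables
    delay_per_channel: float = 0.02  # seconds of lag per midline step


@dataclass
class IntensitySpec:
    """Rise-and-decay subjective intensity curve parameters."""

    peak: float = 8.0              # modal peak rating (0-10)
    rise_minutes: float = 0.7      # exponential rise time constant
    peak_delay_minutes: float = 2.0
    decay_minutes: float = 8.0     # exponential decay time constant
    placebo_ceiling: int = 1
    subject_sd: float = 0.2        # between-subject amplitude spread
    modulation_sd: float = 0.3     # within-subject smooth effect modulation


@dataclass
class SimConfig:
    """Full description of a simulated paired-session experiment."""

    n_subjects: int = 12
    n_regions: int = 112
    tr_seconds: float = 2.0
    n_volumes: int = 840          # 28 min at TR 2 s
    injection_index: int = 240    # end of minute 8
    eeg_fs: float = 250.0
    eeg_channels: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    epoch_seconds: float = 2.0
    partition: NetworkPartition | None = None
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    bands: BandSpec = field(default_factory=BandSpec)
    wave: WaveSpec = field(default_factory=WaveSpec)
    intensity: IntensitySpec = field(default_factory=IntensitySpec)
    background_sd: float = 10.0   # microvolts, 1/f background
    background_exponent: float = 1.0
    noise_sd: float = 1.0         # BOLD measurement noise
    bad_epoch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition is None:
            self.partition = default_partition(self.n_regions)
        if len(self.partition) != self.n_regions:
            raise ValueError("partition length must equal n_regions")
        if not 0 <= self.injection_index < self.n_volumes:
            raise ValueError("injection_index must fall inside the scan")
        if self.eeg_fs < 2 * 45:
            raise ValueError("eeg_fs must be at least twice the top band edge")
        if any(a < 0 for a in self.bands.amplitudes.values()):
            raise ValueError("band amplitudes must be nonnegative")
        if self.tr_seconds <= 0 or self.epoch_seconds <= 0:
            raise ValueError("durations must be positive")

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds

    @property
    def injection_minute(self) -> float:
        return self.injection_index * self.tr_seconds / 60.0


@dataclass
class SessionBundle:
    """All data of one subject's paired sessions plus the planted truth."""

    subject: str
    bold_drug: ParcelTimeSeries
    bold_placebo: ParcelTimeSeries
    eeg_drug: EEGRecording
    eeg_placebo: EEGRecording
    intensity_drug: IntensityTrace
    intensity_placebo: IntensityTrace
    receptor_map: ReceptorMap
    truth: dict


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

_STREAMS = {
    "subject": 11, "effect": 12, "latents": 13, "bold_noise": 14,
    "eeg_background": 15, "eeg_phase": 16, "topography": 17,
    "intensity": 18, "receptor": 19, "bad_epochs": 20,
}


def _rng(cfg: SimConfig, stream: str, subject: str = "", condition: str = "") -> np.random.Generator:
    subj = int(subject.split("-")[-1]) if subject else 0
    cond = {"": 0, "drug": 1, "placebo": 2}[condition]
    return np.random.default_rng([cfg.seed, _STREAMS[stream], subj, cond])


def subject_ids(cfg: SimConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


# ---------------------------------------------------------------------------
# latent effect curve
# ---------------------------------------------------------------------------

def intensity_curve(minutes: np.ndarray, spec: IntensitySpec) -> np.ndarray:
    """Unit-peak rise-and-decay curve on a minutes-from-injection grid."""
    t = np.asarray(minutes, dtype=float)
    rise = 1.0 - np.exp(-np.maximum(t, 0.0) / spec.rise_minutes)
    decay = np.exp(-np.maximum(t - spec.peak_delay_minutes, 0.0) / spec.decay_minutes)
    c = np.where(t >= 0, rise * decay, 0.0)
    peak = c.max()
    return c / peak if peak > 0 else c


def _subject_params(cfg: SimConfig, subject: str) -> dict:
    rng = _rng(cfg, "subject", subject)
    amp = float(np.clip(rng.normal(1.0, cfg.intensity.subject_sd), 0.4, 1.6))
    decay_jitter = float(rng.uniform(0.8, 1.25))
    return {"amplitude": amp, "decay_jitter": decay_jitter}


def effect_curve(cfg: SimConfig, subject: str, condition: str) -> np.ndarray:
    """Latent per-volume effect level e(t) in [0, ~1.5]; zero under placebo.

    Shared by the BOLD and EEG generators of one session so the two
    modalities covary within subject beyond the group-mean time course.
    """
    _check_condition(condition)
    times = np.arange(cfg.n_volumes) * cfg.tr_seconds
    if condition == "placebo":
        return np.zeros(cfg.n_volumes)
    params = _subject_params(cfg, subject)
    spec = IntensitySpec(**{**asdict(cfg.intensity),
                            "decay_minutes": cfg.intensity.decay_minutes * params["decay_jitter"]})
    minutes = times / 60.0 - cfg.injection_minute
    base = intensity_curve(minutes, spec) * params["amplitude"]
    rng = _rng(cfg, "effect", subject, condition)
    # smooth AR(1) modulation, stationary sd 1, ~30 s time constant
    rho = float(np.exp(-cfg.tr_seconds / 30.0))
    innov = rng.normal(0.0, np.sqrt(1 - rho**2), cfg.n_volumes)
    ar = np.empty(cfg.n_volumes)
    ar[0] = rng.normal()
    for i in range(1, cfg.n_volumes):
        ar[i] = rho * ar[i - 1] + innov[i]
    e = base * np.clip(1.0 + cfg.intensity.modulation_sd * ar, 0.0, 2.0)
    return np.clip(e, 0.0, 1.5)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def canonical_hrf(tr_seconds: float, length_seconds: float = 32.0) -> np.ndarray:
    """Double-gamma canonical HRF sampled at TR, normalized to unit energy.

    Peak at 6 s, undershoot at 16 s, peak/undershoot ratio 6:1.  Unit L2
    norm keeps zero-lag correlations of jointly-white mixed signals equal
    to their pre-convolution values.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, length_seconds + tr_seconds / 2, tr_seconds)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / np.linalg.norm(h)


def loading_profiles(partition: NetworkPartition) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic core-periphery multipliers for network and pole loadings.

    Within each network, regions run from network-core (strong network
    factor, weak pole factor) to pole-core (the reverse), so connectivity
    profiles grade smoothly across same-pole networks instead of forming
    disjoint network blocks.  Multipliers average ~1 per network.
    """
    n = len(partition)
    u_net = np.ones(n)
    u_pole = np.ones(n)
    for net in partition.present_networks:
        members = partition.members(net)
        t = np.linspace(0.0, 1.0, members.size) if members.size > 1 else np.array([0.5])
        u_net[members] = 1.25 - 0.5 * t
        u_pole[members] = 0.5 + 1.0 * t
    return u_net, u_pole


def region_weights(cfg: SimConfig, effect: np.ndarray, density: np.ndarray | None = None):
    """Time-resolved mixing weights implied by the config and effect curve.

    Returns ``(w_net, w_pole, w_glob, mix)`` with shapes
    ``(n_volumes, n_regions)`` for the first three and ``(n_volumes,)`` for
    the pole-mixing fraction.
    """
    part = cfg.partition
    cp = cfg.coupling
    e = effect[:, None]
    trans = part.indicator(TRANSMODAL_NETWORKS).astype(float)
    if cp.receptor_coupled:
        if density is None:
            raise ValueError("receptor_coupled requires a density map")
        gain = density / density.mean()
    else:
        gain = trans
    u_net, u_pole = loading_profiles(part)
    w_net = cp.within * u_net * (1.0 - cp.within_loss * e)
    pole_member = (part.indicator(UNIMODAL_POLE) | part.indicator(TRANSMODAL_NETWORKS)).astype(float)
    # LIM and SC are bridge regions: they load on the average of the two
    # pole factors (mid-gradient placement), at reduced weight
    bridge = (1.0 - pole_member) * BRIDGE_POLE_WEIGHT
    w_pole = cp.pole * u_pole * (pole_member + bridge) * np.ones_like(e)
    w_glob = cp.global_base * (1.0 + cp.global_gain * gain[None, :] * e)
    mix = np.clip(cp.pole_mix_floor + cp.pole_mix * effect, 0.0, 1.0)
    return w_net, w_pole, w_glob, mix


def expected_correlation(w_i: np.ndarray, w_j: np.ndarray, noise_sd: float) -> float:
    """Closed-form Pearson correlation of two regions under static weights.

    ``w_i`` and ``w_j`` are the regions' loading vectors on a shared
    orthonormal white factor basis.
    """
    num = float(w_i @ w_j)
    den = np.sqrt((w_i @ w_i + noise_sd**2) * (w_j @ w_j + noise_sd**2))
    return num / den


def simulate_parcel_bold(cfg: SimConfig, subject: str, condition: str) -> ParcelTimeSeries:
    """Simulate one session's parcel BOLD matrix (volumes x regions)."""
    _check_condition(condition)
    part = cfg.partition
    T, R = cfg.n_volumes, cfg.n_regions
    e = effect_curve(cfg, subject, condition)
    density = make_receptor_map(cfg).density if cfg.coupling.receptor_coupled else None
    w_net, w_pole, w_glob, mix = region_weights(cfg, e, density)

    rng = _rng(cfg, "latents", subject, condition)
    net_names = part.present_networks
    F = rng.normal(size=(len(net_names), T))          # network factors
    P = rng.normal(size=(2, T))                       # pole factors (uni, trans)
    G = rng.normal(size=T)                            # global factor

    net_index = {n: i for i, n in enumerate(net_names)}
    net_of = np.array([net_index[n] for n in part.networks])
    is_trans = part.indicator(TRANSMODAL_NETWORKS)
    is_uni = part.indicator(UNIMODAL_POLE)

    pole_uni = (1.0 - mix)[:, None] * P[0][:, None] + mix[:, None] * P[1][:, None]
    pole_trans = (1.0 - mix)[:, None] * P[1][:, None] + mix[:, None] * P[0][:, None]
    pole_bridge = (pole_uni + pole_trans) / np.sqrt(2.0)
    is_bridge = ~(is_uni | is_trans)

    sig = w_net * F[net_of].T
    sig += w_pole * (is_uni * pole_uni + is_trans * pole_trans
                     + is_bridge * pole_bridge)
    sig += w_glob * G[:, None]

    h = canonical_hrf(cfg.tr_seconds)
    sig = spsig.fftconvolve(sig, h[:, None], mode="full", axes=0)[:T]
    noise_rng = _rng(cfg, "bold_noise", subject, condition)
    data = sig + cfg.noise_sd * noise_rng.normal(size=(T, R))
    return ParcelTimeSeries(
        data=data, tr_seconds=cfg.tr_seconds, region_labels=list(part.region_labels),
        subject=subject, condition=condition, injection_index=cfg.injection_index,
    )


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     fs: float, exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, per-channel sd.

    Computed in single precision: the generator's noise floor does not
    need 53-bit mantissas and long sessions are FFT-bound.
    """
    white = rng.standard_normal(size=(n_channels, n_samples), dtype=np.float32)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.ones_like(freqs, dtype=np.float32)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return (sd * x).astype(np.float32)


def simulate_eeg(cfg: SimConfig, subject: str, condition: str) -> EEGRecording:
    """Simulate one session's EEG: 1/f background + band oscillators (+ wave)."""
    _check_condition(condition)
    if cfg.wave.direction not in ("none", "forward", "backward"):
        raise ValueError(f"unknown wave direction {cfg.wave.direction!r}")
    missing = [ch for ch in MIDLINE_CHAIN if ch not in cfg.eeg_channels]
    if cfg.wave.direction != "none" and missing:
        raise ValueError(f"traveling wave requires midline channels, missing {missing}")

    fs = cfg.eeg_fs
    n_samples = int(round(cfg.duration_seconds * fs))
    n_ch = len(cfg.eeg_channels)
    t = np.arange(n_samples) / fs

    e_vol = effect_curve(cfg, subject, condition)
    e = np.interp(t, np.arange(cfg.n_volumes) * cfg.tr_seconds, e_vol)

    rng_bg = _rng(cfg, "eeg_background", subject, condition)
    data = one_over_f_noise(rng_bg, n_ch, n_samples, fs,
                            cfg.background_exponent, cfg.background_sd)

    topo_rng = _rng(cfg, "topography", subject)
    gains = topo_rng.uniform(0.7, 1.3, size=(len(BAND_FREQS), n_ch))
    phase_rng = _rng(cfg, "eeg_phase", subject, condition)
    oscs = np.zeros((len(BAND_FREQS), n_samples), dtype=np.float32)
    for bi, (band, f0) in enumerate(BAND_FREQS.items()):
        amp0 = cfg.bands.amplitudes.get(band, 0.0)
        phase = phase_rng.uniform(0, 2 * np.pi)
        if amp0 == 0.0:
            continue
        change = cfg.bands.changes.get(band, 0.0)
        amp_t = amp0 * np.clip(1.0 + change * e, 0.0, None)
        oscs[bi] = (amp_t * np.sin(2 * np.pi * f0 * t + phase)).astype(np.float32)
    data += gains.T.astype(np.float32) @ oscs

    if cfg.wave.direction != "none" and cfg.wave.amplitude > 0:
        sign = 1.0 if cfg.wave.direction == "forward" else -1.0
        phase = phase_rng.uniform(0, 2 * np.pi)
        f0 = cfg.wave.freq_hz
        for k, ch in enumerate(MIDLINE_CHAIN):
            idx = cfg.eeg_channels.index(ch)
            lag = sign * k * cfg.wave.delay_per_channel
            data[idx] += cfg.wave.amplitude * np.sin(2 * np.pi * f0 * (t - lag) + phase)

    n_epochs = n_samples // int(round(cfg.epoch_seconds * fs))
    bad = set()
    if cfg.bad_epoch_rate > 0:
        bad_rng = _rng(cfg, "bad_epochs", subject, condition)
        bad = set(np.flatnonzero(bad_rng.random(n_epochs) < cfg.bad_epoch_rate).tolist())
    return EEGRecording(
        data=data, fs=fs, channel_names=list(cfg.eeg_channels),
        epoch_seconds=cfg.epoch_seconds, bad_epochs=bad,
        midline_chain=MIDLINE_CHAIN,
        injection_sample=int(round(cfg.injection_index * cfg.tr_seconds * fs)),
        subject=subject, condition=condition,
    )


# ---------------------------------------------------------------------------
# intensity ratings and receptor map
# ---------------------------------------------------------------------------

def simulate_intensity(cfg: SimConfig, condition: str, subject: str = "sub-01") -> IntensityTrace:
    """Per-minute 0-10 ratings time-locked to the injection."""
    _check_condition(condition)
    if cfg.intensity.peak > 10:
        raise ValueError("peak rating cannot exceed 10")
    n_minutes = int(np.ceil(cfg.duration_seconds / 60.0))
    minutes = np.arange(n_minutes) - cfg.injection_minute
    if condition == "placebo":
        ratings = np.zeros(n_minutes)
        rng = _rng(cfg, "intensity", subject, condition)
        if cfg.intensity.placebo_ceiling > 0 and rng.random() < 0.15:
            post = np.flatnonzero((minutes > 0) & (minutes <= 5))
            if post.size:
                ratings[rng.choice(post)] = min(1, cfg.intensity.placebo_ceiling)
        return IntensityTrace(minutes, ratings)
    params = _subject_params(cfg, subject)
    spec = IntensitySpec(**{**asdict(cfg.intensity),
                            "decay_minutes": cfg.intensity.decay_minutes * params["decay_jitter"]})
    curve = intensity_curve(minutes, spec)
    ratings = np.clip(np.round(cfg.intensity.peak * params["amplitude"] * curve), 0, 10)
    ratings[minutes < 0] = 0
    return IntensityTrace(minutes, ratings)


def make_receptor_map(cfg: SimConfig, correlation_with_transmodal: float = 0.8) -> ReceptorMap:
    """Per-region receptor densities correlated with transmodal membership."""
    rho = correlation_with_transmodal
    if not -1.0 <= rho <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    part = cfg.partition
    ind = part.indicator(TRANSMODAL_NETWORKS).astype(float)
    z_ind = (ind - ind.mean()) / ind.std()
    rng = _rng(cfg, "receptor")
    noise = rng.normal(size=len(part))
    noise = (noise - noise.mean()) / noise.std()
    # remove the indicator component of the noise so the planted rho is exact
    noise = noise - (noise @ z_ind) / (z_ind @ z_ind) * z_ind
    noise /= noise.std()
    mixed = rho * z_ind + np.sqrt(max(0.0, 1 - rho**2)) * noise
    density = np.clip(7.0 + 3.0 * mixed, 0.0, None)
    return ReceptorMap(list(part.region_labels), density)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def simulate_session(cfg: SimConfig, subject: str) -> SessionBundle:
    """Generate one subject's full paired drug/placebo session bundle."""
    receptor = make_receptor_map(cfg)
    truth = {
        "coupling": asdict(cfg.coupling),
        "band_changes": dict(cfg.bands.changes),
        "wave_direction": cfg.wave.direction,
        "subject_params": _subject_params(cfg, subject),
    }
    return SessionBundle(
        subject=subject,
        bold_drug=simulate_parcel_bold(cfg, subject, "drug"),
        bold_placebo=simulate_parcel_bold(cfg, subject, "placebo"),
        eeg_drug=simulate_eeg(cfg, subject, "drug"),
        eeg_placebo=simulate_eeg(cfg, subject, "placebo"),
        intensity_drug=simulate_intensity(cfg, "drug", subject),
        intensity_placebo=simulate_intensity(cfg, "placebo", subject),
        receptor_map=receptor,
        truth=truth,
    )


def simulate_cohort(cfg: SimConfig):
    """Yield a :class:`SessionBundle` per subject (lazily, to bound memory)."""
    for subject in subject_ids(cfg):
        yield simulate_session(cfg, subject)
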