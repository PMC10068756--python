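"""EEG-derived measures: IRASA spectra, LZ76 diversity, traveling waves.

* IRASA (irregular-resampling auto-spectral analysis) separates the
  fractal (1/f) from the oscillatory part of the power spectrum by
  resampling the signal at pairwise-reciprocal non-integer factors:
  oscillatory peaks move, the self-affine fractal background does not, so
  the median across geometric-mean pairs of resampled spectra estimates
  the fractal component and the residual is oscillatory.
* Signal diversity is Lempel-Ziv 1976 complexity of the mean-binarized
  signal per 2-s epoch (LZs per channel, LZc = channel average).
* Traveling waves are quantified from the 2D FFT of a time-by-electrode
  map over the midline chain (Oz, POz, Pz, Cz, FCz): the maxima of the two
  off-axis quadrants measure forward (occipital->frontal) and backward
  propagation, in dB relative to electrode-shuffled surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as spsig

from .containers import EEGRecording

#: Analysis bands in Hz: delta, theta, alpha, beta, gamma.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

ANALYSIS_RANGE = (1.0, 45.0)

#: Default IRASA resampling factors: 1.1 to 1.9 in steps of 0.05.
DEFAULT_FACTORS = tuple(np.round(np.arange(1.1, 1.91, 0.05), 3))


def band_of(freq_hz: float) -> str:
    """Name of the band containing ``freq_hz`` (upper edges exclusive)."""
    for name, (lo, hi) in BANDS.items():
        if lo <= freq_hz < hi:
            return name
    raise ValueError(f"{freq_hz} Hz lies outside the analysis bands")


@dataclass
class SpectralDecomposition:
    """Total = fractal + oscillatory PSD on a common frequency grid."""

    frequencies: np.ndarray
    fractal: np.ndarray        # channels x frequencies, >= 0
    oscillatory: np.ndarray    # channels x frequencies, signed residual
    total: np.ndarray
    channel_names: list


def _block_signal(recording: EEGRecording, block: slice | None) -> np.ndarray:
    """Concatenate the good epochs of ``block`` into channels x samples."""
    n = recording.n_epochs
    block = block or slice(0, n)
    good = recording.good_epochs()
    epochs = [e for e in range(*block.indices(n)) if good[e]]
    if not epochs:
        raise ValueError("block contains no good epochs")
    return np.concatenate([recording.epoch(e) for e in epochs], axis=1)


def irasa(
    recording: EEGRecording,
    block: slice | None = None,
    resampling_factors=DEFAULT_FACTORS,
    channels=None,
    welch_seconds: float = 4.0,
) -> SpectralDecomposition:
    """IRASA decomposition of a block of epochs, evaluated over 1-45 Hz.

    For each factor h the signal is resampled by h and by 1/h, the
    geometric mean of the two Welch spectra is taken, and the median over
    factors estimates the fractal spectrum; oscillatory = total - fractal
    (a signed residual).  Welch uses Hann windows of ``welch_seconds``
    with 50% overlap.
    """
    factors = [float(h) for h in resampling_factors]
    if not factors:
        raise ValueError("empty resampling-factor set")
    if any(h <= 1.0 for h in factors):
        raise ValueError("resampling factors must exceed 1")
    x = _block_signal(recording, block)
    if channels is not None:
        idx = [recording.channel_index(c) for c in channels]
        x = x[idx]
        names = list(channels)
    else:
        names = list(recording.channel_names)
    fs = recording.fs
    if x.shape[1] < 4 * fs:
        raise ValueError("block must contain at least 4 s of good data")
    nperseg = int(round(welch_seconds * fs))
    nperseg = min(nperseg, x.shape[1])

    def psd(sig):
        f, p = spsig.welch(sig, fs=fs, nperseg=nperseg, window="hann", axis=-1)
        return f, p

    freqs, total = psd(x)
    resampled = []
    for h in factors:
        frac = Fraction(h).limit_denominator(100)
        up = spsig.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
        down = spsig.resample_poly(x, frac.denominator, frac.numerator, axis=-1)
        _, p_up = psd(up)
        _, p_down = psd(down)
        resampled.append(np.sqrt(p_up * p_down))
    fractal = np.median(resampled, axis=0)

    lo, hi = ANALYSIS_RANGE
    sel = (freqs >= lo) & (freqs <= hi)
    return SpectralDecomposition(
        freqs[sel], fractal[..., sel], (total - fractal)[..., sel],
        total[..., sel], names,
    )


def fractal_exponent(decomp: SpectralDecomposition) -> np.ndarray:
    """Per-channel 1/f exponent: -slope of log10 fractal PSD vs log10 f."""
    lf = np.log10(decomp.frequencies)
    slopes = np.polyfit(lf, np.log10(np.clip(decomp.fractal, 1e-30, None)).T, 1)[0]
    return -slopes


def band_power(
    decomp: SpectralDecomposition,
    bands: dict = BANDS,
    baseline: SpectralDecomposition | None = None,
    component: str = "oscillatory",
    clip_negative: bool = False,
) -> dict:
    """Integrate a spectral component per band, optionally baseline-subtracted.

    Returns ``{band: channels array}``.  The oscillatory residual may be
    negative; by default the signed residual is integrated
    (``clip_negative=True`` floors it at zero first).
    """
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (decomp.frequencies >= lo) & (decomp.frequencies <= hi)
        if not sel.any():
            raise ValueError(f"band {name} outside the evaluated grid")
        comp = getattr(decomp, component)
        vals = np.clip(comp, 0, None) if clip_negative else comp
        power = np.trapezoid(vals[..., sel], decomp.frequencies[sel], axis=-1)
        if baseline is not None:
            bp = band_power(baseline, {name: (lo, hi)}, component=component,
                            clip_negative=clip_negative)[name]
            power = power - bp
        out[name] = power
    return out


# ---------------------------------------------------------------------------
# Lempel-Ziv 1976
# ---------------------------------------------------------------------------

def lz76(sequence) -> int:
    """LZ76 exhaustive-history phrase count of a binary sequence.

    Each phrase is the shortest continuation that cannot be copied from
    the prior history, where the copy window may extend into the phrase
    itself; the final phrase may be fully reproducible.  ``sequence`` may
    be a 0/1 string or array.
    """
    if isinstance(sequence, (str, bytes)):
        b = sequence.encode() if isinstance(sequence, str) else sequence
    else:
        b = np.asarray(sequence).astype(np.uint8).tobytes()
    n = len(b)
    if n == 0:
        raise ValueError("empty sequence")
    c = 0
    i = 0
    while i < n:
        ln = 1
        # grow while s[i:i+ln] occurs starting before position i
        while i + ln <= n and b.find(b[i : i + ln], 0, i + ln - 1) != -1:
            ln += 1
        c += 1
        i += ln
    return c


def _make_fast_parser():
    """Compiled exhaustive-history parser for the batch diversity path.

    Same phrase-counting convention as :func:`lz76` (equality is asserted
    in the tests); falls back to the pure-Python routine without numba.
    """
    try:
        from numba import njit
    except ImportError:                                    # pragma: no cover
        return None

    @njit(cache=False)
    def parse(s):
        n = s.size
        c = 1
        l = 1
        i = 0
        k = 1
        kmax = 1
        if n == 1:
            return 1
        while True:
            if s[i + k - 1] != s[l + k - 1]:
                if k > kmax:
                    kmax = k
                i += 1
                if i == l:
                    c += 1
                    l += kmax
                    if l + 1 > n:
                        return c
                    i = 0
                    k = 1
                    kmax = 1
                else:
                    k = 1
            else:
                k += 1
                if l + k > n:
                    return c + 1

    return parse


_FAST_PARSER = _make_fast_parser()


def binarize_epoch(x: np.ndarray) -> np.ndarray:
    """Binarize by the epoch mean; samples exactly at the mean map to 1."""
    x = np.asarray(x, dtype=float)
    return (x >= x.mean()).astype(np.uint8)


@dataclass
class LZResult:
    counts: np.ndarray          # channels x epochs raw phrase counts (NaN = bad)
    normalized: np.ndarray      # counts * log2(n) / n
    lzs: np.ndarray             # per-channel mean over good epochs
    lzc: float                  # channel mean of LZs
    lzs_normalized: np.ndarray
    lzc_normalized: float
    epoch_indices: np.ndarray
    channel_names: list


def lz_diversity(recording: EEGRecording, block: slice | None = None) -> LZResult:
    """LZ76 diversity per channel per 2-s epoch within ``block``."""
    n = recording.n_epochs
    block = block or slice(0, n)
    good = recording.good_epochs()
    epochs = np.array([e for e in range(*block.indices(n))])
    if epochs.size == 0 or not good[epochs].any():
        raise ValueError("block contains no good epochs")
    n_ch = recording.n_channels
    counts = np.full((n_ch, epochs.size), np.nan)
    w = recording.samples_per_epoch
    count = _FAST_PARSER if _FAST_PARSER is not None else lz76
    for j, e in enumerate(epochs):
        if not good[e]:
            continue
        seg = recording.epoch(e)
        binary = seg >= seg.mean(axis=1, keepdims=True)
        for ch in range(n_ch):
            counts[ch, j] = count(binary[ch].astype(np.uint8))
    norm = counts * np.log2(w) / w
    lzs = np.nanmean(counts, axis=1)
    lzs_n = np.nanmean(norm, axis=1)
    return LZResult(counts, norm, lzs, float(lzs.mean()), lzs_n,
                    float(lzs_n.mean()), epochs, list(recording.channel_names))


def epoch_band_power(recording: EEGRecording, bands: dict = BANDS) -> dict:
    """Raw per-epoch spectral power per band: {band: channels x epochs}.

    Periodogram power integrated per band on each 2-s epoch; used by the
    dynamic (per-epoch) EEG analyses where IRASA blocks are too short.
    Bad epochs are NaN.
    """
    w = recording.samples_per_epoch
    freqs = np.fft.rfftfreq(w, 1.0 / recording.fs)
    segs = recording.data[:, : recording.n_epochs * w]
    segs = segs.reshape(recording.n_channels, recording.n_epochs, w)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(segs * np.hanning(w), axis=-1)) ** 2
    good = recording.good_epochs()
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        p = spec[:, :, sel].sum(axis=-1)
        p[:, ~good] = np.nan
        out[name] = p
    return out


# ---------------------------------------------------------------------------
# traveling waves
# ---------------------------------------------------------------------------

#: 2D-FFT quadrant encoding a forward (occipital->frontal) wave, fixed by
#: calibration against a planted forward wave: with rows stacked
#: occipital->frontal and numpy FFT conventions, forward power lands at
#: (negative spatial frequency, positive temporal frequency).
FORWARD_QUADRANT = "negative_spatial"


@dataclass
class WaveStats:
    window_times: np.ndarray    # window start, seconds
    fw_db: np.ndarray
    bw_db: np.ndarray

    @property
    def asymmetry_db(self) -> np.ndarray:
        """FW - BW per window; positive = net forward waves."""
        return self.fw_db - self.bw_db


def traveling_waves(
    recording: EEGRecording,
    n_surrogates: int = 100,
    window_seconds: float = 1.0,
    step_seconds: float = 0.5,
    rng: np.random.Generator | None = None,
) -> WaveStats:
    """Forward/backward wave power in dB relative to shuffled surrogates.

    Per 1-s window the midline channels are stacked occipital->frontal
    into a 2D map, 2D-FFT'd, and the maxima of the two off-axis quadrants
    (temporal frequencies within the 1-45 Hz analysis band) are referenced
    to the average of ``n_surrogates`` electrode-order shuffles.
    """
    rng = rng or np.random.default_rng()
    try:
        chain = [recording.channel_index(c) for c in recording.midline_chain]
    except KeyError as err:
        raise ValueError(f"midline chain incomplete: {err}") from None
    n_rows = len(chain)
    fs = recording.fs
    wlen = int(round(window_seconds * fs))
    step = int(round(step_seconds * fs))
    if wlen > recording.n_samples:
        raise ValueError("window longer than the recording")

    ft = np.fft.fftfreq(wlen, 1.0 / fs)
    fx = np.fft.fftfreq(n_rows)
    tsel = (ft >= ANALYSIS_RANGE[0]) & (ft <= ANALYSIS_RANGE[1])
    neg_rows = np.flatnonzero(fx < 0)
    pos_rows = np.flatnonzero(fx > 0)
    fw_rows, bw_rows = (neg_rows, pos_rows)
    if FORWARD_QUADRANT != "negative_spatial":  # pragma: no cover
        fw_rows, bw_rows = bw_rows, fw_rows

    data = recording.data[chain]
    starts = np.arange(0, recording.n_samples - wlen + 1, step)
    fw_db = np.empty(starts.size)
    bw_db = np.empty(starts.size)
    perms = np.stack([rng.permutation(n_rows) for _ in range(n_surrogates)])
    for i, s in enumerate(starts):
        seg = data[:, s : s + wlen]
        seg = seg - seg.mean(axis=1, keepdims=True)
        time_fft = np.fft.fft(seg, axis=1)[:, tsel]
        power = np.abs(np.fft.fft(time_fft, axis=0)) ** 2
        fw = power[fw_rows].max()
        bw = power[bw_rows].max()
        surr = np.abs(np.fft.fft(time_fft[perms], axis=1)) ** 2
        fw_surr = surr[:, fw_rows].reshape(n_surrogates, -1).max(axis=1).mean()
        bw_surr = surr[:, bw_rows].reshape(n_surrogates, -1).max(axis=1).mean()
        fw_db[i] = 10.0 * np.log10(fw / fw_surr)
        bw_db[i] = 10.0 * np.log10(bw / bw_surr)
    return WaveStats(starts / fs, fw_db, bw_db)
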