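"""Speech front-ends: gammatone filterbank, LIF spike encoding, MFCC, rate code.

The bio-inspired path mimics peripheral auditory processing: a bank of
gammatone filters (impulse response a_g t^{n-1} e^{-2 pi b t} cos(2 pi f_c t
+ phi)) models basilar-membrane frequency selectivity; the per-channel
outputs are normalized to a shared peak current and driven through leaky
integrate-and-fire neurons with spike-rate adaptation (SRA) and a refractory
conductance, producing one spike train per channel.

Units: membrane voltages in mV, time constants in ms, R_m in megohm and
currents in microamp.  The reference LIF parameterization is not
unit-consistent: a literal MOhm x uA product is volts, i.e. a 40 V drive at
the 4 uA normalization, which fires on every ripple (~160 spikes per 25 ms
frame); read as millivolts instead, the 40 mV drive never crosses threshold
once the 10 ms membrane low-passes the oscillating filterbank output.  The
drive term therefore carries an explicit gain (default 100 mV per MOhm*uA)
chosen so encoded speech-like input lands inside the reference band of
0.42-25.49 mean spikes per 25 ms frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .kernels import SpikeFrame, SpikeTrain

__all__ = [
    "GammatoneParams",
    "LIFParams",
    "erb_bandwidth",
    "erb_rate",
    "erb_rate_inverse",
    "erb_spaced_centers",
    "gammatone_filter",
    "normalize_to_current",
    "lif_encode",
    "audio_to_spikes",
    "endpoint_trim",
    "mfcc",
    "rate_code",
    "save_features",
    "load_features",
]


# -- ERB-rate scale -----------------------------------------------------------

def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """ERB-rate scale E(f) = 21.4 log10(0.00437 f + 1), f in Hz."""
    return 21.4 * np.log10(0.00437 * np.asarray(f, dtype=float) + 1.0)


def erb_rate_inverse(e: np.ndarray | float) -> np.ndarray | float:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


def erb_bandwidth(fc: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth at center frequency fc (Hz)."""
    return 24.7 * (0.00437 * np.asarray(fc, dtype=float) + 1.0)


def erb_spaced_centers(n: int, f_lo: float = 50.0, f_hi: float = 8000.0) -> np.ndarray:
    """n center frequencies equally spaced on the ERB-rate scale, endpoints included."""
    if n < 1:
        raise ValueError("need n >= 1")
    if f_hi <= f_lo or f_lo <= 0:
        raise ValueError("need 0 < f_lo < f_hi")
    if n == 1:
        return np.array([f_lo])
    return np.asarray(erb_rate_inverse(np.linspace(erb_rate(f_lo), erb_rate(f_hi), n)))


@dataclass
class GammatoneParams:
    """Gammatone filterbank layout (defaults: 12 channels, 50 Hz - 8 kHz)."""

    n_channels: int = 12
    f_lo: float = 50.0
    f_hi: float = 8000.0
    order: int = 4
    phase: float = 0.0
    bandwidth_scale: float = 1.019  # b = 1.019 * ERB(f_c)

    @property
    def centers(self) -> np.ndarray:
        return erb_spaced_centers(self.n_channels, self.f_lo, self.f_hi)

    @property
    def bandwidths(self) -> np.ndarray:
        return self.bandwidth_scale * np.asarray(erb_bandwidth(self.centers))


def _gammatone_ir(fc: float, b: float, order: int, phase: float, fs: float,
                  trunc: float = 1e-5, max_dur: float = 0.5) -> np.ndarray:
    """Truncated impulse response, peak-normalized to unit gain at fc."""
    # envelope t^{n-1} e^{-2 pi b t}; truncate where it drops below trunc * peak
    t_peak = (order - 1) / (2 * np.pi * b) if order > 1 else 0.0
    t = np.arange(0.0, max_dur, 1.0 / fs)
    env = t ** (order - 1) * np.exp(-2 * np.pi * b * t)
    peak = env.max() if env.size else 1.0
    keep = np.nonzero(env >= trunc * peak)[0]
    last = keep[-1] + 1 if keep.size else len(t)
    t = t[:last]
    ir = t ** (order - 1) * np.exp(-2 * np.pi * b * t) * np.cos(2 * np.pi * fc * t + phase)
    # scale so the magnitude response peaks at 1
    nfft = max(4096, 2 ** int(np.ceil(np.log2(len(ir) + 1))))
    gain = np.abs(np.fft.rfft(ir, nfft)).max()
    return ir / gain


def gammatone_filter(audio: np.ndarray, fs: float,
                     params: GammatoneParams | None = None) -> np.ndarray:
    """Filter audio through the bank; returns (n_channels, n_samples)."""
    params = params or GammatoneParams()
    if fs <= 2 * params.f_hi:
        raise ValueError("sampling rate must exceed twice the highest center frequency")
    audio = np.asarray(audio, dtype=float).ravel()
    out = np.empty((params.n_channels, len(audio)))
    for c, (fc, b) in enumerate(zip(params.centers, params.bandwidths)):
        ir = _gammatone_ir(fc, b, params.order, params.phase, fs)
        out[c] = fftconvolve(audio, ir, mode="full")[: len(audio)]
    return out


def normalize_to_current(traces: np.ndarray, peak_uA: float = 4.0) -> np.ndarray:
    """Scale the whole filterbank output so its global peak is `peak_uA` (uA).

    A single shared scale preserves inter-channel amplitude ratios.
    """
    traces = np.asarray(traces, dtype=float)
    peak = np.max(np.abs(traces))
    if peak == 0:
        raise ValueError("all-zero traces cannot be normalized")
    return traces * (peak_uA / peak)


# -- LIF neuron ---------------------------------------------------------------

@dataclass
class LIFParams:
    """Leaky integrate-and-fire constants (mV / ms / MOhm / uA / nS).

    The membrane obeys tau_m dV/dt = (E_rest - V) + R_m I - E_sra with
    E_sra = (V - E_k) R_m (g_sra + g_ref); a spike is emitted when V exceeds
    V_th, after which V resets and both conductances jump by their deltas and
    then decay exponentially.  E_rest defaults to -70 mV.  V_spike is a
    cosmetic spike height for plotting only and does not enter the dynamics.
    """

    R_m: float = 10.0          # MOhm
    tau_m: float = 10.0        # ms
    V_th: float = -55.0        # mV
    V_reset: float = -80.0     # mV
    E_rest: float = -70.0      # mV
    E_k: float = -200.0        # mV
    V_spike: float = 500.0     # mV, cosmetic
    tau_sra: float = 200.0     # ms
    tau_ref: float = 2.0       # ms
    delta_sra: float = 5.0     # nS
    delta_ref: float = 200.0   # nS

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau_sra, self.tau_ref) <= 0:
            raise ValueError("time constants must be positive")
        if self.V_reset >= self.V_th:
            raise ValueError("V_reset must lie below V_th")


def lif_encode(currents: np.ndarray, fs: float,
               params: LIFParams | None = None,
               drive_gain: float = 100.0) -> SpikeTrain:
    """Convert (n_channels, n_samples) current traces (uA) into a spike train.

    Forward-Euler membrane integration at dt = 1/fs; conductances decay by
    exact exponential factors between spikes.  The membrane drive is
    ``R_m (MOhm) * I (uA) * drive_gain`` millivolt; see the module docstring
    for why the gain exists.
    """
    params = params or LIFParams()
    currents = np.atleast_2d(np.asarray(currents, dtype=float))
    if not np.all(np.isfinite(currents)):
        raise ValueError("currents must be finite")
    C, N = currents.shape
    dt_ms = 1000.0 / fs
    V = np.full(C, params.E_rest)
    g_sra = np.zeros(C)
    g_ref = np.zeros(C)
    decay_sra = np.exp(-dt_ms / params.tau_sra)
    decay_ref = np.exp(-dt_ms / params.tau_ref)
    rm_g_scale = params.R_m * 1e-3  # MOhm * nS = 1e-3 (dimensionless)
    spikes: list[list[float]] = [[] for _ in range(C)]
    for k in range(N):
        drive = params.R_m * currents[:, k] * drive_gain  # mV
        leak_sra = (V - params.E_k) * rm_g_scale * (g_sra + g_ref)
        V = V + (dt_ms / params.tau_m) * ((params.E_rest - V) + drive - leak_sra)
        g_sra *= decay_sra
        g_ref *= decay_ref
        fired = V > params.V_th
        if np.any(fired):
            t = (k + 1) / fs
            for c in np.nonzero(fired)[0]:
                spikes[c].append(t)
            V[fired] = params.V_reset
            g_sra[fired] += params.delta_sra
            g_ref[fired] += params.delta_ref
    duration = N / fs
    return SpikeTrain([np.asarray(ch) for ch in spikes], duration)


def audio_to_spikes(audio: np.ndarray, fs: float,
                    gparams: GammatoneParams | None = None,
                    lparams: LIFParams | None = None,
                    peak_uA: float = 4.0,
                    drive_gain: float = 100.0) -> SpikeTrain:
    """Full bio-inspired path: gammatone -> current normalization -> LIF."""
    traces = gammatone_filter(audio, fs, gparams)
    currents = normalize_to_current(traces, peak_uA)
    return lif_encode(currents, fs, lparams, drive_gain)


# -- endpoint detection -------------------------------------------------------

def endpoint_trim(audio: np.ndarray, fs: float, threshold: float = 0.01,
                  frame_len: float = 0.010) -> np.ndarray:
    """Amplitude-normalize then crop to the active region.

    The signal is scaled to max |x| = 1, split into non-overlapping frames
    (10 ms default), and cropped to the smallest window containing every
    frame whose energy reaches `threshold` times the maximum frame energy.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        raise ValueError("empty audio")
    peak = np.max(np.abs(audio))
    if peak == 0:
        warnings.warn("silent input; returning unchanged")
        return audio
    x = audio / peak
    n = int(round(frame_len * fs))
    n_frames = max(1, len(x) // n)
    energies = np.array([np.sum(x[i * n:(i + 1) * n] ** 2) for i in range(n_frames)])
    active = np.nonzero(energies >= threshold * energies.max())[0]
    if active.size == 0:
        warnings.warn("no frame passed the energy threshold; returning unchanged")
        return x
    start = active[0] * n
    end = min(len(x), (active[-1] + 1) * n)
    return x[start:end]


# -- MFCC ---------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float) -> np.ndarray:
    """Triangular filters equally spaced on the Mel scale over [0, fs/2]."""
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_filters + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bins = np.floor((nfft + 1) * hz_pts / fs).astype(int)
    fbank = np.zeros((n_filters, nfft // 2 + 1))
    for j in range(n_filters):
        lo, mid, hi = bins[j], bins[j + 1], bins[j + 2]
        for k in range(lo, mid):
            if mid > lo:
                fbank[j, k] = (k - lo) / (mid - lo)
        for k in range(mid, hi):
            if hi > mid:
                fbank[j, k] = (hi - k) / (hi - mid)
    return fbank


def mfcc(audio: np.ndarray, fs: float, n_coeffs: int = 12, n_filters: int = 26,
         frame_len: float = 0.025, stride: float = 0.010,
         preemphasis: float = 0.95, nfft: int = 512) -> np.ndarray:
    """Mel-frequency cepstral coefficients, (n_frames, n_coeffs).

    25 ms Hamming frames at 100 fps, first-order pre-emphasis (alpha = 0.95),
    magnitude spectrum, triangular Mel filterbank, log compression and an
    orthonormal DCT-II; thirteen coefficients are computed and c0 is dropped.
    """
    from scipy.fft import dct

    audio = np.asarray(audio, dtype=float).ravel()
    n = int(round(frame_len * fs))
    step = int(round(stride * fs))
    if len(audio) < n:
        raise ValueError("audio shorter than one frame")
    x = np.append(audio[0], audio[1:] - preemphasis * audio[:-1])
    n_frames = (len(x) - n) // step + 1
    window = np.hamming(n)
    fbank = mel_filterbank(n_filters, nfft, fs)
    out = np.empty((n_frames, n_coeffs))
    for i in range(n_frames):
        frame = x[i * step: i * step + n] * window
        mag = np.abs(np.fft.rfft(frame, nfft))
        energies = np.maximum(fbank @ mag, 1e-12)
        ceps = dct(np.log(energies), type=2, norm="ortho")
        out[i] = ceps[1: n_coeffs + 1]
    return out


def rate_code(frames: list[SpikeFrame]) -> np.ndarray:
    """Per-frame, per-channel firing rate (spike count / frame duration, Hz)."""
    if not frames:
        return np.empty((0, 0))
    out = np.empty((len(frames), frames[0].n_channels))
    for i, fr in enumerate(frames):
        out[i] = [len(ch) / fr.frame_duration for ch in fr.spikes]
    return out


def save_features(path, features: np.ndarray) -> None:
    """Write a feature sequence (MFCC or rate vectors) as TSV, one frame per row."""
    np.savetxt(path, np.atleast_2d(np.asarray(features, dtype=float)),
               delimiter="\t", fmt="%.17g")


def load_features(path) -> np.ndarray:
    """Read a TSV feature sequence written by :func:`save_features`."""
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
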