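"""Seeded generators for every input the recognizer consumes.

Three families of data stand in for a licensed speech corpus:

* **Tomita grammar strings** — labeled binary sequences from the seven
  classic regular grammars, the standard benchmark for grammatical
  inference with recurrent networks.
* **Synthetic spike words** — K-class multichannel spike trains drawn from
  class-specific piecewise-constant intensity profiles (inhomogeneous
  Poisson sampling with jittered segment boundaries).  Each class plays the
  role of one vocabulary word with its own spectrotemporal firing pattern.
* **Tone words** — short audio-like waveforms built from class-specific
  formant-style tone stacks, for exercising the gammatone/LIF front-end.

Noise injection covers additive white, pink (1/f power) and a
multi-speaker-babble surrogate for continuous signals at exact target SNRs,
plus a point-process analog for spike trains (superimposed homogeneous
Poisson events, the flat-intensity counterpart of white noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import SpikeTrain

__all__ = [
    "NoiseSpec",
    "SpikeWordSpec",
    "tomita_accepts",
    "tomita_strings",
    "generate_spike_words",
    "generate_tone_words",
    "add_noise",
    "add_spike_noise",
]


# -- Tomita grammars ----------------------------------------------------------

def _t3_accepts(s: str) -> bool:
    # reject iff an odd run of 1s is immediately followed by a non-empty
    # even run of 0s
    i, n = 0, len(s)
    while i < n:
        if s[i] == "1":
            j = i
            while j < n and s[j] == "1":
                j += 1
            ones = j - i
            k = j
            while k < n and s[k] == "0":
                k += 1
            zeros = k - j
            if ones % 2 == 1 and zeros > 0 and zeros % 2 == 0:
                return False
            i = k
        else:
            i += 1
    return True


def _t7_accepts(s: str) -> bool:
    import re
    return re.fullmatch("0*1*0*1*", s) is not None


_TOMITA = {
    1: lambda s: "0" not in s,                                   # 1*
    2: lambda s: s == "10" * (len(s) // 2) and len(s) % 2 == 0,  # (10)*
    3: _t3_accepts,
    4: lambda s: "000" not in s,
    5: lambda s: s.count("0") % 2 == 0 and s.count("1") % 2 == 0,
    6: lambda s: (s.count("0") - s.count("1")) % 3 == 0,
    7: _t7_accepts,
}


def tomita_accepts(grammar_id: int, string: str) -> bool:
    """Membership of a binary string in Tomita grammar 1-7."""
    if grammar_id not in _TOMITA:
        raise ValueError("grammar_id must be in 1..7")
    if any(c not in "01" for c in string):
        raise ValueError("strings are over the alphabet {0, 1}")
    return bool(_TOMITA[grammar_id](string))


def tomita_strings(grammar_id: int, n: int, length_range: tuple[int, int] = (3, 15),
                   seed: int = 0, balanced: bool = True,
                   max_tries: int = 1_000_000):
    """Random labeled strings; (f, 1) float arrays of 0/1 symbols, labels +/-1.

    With ``balanced`` the two classes are equalized by rejection sampling
    (n//2 accepting, n - n//2 rejecting strings).
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    want = {1: n // 2, -1: n - n // 2} if balanced else None
    have = {1: 0, -1: 0}
    out = []
    for _ in range(max_tries):
        if len(out) >= n:
            break
        length = int(rng.integers(lo, hi + 1))
        bits = rng.integers(0, 2, size=length)
        label = 1 if tomita_accepts(grammar_id, "".join(map(str, bits))) else -1
        if balanced and have[label] >= want[label]:
            continue
        have[label] += 1
        out.append((bits.astype(float)[:, None], label))
    if len(out) < n:
        raise RuntimeError("rejection sampling failed to balance classes")
    # rejection fills one class quota before the other; shuffle so the
    # class sequence is exchangeable over the list
    rng.shuffle(out)
    return out


# -- synthetic spike words ----------------------------------------------------

@dataclass
class SpikeWordSpec:
    """Conditions for the K-class spike-word benchmark.

    Each class owns a (channels x segments) matrix of firing rates (Hz)
    drawn once from ``rate_range``; every sampled word realizes those rates
    as an inhomogeneous Poisson process with jittered segment boundaries.
    Defaults mimic short spoken words: 12 channels, 0.415 s (40 analysis
    frames at 100 fps with 25 ms windows), four spectrotemporal segments,
    rates 10-200 Hz (0.25-5 expected spikes per 25 ms frame, inside the
    span observed for LIF-encoded speech), 10 ms boundary jitter.
    """

    n_classes: int = 5
    n_channels: int = 12
    frames_per_word: int = 40
    frame_len: float = 0.025
    stride: float = 0.010
    n_segments: int = 4
    rate_range: tuple[float, float] = (10.0, 200.0)
    jitter: float = 0.010
    seed: int = 0

    @property
    def duration(self) -> float:
        return self.frame_len + (self.frames_per_word - 1) * self.stride

    def profiles(self) -> np.ndarray:
        """(K, channels, segments) class intensity profiles, seed-determined."""
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(0,)))
        lo, hi = self.rate_range
        if lo < 0 or hi < lo:
            raise ValueError("rates must be non-negative")
        return rng.uniform(lo, hi,
                           size=(self.n_classes, self.n_channels, self.n_segments))


def _sample_inhomogeneous(rng, rates: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Poisson spikes for piecewise-constant rates over segment edges."""
    times = []
    for r, a, b in zip(rates, edges[:-1], edges[1:]):
        if r <= 0 or b <= a:
            continue
        count = rng.poisson(r * (b - a))
        if count:
            times.append(rng.uniform(a, b, size=count))
    if not times:
        return np.empty(0)
    t = np.sort(np.concatenate(times))
    # enforce strictly increasing times (duplicate draws have measure zero,
    # but guard against float ties)
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) > 0
    return t[keep]


def generate_spike_words(spec: SpikeWordSpec, n_words: int | None = None,
                         profiles: np.ndarray | None = None,
                         seed: int | None = None):
    """Labeled multichannel spike words: list of (SpikeTrain, class_index).

    ``n_words`` is the total count, spread evenly over classes (default
    100 per class).  Pass ``profiles`` to override the class intensity
    matrices (e.g. for separability oracles).
    """
    if profiles is None:
        profiles = spec.profiles()
    profiles = np.asarray(profiles, dtype=float)
    if np.any(profiles < 0):
        raise ValueError("intensities must be non-negative")
    K = profiles.shape[0]
    n_words = n_words if n_words is not None else 100 * K
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=spec.seed if seed is None else seed, spawn_key=(1,)))
    T = spec.duration
    base_edges = np.linspace(0.0, T, spec.n_segments + 1)
    words = []
    for w in range(n_words):
        cls = w % K
        edges = base_edges.copy()
        if spec.jitter > 0:
            edges[1:-1] = edges[1:-1] + rng.uniform(
                -spec.jitter, spec.jitter, size=len(edges) - 2)
            edges = np.clip(np.sort(edges), 0.0, T)
        chans = [_sample_inhomogeneous(rng, profiles[cls, c], edges)
                 for c in range(profiles.shape[1])]
        words.append((SpikeTrain(chans, T), cls))
    return words


# -- tone words (audio surrogates) --------------------------------------------

def generate_tone_words(n_classes: int = 3, n_words: int = 30, fs: float = 22050.0,
                        duration: float = 0.4, seed: int = 0):
    """Audio-like words: class-specific stacks of 3 'formant' tones whose
    frequencies glide between two class anchors; returns (waveform, class)."""
    rng = np.random.default_rng(seed)
    anchors = rng.uniform(200.0, 3500.0, size=(n_classes, 3, 2))
    t = np.arange(int(duration * fs)) / fs
    env = np.sin(np.pi * t / duration) ** 2  # smooth on/offset
    words = []
    for w in range(n_words):
        cls = w % n_classes
        x = np.zeros_like(t)
        for f0, f1 in anchors[cls]:
            jitter = rng.normal(0, 0.02)
            freq = f0 * (1 + jitter) + (f1 - f0) * t / duration
            phase = 2 * np.pi * np.cumsum(freq) / fs
            x += rng.uniform(0.5, 1.0) * np.sin(phase)
        words.append((env * x / np.max(np.abs(env * x)), cls))
    return words


# -- noise --------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Additive-noise conditions: kind, target SNR in dB, and seed."""

    kind: str = "white"
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "pink", "babble_surrogate"):
            raise ValueError("kind must be white, pink or babble_surrogate")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def _pink_noise(rng, n: int) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])   # power ~ 1/f
    spec *= scale
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x


def _babble_surrogate(rng, n: int, fs: float, n_streams: int = 6) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(n_streams):
        stream = np.zeros(n)
        for _ in range(3):  # multi-formant tone stack
            f0 = rng.uniform(100.0, 3000.0)
            stream += np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        # syllabic-rate amplitude modulation (~2-6 Hz)
        fm = rng.uniform(2.0, 6.0)
        am = 0.5 * (1 + np.sin(2 * np.pi * fm * t + rng.uniform(0, 2 * np.pi)))
        out += am * stream
    return out


def add_noise(signal: np.ndarray, spec: NoiseSpec, fs: float = 16000.0) -> np.ndarray:
    """Add noise scaled so 10 log10(P_signal / P_noise) equals snr_db exactly.

    Powers are mean squares over the full signal.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    p_sig = float(np.mean(signal**2))
    if p_sig == 0:
        raise ValueError("zero-power signal")
    rng = np.random.default_rng(spec.seed)
    n = len(signal)
    if spec.kind == "white":
        noise = rng.standard_normal(n)
    elif spec.kind == "pink":
        noise = _pink_noise(rng, n)
    else:
        noise = _babble_surrogate(rng, n, fs)
    p_noise = float(np.mean(noise**2))
    target = p_sig / 10.0 ** (spec.snr_db / 10.0)
    return signal + noise * np.sqrt(target / p_noise)


def add_spike_noise(train: SpikeTrain, snr_db: float, seed: int = 0) -> SpikeTrain:
    """Point-process white noise: superimpose homogeneous Poisson spikes.

    The noise rate per channel follows the amplitude analogy
    ``lambda_noise = lambda_mean * 10^(-snr_db/20)`` where lambda_mean is
    that channel's mean firing rate; lower SNR therefore injects
    proportionally more spurious events.
    """
    rng = np.random.default_rng(seed)
    T = train.duration
    chans = []
    for ch in train.spikes:
        lam = len(ch) / T if T > 0 else 0.0
        lam_noise = lam * 10.0 ** (-snr_db / 20.0)
        count = rng.poisson(lam_noise * T)
        extra = rng.uniform(0.0, T, size=count)
        merged = np.sort(np.concatenate([ch, extra]))
        keep = np.ones(len(merged), dtype=bool)
        keep[1:] = np.diff(merged) > 0
        chans.append(merged[keep])
    return SpikeTrain(chans, T)
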