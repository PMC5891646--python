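"""Spike-train containers and the kernels used by the KAARMA learner.

Spike trains are multichannel ordered lists of event times.  For sequence
learning they are cut into short overlapping frames (default 25 ms at
100 fps, mirroring conventional speech analysis) and each pair of frames is
compared through the Schoenberg kernel

    K(S_a, S_b) = exp(-a_lambda * D(S_a, S_b)),

where ``D`` is a squared distance between the conditional-intensity-function
(CIF) estimates of the two frames.  With a rectangular smoothing function of
width equal to the frame duration the CIF estimate of a frame is a unit-step
staircase, and two equivalent-looking distances arise:

``ordered_set``
    squared Euclidean distance between the ordered spike-time sets, the
    shorter set padded with the frame duration, scaled by 1/T^2.  This is the
    default.
``staircase_integral``
    the exact integral of the squared difference of the two staircase CIF
    estimates over the frame.

The two coincide when the spike counts differ by at most one between any two
prefixes but differ in general; both are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "SpikeFrame",
    "KernelConfig",
    "segment_frames",
    "spike_frame_distance",
    "multichannel_distance",
    "schoenberg_kernel",
    "gaussian_kernel",
    "joint_kernel",
    "pad_frame",
    "read_spike_train",
    "write_spike_train",
]


def _as_spike_array(times: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(times) if not isinstance(times, np.ndarray) else times,
                     dtype=float).ravel()
    return arr


@dataclass
class SpikeTrain:
    """Multichannel spike train: per-channel strictly increasing times (s)."""

    spikes: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        self.spikes = [_as_spike_array(ch) for ch in self.spikes]
        self.validate()

    @property
    def n_channels(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(ch) for ch in self.spikes))

    def validate(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        for c, ch in enumerate(self.spikes):
            if ch.size and (np.any(np.diff(ch) <= 0)):
                raise ValueError(f"channel {c}: spike times must be strictly increasing")
            if ch.size and (ch[0] < 0 or ch[-1] > self.duration):
                raise ValueError(f"channel {c}: spike times outside [0, duration]")


@dataclass
class SpikeFrame:
    """One analysis frame: spike times re-referenced to the frame start.

    All times lie in ``[0, frame_duration)``; the frame is the unit of
    comparison for the spike kernel.
    """

    spikes: list[np.ndarray]
    frame_duration: float

    def __post_init__(self) -> None:
        self.spikes = [_as_spike_array(ch) for ch in self.spikes]
        for c, ch in enumerate(self.spikes):
            if ch.size and (np.any(np.diff(ch) <= 0)):
                raise ValueError(f"channel {c}: times must be strictly increasing")
            if ch.size and (ch[0] < 0 or ch[-1] >= self.frame_duration):
                raise ValueError(f"channel {c}: times must lie in [0, frame_duration)")

    @property
    def n_channels(self) -> int:
        return len(self.spikes)

    def padded(self, width: int | None = None) -> np.ndarray:
        """(channels, width) array, padded with the frame duration."""
        return pad_frame(self, width)


@dataclass
class KernelConfig:
    """Kernel sizes and spike-distance conventions.

    a_lambda : spike kernel size (default 1, the speech setting)
    a_s      : hidden-state Gaussian kernel size (default 4)
    a_u      : continuous-input Gaussian kernel size (default 5)
    """

    a_lambda: float = 1.0
    a_s: float = 4.0
    a_u: float = 5.0
    channel_aggregation: str = "mean"
    distance_mode: str = "ordered_set"

    def __post_init__(self) -> None:
        for name in ("a_lambda", "a_s", "a_u"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.channel_aggregation not in ("mean", "sum"):
            raise ValueError("channel_aggregation must be 'mean' or 'sum'")
        if self.distance_mode not in ("ordered_set", "staircase_integral"):
            raise ValueError("distance_mode must be 'ordered_set' or 'staircase_integral'")


def segment_frames(train: SpikeTrain, frame_len: float = 0.025,
                   stride: float = 0.010) -> list[SpikeFrame]:
    """Cut a spike train into half-open frames [k*stride, k*stride + frame_len).

    Spike times are shifted to frame-local coordinates; a spike inside
    overlapping windows appears in every containing frame.  Frame count is
    ``floor((duration - frame_len)/stride) + 1`` (at least one frame).
    """
    if frame_len <= 0 or stride <= 0:
        raise ValueError("frame_len and stride must be positive")
    train.validate()
    n_frames = max(1, int(np.floor((train.duration - frame_len) / stride + 1e-9)) + 1)
    frames = []
    for k in range(n_frames):
        start = k * stride
        chans = []
        for ch in train.spikes:
            local = ch[(ch >= start - 1e-12) & (ch < start + frame_len - 1e-12)] - start
            # guard tiny negative round-off
            chans.append(np.clip(local, 0.0, None))
        frames.append(SpikeFrame(chans, frame_len))
    return frames


def pad_frame(frame: SpikeFrame | Sequence[np.ndarray], width: int | None = None,
              frame_duration: float | None = None) -> np.ndarray:
    """Pad per-channel ordered spike sets with the frame duration.

    Because the pad value equals the frame duration, padding both operands of
    the ordered-set distance to any common width leaves the distance
    unchanged, so frames of different spike counts live in one array.
    """
    if isinstance(frame, SpikeFrame):
        chans, T = frame.spikes, frame.frame_duration
    else:
        if frame_duration is None:
            raise ValueError("frame_duration required for raw channel lists")
        chans, T = [_as_spike_array(c) for c in frame], frame_duration
    w = max((len(c) for c in chans), default=0)
    if width is not None:
        if width < w:
            raise ValueError("width smaller than longest channel")
        w = width
    out = np.full((len(chans), w), T, dtype=float)
    for i, c in enumerate(chans):
        out[i, : len(c)] = c
    return out


def _ordered_set_distance(a: np.ndarray, b: np.ndarray, T: float) -> float:
    m = max(len(a), len(b))
    pa = np.full(m, T)
    pb = np.full(m, T)
    pa[: len(a)] = a
    pb[: len(b)] = b
    return float(np.sum((pa - pb) ** 2) / T**2)


def _staircase_distance(a: np.ndarray, b: np.ndarray, T: float) -> float:
    # CIF estimate with rectangular smoothing of width T is N(t)/T inside the
    # frame; integrate the squared count difference exactly over breakpoints.
    if len(a) == 0 and len(b) == 0:
        return 0.0
    t = np.concatenate([a, b])
    d = np.concatenate([np.ones(len(a)), -np.ones(len(b))])
    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    counts = np.cumsum(d)               # count difference on [t_k, t_{k+1})
    next_edge = np.append(t[1:], T)     # before t_0 the difference is zero
    integral = float(np.sum(counts**2 * (next_edge - t)))
    return integral / T**2


def spike_frame_distance(a, b, frame_duration: float | None = None,
                         mode: str = "ordered_set") -> float:
    """Squared CIF distance between two single-channel spike sets.

    Parameters may be raw ordered arrays plus ``frame_duration``, or two
    single-channel :class:`SpikeFrame` objects (durations must match).
    """
    if isinstance(a, SpikeFrame):
        if not isinstance(b, SpikeFrame) or abs(a.frame_duration - b.frame_duration) > 1e-12:
            raise ValueError("frames must share the same duration")
        if a.n_channels != 1 or b.n_channels != 1:
            raise ValueError("per-channel distance expects single-channel frames")
        frame_duration = a.frame_duration
        a, b = a.spikes[0], b.spikes[0]
    if frame_duration is None or frame_duration <= 0:
        raise ValueError("frame_duration must be positive")
    a = _as_spike_array(a)
    b = _as_spike_array(b)
    if mode == "ordered_set":
        return _ordered_set_distance(a, b, frame_duration)
    if mode == "staircase_integral":
        return _staircase_distance(a, b, frame_duration)
    raise ValueError(f"unknown distance mode {mode!r}")


def multichannel_distance(a: SpikeFrame, b: SpikeFrame,
                          cfg: KernelConfig | None = None) -> float:
    """Aggregate (mean or sum) of per-channel spike-frame distances."""
    cfg = cfg or KernelConfig()
    if a.n_channels != b.n_channels:
        raise ValueError("channel counts differ")
    if abs(a.frame_duration - b.frame_duration) > 1e-12:
        raise ValueError("frame durations differ")
    d = [spike_frame_distance(ca, cb, a.frame_duration, cfg.distance_mode)
         for ca, cb in zip(a.spikes, b.spikes)]
    return float(np.mean(d)) if cfg.channel_aggregation == "mean" else float(np.sum(d))


def schoenberg_kernel(a: SpikeFrame, b: SpikeFrame,
                      cfg: KernelConfig | None = None) -> float:
    """exp(-a_lambda * D) on the aggregated multichannel CIF distance."""
    cfg = cfg or KernelConfig()
    return float(np.exp(-cfg.a_lambda * multichannel_distance(a, b, cfg)))


def gaussian_kernel(v: np.ndarray, w: np.ndarray, size: float) -> float:
    """exp(-size * ||v - w||^2)."""
    v = np.asarray(v, dtype=float).ravel()
    w = np.asarray(w, dtype=float).ravel()
    if v.shape != w.shape:
        raise ValueError("dimension mismatch")
    if size <= 0:
        raise ValueError("kernel size must be positive")
    return float(np.exp(-size * np.sum((v - w) ** 2)))


def joint_kernel(s, u, s2, u2, cfg: KernelConfig | None = None) -> float:
    """Tensor-product kernel K_s(s, s') * K_u(u, u').

    The state factor is always Gaussian (size ``a_s``).  The input factor is
    the Schoenberg spike kernel when inputs are spike frames and a Gaussian
    (size ``a_u``) when they are continuous vectors.
    """
    cfg = cfg or KernelConfig()
    ks = gaussian_kernel(s, s2, cfg.a_s)
    a_spike = isinstance(u, SpikeFrame)
    b_spike = isinstance(u2, SpikeFrame)
    if a_spike != b_spike:
        raise ValueError("mixed input kinds")
    if a_spike:
        ku = schoenberg_kernel(u, u2, cfg)
    else:
        ku = gaussian_kernel(u, u2, cfg.a_u)
    return ks * ku


# ---------------------------------------------------------------------------
# spike-train text format: header `#channels=N duration=D`, then
# `channel<TAB>time_seconds` records, channels 0-based, times ascending.

def write_spike_train(train: SpikeTrain, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#channels={train.n_channels} duration={float(train.duration)!r}\n")
        for c, ch in enumerate(train.spikes):
            for t in ch:
                fh.write(f"{c}\t{float(t)!r}\n")


def read_spike_train(path: str | Path) -> SpikeTrain:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#channels="):
            raise ValueError(f"{path}:1: missing '#channels=N duration=D' header")
        try:
            parts = dict(p.split("=") for p in header.lstrip("#").split())
            n_channels = int(parts["channels"])
            duration = float(parts["duration"])
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}:1: malformed header: {header!r}") from exc
        spikes: list[list[float]] = [[] for _ in range(n_channels)]
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                c_str, t_str = line.split("\t")
                c, t = int(c_str), float(t_str)
                spikes[c].append(t)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: bad record {line!r}") from exc
    return SpikeTrain([np.asarray(ch) for ch in spikes], duration)
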