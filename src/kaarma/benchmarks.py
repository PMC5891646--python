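"""Reproducible experiment runners shared by tests, CLI and scripts.

Two benchmarks exercise the full system without any external corpus:

* :func:`run_tomita_experiment` — single-pass grammatical inference on a
  Tomita grammar with one KAARMA network.
* :func:`run_spike_word_benchmark` — the K-class synthetic spike-word task:
  segment words into frames, train forward and reversed KAARMA chains
  (one-vs-all banks, one epoch), evaluate clean and optionally under
  point-process noise at a list of SNRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import KaarmaChainClassifier, classify
from .kernels import SpikeTrain, segment_frames
from .network import KaarmaNetwork
from .synthetic import SpikeWordSpec, add_spike_noise, generate_spike_words, \
    tomita_strings

__all__ = [
    "TomitaResult",
    "symbol_frames",
    "SpikeWordResult",
    "run_tomita_experiment",
    "run_spike_word_benchmark",
    "frames_to_arrays",
]


def frames_to_arrays(train: SpikeTrain, frame_len: float = 0.025,
                     stride: float = 0.010, width: int | None = None) -> np.ndarray:
    """Segment a spike train and stack padded frames into one (f, C, P) array."""
    frames = segment_frames(train, frame_len, stride)
    padded = [f.padded() for f in frames]
    w = max([p.shape[1] for p in padded] + [width or 1])
    out = np.full((len(padded), padded[0].shape[0], w), frame_len)
    for i, p in enumerate(padded):
        out[i, :, : p.shape[1]] = p
    return out


@dataclass
class TomitaResult:
    train_accuracy: float
    test_accuracy: float
    dictionary_size: int
    training_frames: int


def symbol_frames(string: np.ndarray, width: int = 3) -> np.ndarray:
    """Overlapping symbol windows (stride 1), symbols recoded 0/1 -> -1/+1.

    The recognizer is frame-based throughout (speech frames are overlapping
    windows of the signal); grammar strings are presented the same way, as
    sliding windows of ``width`` consecutive symbols.  Strings shorter than
    the window are padded by repeating the final symbol.
    """
    s = 2.0 * np.asarray(string, dtype=float).reshape(-1, 1) - 1.0
    if len(s) < width:
        s = np.vstack([s, np.repeat(s[-1:], width - len(s), axis=0)])
    return np.hstack([s[i: len(s) - width + 1 + i] for i in range(width)])


def run_tomita_experiment(seed: int = 0, grammar_id: int = 4,
                          n_train: int = 1000, n_test: int = 200,
                          length_range: tuple[int, int] = (3, 15),
                          frame_width: int = 3,
                          state_dim: int = 4, a_s: float = 1.0, a_u: float = 1.0,
                          eta: float = 0.05, epsilon: float = 0.005,
                          epochs: int = 1) -> TomitaResult:
    """Train one KAARMA network on a Tomita grammar, single pass by default."""
    train = tomita_strings(grammar_id, n_train, length_range, seed=seed)
    test = tomita_strings(grammar_id, n_test, length_range, seed=seed + 50_000)
    net = KaarmaNetwork(state_dim=state_dim, output_dim=1, input_kind="vector",
                        a_s=a_s, a_u=a_u, eta=eta, epsilon=epsilon, epochs=epochs)
    X = [symbol_frames(s, frame_width) for s, _ in train]
    y = [l for _, l in train]
    net.fit(X, y)

    def acc(data):
        pred = net.predict([symbol_frames(s, frame_width) for s, _ in data])
        return float(np.mean(pred == np.asarray([l for _, l in data])))

    return TomitaResult(train_accuracy=acc(train), test_accuracy=acc(test),
                        dictionary_size=net.dictionary_size_,
                        training_frames=net.stats_["proposals"])


@dataclass
class SpikeWordResult:
    forward_accuracy: float
    reversed_accuracy: float
    bidirectional_accuracy: float
    noise_accuracy: dict = field(default_factory=dict)  # snr_db -> accuracy
    dictionary_sizes: dict = field(default_factory=dict)
    training_frames: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0


def _direction_accuracy(model: KaarmaChainClassifier, X, y,
                        direction: str) -> float:
    from .chain import _reverse
    correct = 0
    for seq, label in zip(X, y):
        s = seq if direction == "forward" else _reverse(seq)
        scores = model.chain_score(s, direction)
        correct += model.classes_[classify(scores)] == label
    return correct / len(y)


def run_spike_word_benchmark(seed: int = 0, spec: SpikeWordSpec | None = None,
                             train_fraction: float = 2 / 3,
                             n_states: int = 5, epsilon: float = 0.25,
                             snr_list: tuple[float, ...] = (),
                             model_kwargs: dict | None = None) -> SpikeWordResult:
    """Full spike-word run: generate, split 67/33, train chains, evaluate."""
    spec = spec or SpikeWordSpec(seed=seed)
    if spec.seed != seed:
        spec = SpikeWordSpec(**{**spec.__dict__, "seed": seed})
    words = generate_spike_words(spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))
    X = [frames_to_arrays(w, spec.frame_len, spec.stride) for w, _ in words]
    y = np.asarray([c for _, c in words])
    # stratified split
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        cut = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:cut])
        test_idx.extend(idx[cut:])
    train_idx = np.asarray(sorted(train_idx))
    test_idx = np.asarray(sorted(test_idx))

    model = KaarmaChainClassifier(
        n_states=n_states, bidirectional=True, epsilon=epsilon,
        frame_duration=spec.frame_len, random_state=seed,
        **(model_kwargs or {}))
    model.fit([X[i] for i in train_idx], y[train_idx])

    X_test = [X[i] for i in test_idx]
    y_test = y[test_idx]
    fwd = _direction_accuracy(model, X_test, y_test, "forward")
    rev = _direction_accuracy(model, X_test, y_test, "reversed")
    pred = model.predict(X_test)
    bidi = float(np.mean(pred == y_test))

    noise_acc = {}
    for snr in snr_list:
        correct = 0
        for j, i in enumerate(test_idx):
            noisy = add_spike_noise(words[i][0], snr,
                                    seed=int(seed * 1000 + i) % (2**31 - 1))
            seq = frames_to_arrays(noisy, spec.frame_len, spec.stride)
            correct += model.predict([seq])[0] == y_test[j]
        noise_acc[snr] = correct / len(y_test)

    return SpikeWordResult(
        forward_accuracy=fwd, reversed_accuracy=rev, bidirectional_accuracy=bidi,
        noise_accuracy=noise_acc,
        dictionary_sizes=dict(model.dictionary_sizes_),
        training_frames=dict(model.training_frames_),
        n_train=len(train_idx), n_test=len(test_idx))


@dataclass
class CompactionResult:
    dictionary_size: int
    training_frames: int
    zero_distance_merges: int

    @property
    def ratio(self) -> float:
        return self.dictionary_size / self.training_frames


def run_compaction_check(seed: int = 0, epsilon: float = 0.25,
                         spec: SpikeWordSpec | None = None,
                         n_states: int = 5) -> CompactionResult:
    """Dictionary growth of one one-vs-all network of the spike-word chain.

    Trains the (grammar state 0, class 0) network of the spike-word
    benchmark at the given quantization threshold and reports its dictionary
    size m against the total number of training frames n.  With epsilon = 0
    only exact duplicates merge, so m equals n minus the zero-distance
    merges; at the reference threshold the dictionary is much smaller.
    """
    from .chain import _replicate_positives, partition

    spec = spec or SpikeWordSpec(seed=seed)
    if spec.seed != seed:
        spec = SpikeWordSpec(**{**spec.__dict__, "seed": seed})
    words = generate_spike_words(spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(2,)))
    X = [frames_to_arrays(w, spec.frame_len, spec.stride) for w, _ in words]
    y = np.asarray([c for _, c in words])
    train_idx = []
    for cls in np.unique(y):
        idx = rng.permutation(np.nonzero(y == cls)[0])
        train_idx.extend(idx[: int(round(2 / 3 * len(idx)))])
    train_idx = sorted(train_idx)
    segs = [partition(X[i], n_states)[0] for i in train_idx]
    labels = np.where(y[train_idx] == 0, 1.0, -1.0)
    rng_rep = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(0, 0, 0)))
    segs, labels = _replicate_positives(segs, labels, 3, rng_rep)
    net = KaarmaNetwork(input_kind="spike", frame_duration=spec.frame_len,
                        epsilon=epsilon)
    net.fit(segs, labels)
    return CompactionResult(
        dictionary_size=net.dictionary_size_,
        training_frames=net.stats_["proposals"],
        zero_distance_merges=net.stats_["merged_zero_distance"])
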