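"""KAARMA-chain isolated-word classifier.

A word utterance is partitioned into L contiguous, near-equal "grammar
state" segments (no alignment step; the last frame is replicated when the
utterance is shorter than L).  Each grammar state holds a one-vs-all bank of
K KAARMA networks; within a state, the K final outputs pass through a
softmax to form class posteriors, and the chain score of a class is the
product of its per-state posteriors (chain transitions are fixed at
a_{i,i+1} = 1).  The recognized word is the argmax of the product score
(MAP), optionally fused with a second chain trained on frame-reversed
sequences by multiplying the two scores.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .network import KaarmaNetwork

__all__ = [
    "KaarmaChainClassifier",
    "partition",
    "softmax_scores",
    "chain_score",
    "bidirectional_score",
    "classify",
    "train_chain",
]


def _seq_len(seq) -> int:
    return seq.shape[0] if isinstance(seq, np.ndarray) else len(seq)


def _reverse(seq):
    if isinstance(seq, np.ndarray):
        return seq[::-1].copy()
    return list(reversed(seq))


def partition(seq, n_states: int) -> list:
    """Split a frame sequence into L contiguous near-equal segments.

    Sequences shorter than L are padded by repeating the final frame; sizes
    are ceil(f/L) for the first f mod L segments and floor(f/L) after
    (remainder-first), so concatenation reproduces the input order.
    """
    f = _seq_len(seq)
    if f == 0:
        raise ValueError("empty sequence")
    if n_states < 1:
        raise ValueError("need n_states >= 1")
    if f < n_states:
        if isinstance(seq, np.ndarray):
            pad = np.repeat(seq[-1:], n_states - f, axis=0)
            seq = np.concatenate([seq, pad], axis=0)
        else:
            seq = list(seq) + [seq[-1]] * (n_states - f)
        f = n_states
    base, rem = divmod(f, n_states)
    sizes = [base + 1] * rem + [base] * (n_states - rem)
    out, pos = [], 0
    for sz in sizes:
        out.append(seq[pos: pos + sz])
        pos += sz
    return out


def softmax_scores(outputs: np.ndarray) -> np.ndarray:
    """Softmax over per-class final outputs (max-subtracted for stability)."""
    y = np.asarray(outputs, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite outputs")
    z = np.exp(y - y.max())
    return z / z.sum()


def classify(scores: np.ndarray) -> int:
    """Argmax class index; lowest index wins exact ties."""
    return int(np.argmax(np.asarray(scores, dtype=float)))


class KaarmaChainClassifier(ClassifierMixin, BaseEstimator):
    """Isolated-word classifier made of L x K (x 2 directions) KAARMA banks.

    Parameters
    ----------
    n_states : number of grammar states L.
    bidirectional : also train a reversed-order chain and fuse by score product.
    state_dim, a_s, a_u, a_lambda, frame_duration, channel_aggregation,
    eta, epsilon, epochs : forwarded to each :class:`KaarmaNetwork`
        (one-vs-all, single output, targets +/-1).
    positive_replication : extra copies of the positive class inserted at
        seeded random positions in each one-vs-all training set (default 3).
    random_state : master seed; per-network streams are spawned from it.

    Attributes
    ----------
    classes_ : sorted class labels.
    networks_ : dict {(direction, state, class_index): KaarmaNetwork}.
    dictionary_sizes_, training_frames_ : per-network compaction stats.
    """

    def __init__(self, n_states: int = 5, bidirectional: bool = True,
                 state_dim: int = 3, a_s: float = 4.0, a_u: float = 5.0,
                 a_lambda: float = 1.0, frame_duration: float = 0.025,
                 channel_aggregation: str = "mean", eta: float = 0.1,
                 epsilon: float = 0.25, epochs: int = 1,
                 positive_replication: int = 3, random_state: int = 0):
        self.n_states = n_states
        self.bidirectional = bidirectional
        self.state_dim = state_dim
        self.a_s = a_s
        self.a_u = a_u
        self.a_lambda = a_lambda
        self.frame_duration = frame_duration
        self.channel_aggregation = channel_aggregation
        self.eta = eta
        self.epsilon = epsilon
        self.epochs = epochs
        self.positive_replication = positive_replication
        self.random_state = random_state

    def _infer_kind(self, seq) -> str:
        if isinstance(seq, np.ndarray) and seq.ndim == 3:
            return "spike"
        if isinstance(seq, np.ndarray) and seq.ndim in (1, 2):
            return "vector"
        return "spike"  # list of SpikeFrame

    def _make_network(self) -> KaarmaNetwork:
        return KaarmaNetwork(
            state_dim=self.state_dim, output_dim=1, input_kind=self.input_kind_,
            a_s=self.a_s, a_u=self.a_u, a_lambda=self.a_lambda,
            frame_duration=self.frame_duration,
            channel_aggregation=self.channel_aggregation,
            eta=self.eta, epsilon=self.epsilon, epochs=self.epochs)

    def fit(self, X, y):
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need sequences from at least two classes")
        self.input_kind_ = self._infer_kind(X[0])
        directions = ["forward", "reversed"] if self.bidirectional else ["forward"]
        # pre-partition once per direction
        segments = {}
        for d in directions:
            seqs = X if d == "forward" else [_reverse(s) for s in X]
            segments[d] = [partition(s, self.n_states) for s in seqs]
        self.networks_ = {}
        self.dictionary_sizes_ = {}
        self.training_frames_ = {}
        for di, d in enumerate(directions):
            for state in range(self.n_states):
                for ci, cls in enumerate(self.classes_):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(
                            entropy=self.random_state,
                            spawn_key=(di, state, ci)))
                    seqs = [segs[state] for segs in segments[d]]
                    labels = np.where(y == cls, 1.0, -1.0)
                    seqs, labels = _replicate_positives(
                        seqs, labels, self.positive_replication, rng)
                    net = self._make_network()
                    net.fit(seqs, labels)
                    key = (d, state, ci)
                    self.networks_[key] = net
                    self.dictionary_sizes_[key] = net.dictionary_size_
                    self.training_frames_[key] = net.stats_["proposals"]
        return self

    # -- scoring ---------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "networks_"):
            raise RuntimeError("chain is not trained")

    def _log_chain_score(self, seq, direction: str) -> np.ndarray:
        """Per-class sum of log per-state softmax posteriors."""
        self._check_fitted()
        segs = partition(seq, self.n_states)
        K = len(self.classes_)
        log_score = np.zeros(K)
        for state, seg in enumerate(segs):
            outputs = np.empty(K)
            for ci in range(K):
                _, y_f = self.networks_[(direction, state, ci)].forward(seg)
                outputs[ci] = y_f[0]
            log_score += np.log(softmax_scores(outputs))
        return log_score

    def chain_score(self, seq, direction: str = "forward") -> np.ndarray:
        """Product over grammar states of per-state class posteriors."""
        return np.exp(self._log_chain_score(seq, direction))

    def score_sequence(self, seq) -> np.ndarray:
        """Per-class score; bi-directional chains multiply fwd/rev scores."""
        log_s = self._log_chain_score(seq, "forward")
        if self.bidirectional:
            log_s = log_s + self._log_chain_score(_reverse(seq), "reversed")
        return np.exp(log_s)

    def predict(self, X) -> np.ndarray:
        return np.asarray([self.classes_[classify(self.score_sequence(s))]
                           for s in X])

    def predict_scores(self, X) -> np.ndarray:
        return np.vstack([self.score_sequence(s) for s in X])

    # -- serialization ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "format": "kaarma-chain/1",
            "params": self.get_params(),
            "classes": np.asarray(self.classes_).tolist(),
            "input_kind": self.input_kind_,
            "networks": {
                f"{d}/{state}/{ci}": net.to_dict()
                for (d, state, ci), net in self.networks_.items()
            },
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "KaarmaChainClassifier":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "kaarma-chain/1":
            raise ValueError("unrecognized model container format")
        model = cls(**payload["params"])
        model.classes_ = np.asarray(payload["classes"])
        model.input_kind_ = payload["input_kind"]
        model.networks_ = {}
        for key, net_payload in payload["networks"].items():
            d, state, ci = key.split("/")
            model.networks_[(d, int(state), int(ci))] = \
                KaarmaNetwork.from_dict(net_payload)
        model.dictionary_sizes_ = {
            k: net.dictionary_size_ for k, net in model.networks_.items()}
        model.training_frames_ = {
            k: net.stats_["proposals"] for k, net in model.networks_.items()}
        return model


def _replicate_positives(seqs: list, labels: np.ndarray, copies: int, rng):
    """Insert `copies` extra copies of each positive sequence at random slots."""
    positives = [s for s, l in zip(seqs, labels) if l > 0]
    seqs = list(seqs)
    labels = list(labels)
    for s in positives:
        for _ in range(copies):
            slot = int(rng.integers(0, len(seqs) + 1))
            seqs.insert(slot, s)
            labels.insert(slot, 1.0)
    return seqs, np.asarray(labels)


# -- thin functional wrappers --------------------------------------------------

def chain_score(chain: KaarmaChainClassifier, seq,
                direction: str = "forward") -> np.ndarray:
    return chain.chain_score(seq, direction)


def bidirectional_score(chain_fwd: KaarmaChainClassifier,
                        chain_rev: KaarmaChainClassifier, seq) -> np.ndarray:
    """Element-wise product of forward and reversed-chain scores.

    The two chains must share class layout and state count.
    """
    if len(chain_fwd.classes_) != len(chain_rev.classes_) or \
            chain_fwd.n_states != chain_rev.n_states:
        raise ValueError("mismatched chains")
    fwd = chain_fwd.chain_score(seq, "forward")
    rev_dir = "reversed" if ("reversed", 0, 0) in chain_rev.networks_ else "forward"
    rev = chain_rev.chain_score(_reverse(seq), rev_dir)
    return fwd * rev


def train_chain(dataset, n_classes: int | None = None, n_states: int = 5,
                cfg=None, **kwargs) -> KaarmaChainClassifier:
    """Train a chain from a list of (sequence, label) pairs."""
    X = [s for s, _ in dataset]
    y = [l for _, l in dataset]
    params = dict(n_states=n_states)
    if cfg is not None:
        params.update(eta=cfg.eta, epsilon=cfg.epsilon, epochs=cfg.epochs,
                      random_state=cfg.seed)
    params.update(kwargs)
    return KaarmaChainClassifier(**params).fit(X, y)
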