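"""Binary-state linear-chain conditional random field.

The model scores a label sequence y for an observation matrix X as

    score(y | X) = sum_i  x_i · w_{y_i}  +  sum_i  T[y_{i-1}, y_i]

with conditional probability P(y|X) = exp(score) / Z(X).  Observations
enter only through label-unigram weights (per-offset context is baked
into the expanded observation matrix); the label-bigram transitions carry
no observation.  All inference runs in log space, so chains up to 1e5
residues are safe from underflow.  Training maximizes the L2-penalized
conditional log-likelihood with exact gradients and a deterministic
limited-memory quasi-Newton optimizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

STATES = ("nonturn", "turn")
N_STATES = 2


@dataclass
class CRFModel:
    """Weights of the binary linear-chain CRF."""

    unigram_weights: np.ndarray         # (D, 2)
    transition_weights: np.ndarray      # (2, 2), rows = previous state
    l2_sigma: float = 1.0
    feature_names: list[str] = field(default_factory=list)
    states: tuple[str, str] = STATES

    def __post_init__(self) -> None:
        self.unigram_weights = np.asarray(self.unigram_weights, dtype=float)
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        if self.unigram_weights.ndim != 2 or self.unigram_weights.shape[1] != N_STATES:
            raise ValueError("unigram_weights must be (D, 2)")
        if self.transition_weights.shape != (N_STATES, N_STATES):
            raise ValueError("transition_weights must be 2x2")
        if not (np.isfinite(self.unigram_weights).all()
                and np.isfinite(self.transition_weights).all()):
            raise ValueError("non-finite weights")
        if self.l2_sigma <= 0:
            raise ValueError("l2_sigma must be positive")

    @property
    def n_features(self) -> int:
        return self.unigram_weights.shape[0]


@dataclass
class TrainConfig:
    l2_sigma: float = 1.0
    max_iterations: int = 200
    gradient_tolerance: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_sigma <= 0:
            raise ValueError("l2_sigma must be positive")


@dataclass
class PredictionResult:
    labels: np.ndarray              # uint8
    turn_probability: np.ndarray    # posterior marginal of the turn state
    decision_threshold: float
    viterbi_path: np.ndarray | None = None


def sequence_log_potentials(model: CRFModel, expanded: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Node scores (L×2) = expanded · unigram weights; edge scores are the
    position-independent 2×2 transition weights."""
    expanded = np.asarray(expanded, dtype=float)
    if expanded.ndim != 2 or expanded.shape[1] != model.n_features:
        raise ValueError(
            f"observation width {expanded.shape[1] if expanded.ndim == 2 else '?'} "
            f"does not match model width {model.n_features}"
        )
    return expanded @ model.unigram_weights, model.transition_weights.copy()


def _check_scores(node: np.ndarray, edge: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    node = np.asarray(node, dtype=float)
    edge = np.asarray(edge, dtype=float)
    if node.ndim != 2 or node.shape[1] != N_STATES or node.shape[0] < 1:
        raise ValueError("node scores must be (L, 2) with L >= 1")
    if edge.shape != (N_STATES, N_STATES):
        raise ValueError("edge scores must be 2x2")
    if not (np.isfinite(node).all() and np.isfinite(edge).all()):
        raise ValueError("non-finite potentials")
    return node, edge


def forward_backward(node: np.ndarray, edge: np.ndarray
                     ) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact inference in log space.

    Returns ``(log_partition, marginals, pair_marginals)`` where
    `marginals` is L×2 (each row sums to 1) and `pair_marginals` is
    (L−1)×2×2 posterior edge marginals.
    """
    node, edge = _check_scores(node, edge)
    L = node.shape[0]
    alpha = np.empty((L, N_STATES))
    beta = np.empty((L, N_STATES))
    alpha[0] = node[0]
    for t in range(1, L):
        alpha[t] = node[t] + logsumexp(alpha[t - 1][:, None] + edge, axis=0)
    beta[L - 1] = 0.0
    for t in range(L - 2, -1, -1):
        beta[t] = logsumexp(edge + (node[t + 1] + beta[t + 1])[None, :], axis=1)
    log_z = float(logsumexp(alpha[L - 1]))
    log_z_b = float(logsumexp(node[0] + beta[0]))
    marginals = np.exp(alpha + beta - log_z)
    marginals /= marginals.sum(axis=1, keepdims=True)
    pair = np.empty((max(L - 1, 0), N_STATES, N_STATES))
    for t in range(L - 1):
        m = (alpha[t][:, None] + edge
             + (node[t + 1] + beta[t + 1])[None, :]) - log_z
        pair[t] = np.exp(m)
        pair[t] /= pair[t].sum()
    # consistency of the two recursions is a numerical self-check
    if abs(log_z - log_z_b) > 1e-8 * max(1.0, abs(log_z)):
        warnings.warn(
            f"forward/backward log-partition mismatch: {log_z} vs {log_z_b}"
        )
    return log_z, marginals, pair


def viterbi(node: np.ndarray, edge: np.ndarray) -> np.ndarray:
    """Argmax label path; ties resolve toward state 0 (nonturn)."""
    node, edge = _check_scores(node, edge)
    L = node.shape[0]
    delta = np.empty((L, N_STATES))
    back = np.zeros((L, N_STATES), dtype=np.int8)
    delta[0] = node[0]
    for t in range(1, L):
        cand = delta[t - 1][:, None] + edge          # (from, to)
        back[t] = np.argmax(cand, axis=0)            # first max → state 0 wins ties
        delta[t] = node[t] + np.max(cand, axis=0)
    path = np.empty(L, dtype=np.uint8)
    path[L - 1] = int(np.argmax(delta[L - 1]))
    for t in range(L - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def path_score(node: np.ndarray, edge: np.ndarray, path: Sequence[int]) -> float:
    node = np.asarray(node, dtype=float)
    s = float(node[0, path[0]])
    for t in range(1, len(path)):
        s += float(edge[path[t - 1], path[t]]) + float(node[t, path[t]])
    return s


# ---------------------------------------------------------------------------
# Batched inference for training (sequences grouped by length)


def _forward_backward_batch(nodes: np.ndarray, edge: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """nodes: (B, L, 2).  Returns logZ (B,), marginals (B, L, 2) and pair
    marginals (B, L-1, 2, 2)."""
    B, L, _ = nodes.shape
    alpha = np.empty((B, L, N_STATES))
    beta = np.empty((B, L, N_STATES))
    alpha[:, 0] = nodes[:, 0]
    # two-state recursions use the logaddexp ufunc directly (no generic
    # logsumexp overhead in the hot loop)
    for t in range(1, L):
        prev = alpha[:, t - 1]
        alpha[:, t] = nodes[:, t] + np.logaddexp(
            prev[:, 0, None] + edge[0], prev[:, 1, None] + edge[1])
    beta[:, L - 1] = 0.0
    for t in range(L - 2, -1, -1):
        nxt = nodes[:, t + 1] + beta[:, t + 1]
        beta[:, t] = np.logaddexp(nxt[:, None, 0] + edge[:, 0],
                                  nxt[:, None, 1] + edge[:, 1])
    log_z = np.logaddexp(alpha[:, L - 1, 0], alpha[:, L - 1, 1])
    marg = np.exp(alpha + beta - log_z[:, None, None])
    marg /= marg.sum(axis=2, keepdims=True)
    if L > 1:
        pair = np.exp(
            alpha[:, :-1, :, None] + edge[None, None, :, :]
            + (nodes[:, 1:] + beta[:, 1:])[:, :, None, :]
            - log_z[:, None, None, None])
        pair /= pair.sum(axis=(2, 3), keepdims=True)
    else:
        pair = np.zeros((B, 0, N_STATES, N_STATES))
    return log_z, marg, pair


def _group_by_length(dataset) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for idx, (X, y) in enumerate(dataset):
        groups.setdefault(X.shape[0], []).append(idx)
    return groups


def _as_arrays(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    width = None
    for X, y in dataset:
        X = np.asarray(getattr(X, "values", X), dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("each item must be (L x D observations, L labels)")
        if width is None:
            width = X.shape[1]
        elif X.shape[1] != width:
            raise ValueError("all sequences must share the feature width")
        out.append((X, y))
    if not out:
        raise ValueError("empty dataset")
    return out


class _PreparedCorpus:
    """Length-grouped, pre-stacked training data (built once per fit)."""

    def __init__(self, data: list[tuple[np.ndarray, np.ndarray]]):
        self.groups = []
        for L, idxs in _group_by_length(data).items():
            Xs = np.stack([data[i][0] for i in idxs])      # (B, L, D)
            ys = np.stack([data[i][1] for i in idxs])      # (B, L)
            B = len(idxs)
            b_idx = np.arange(B)[:, None]
            t_idx = np.arange(L)[None, :]
            onehot = np.zeros((B, L, N_STATES))
            onehot[b_idx, t_idx, ys] = 1.0
            emp_pair = np.zeros((N_STATES, N_STATES))
            if L > 1:
                np.add.at(emp_pair, (ys[:, :-1].ravel(), ys[:, 1:].ravel()),
                          1.0)
            self.groups.append((Xs, ys, onehot, emp_pair, b_idx, t_idx))

    def ll_grad(self, W: np.ndarray, T: np.ndarray, l2_sigma: float
                ) -> tuple[float, np.ndarray, np.ndarray]:
        ll = 0.0
        gW = np.zeros_like(W)
        gT = np.zeros_like(T)
        for Xs, ys, onehot, emp_pair, b_idx, t_idx in self.groups:
            L = ys.shape[1]
            nodes = Xs @ W
            log_z, marg, pair = _forward_backward_batch(nodes, T)
            emp_node = nodes[b_idx, t_idx, ys].sum()
            emp_edge = T[ys[:, :-1], ys[:, 1:]].sum() if L > 1 else 0.0
            ll += float(emp_node + emp_edge - log_z.sum())
            diff = onehot - marg
            D = Xs.shape[2]
            gW += Xs.reshape(-1, D).T @ diff.reshape(-1, N_STATES)
            if L > 1:
                gT += emp_pair - pair.sum(axis=(0, 1))
        sig2 = l2_sigma ** 2
        ll -= (np.sum(W ** 2) + np.sum(T ** 2)) / (2.0 * sig2)
        gW -= W / sig2
        gT -= T / sig2
        return ll, gW, gT


def log_likelihood_and_gradient(model: CRFModel, dataset
                                ) -> tuple[float, np.ndarray, np.ndarray]:
    """Penalized conditional log-likelihood and its exact gradient.

    Returns ``(ll, grad_unigram (D×2), grad_transition (2×2))`` where
    ``ll = Σ log P(y|X) − ||w||²/(2σ²)`` and the gradient is empirical
    minus expected feature counts minus ``w/σ²``.
    """
    prepared = _PreparedCorpus(_as_arrays(dataset))
    return prepared.ll_grad(model.unigram_weights, model.transition_weights,
                            model.l2_sigma)


def _pack(W: np.ndarray, T: np.ndarray) -> np.ndarray:
    return np.concatenate([W.ravel(), T.ravel()])


def _unpack(theta: np.ndarray, D: int) -> tuple[np.ndarray, np.ndarray]:
    W = theta[: D * N_STATES].reshape(D, N_STATES)
    T = theta[D * N_STATES:].reshape(N_STATES, N_STATES)
    return W, T


def train(dataset, cfg: TrainConfig | None = None,
          feature_names: Sequence[str] | None = None) -> CRFModel:
    """Fit the CRF by penalized maximum likelihood (L-BFGS-B on the exact
    gradient, zero initialization).  Deterministic for a fixed dataset
    order and config."""
    cfg = cfg or TrainConfig()
    data = _as_arrays(dataset)
    D = data[0][0].shape[1]
    classes = {int(v) for _, y in data for v in np.unique(y)}
    if len(classes) < 2:
        warnings.warn("dataset contains a single label class; the fitted "
                      "model will be degenerate")

    prepared = _PreparedCorpus(data)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        W, T = _unpack(theta, D)
        ll, gW, gT = prepared.ll_grad(W, T, cfg.l2_sigma)
        return -ll, -_pack(gW, gT)

    theta0 = np.zeros(D * N_STATES + N_STATES * N_STATES)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": cfg.max_iterations,
                            "gtol": cfg.gradient_tolerance,
                            "ftol": 1e-12})
    W, T = _unpack(res.x, D)
    return CRFModel(W, T, l2_sigma=cfg.l2_sigma,
                    feature_names=list(feature_names or []))


def predict(model: CRFModel, expanded: np.ndarray, threshold: float = 0.5,
            include_viterbi: bool = False) -> PredictionResult:
    """Posterior-marginal decoding: a residue is labelled turn when its
    posterior turn probability is >= `threshold` (the Viterbi path is
    available separately and does not honour the threshold)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    node, edge = sequence_log_potentials(model, expanded)
    _, marginals, _ = forward_backward(node, edge)
    prob = marginals[:, 1]
    labels = (prob >= threshold).astype(np.uint8)
    vit = viterbi(node, edge) if include_viterbi else None
    return PredictionResult(labels=labels, turn_probability=prob,
                            decision_threshold=threshold, viterbi_path=vit)


# ---------------------------------------------------------------------------
# Serialization (versioned JSON; exact float round-trip)

MODEL_FORMAT_VERSION = 1


def save_model(model: CRFModel, sink: TextIO | str) -> None:
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            save_model(model, fh)
            return
    payload = {
        "format": "turnkit-crf",
        "version": MODEL_FORMAT_VERSION,
        "states": list(model.states),
        "l2_sigma": model.l2_sigma,
        "feature_names": model.feature_names,
        "unigram_weights": [[w.hex() for w in row]
                            for row in model.unigram_weights.astype(float)],
        "transition_weights": [[w.hex() for w in row]
                               for row in model.transition_weights.astype(float)],
    }
    json.dump(payload, sink, indent=1)
    sink.write("\n")


def load_model(source: TextIO | str) -> CRFModel:
    if isinstance(source, str):
        with open(source) as fh:
            return load_model(fh)
    payload = json.load(source)
    if payload.get("format") != "turnkit-crf":
        raise ValueError("not a turnkit CRF model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    W = np.array([[float.fromhex(w) for w in row]
                  for row in payload["unigram_weights"]])
    T = np.array([[float.fromhex(w) for w in row]
                  for row in payload["transition_weights"]])
    return CRFModel(W, T, l2_sigma=payload["l2_sigma"],
                    feature_names=payload["feature_names"],
                    states=tuple(payload["states"]))
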