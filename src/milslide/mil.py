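"""Bag-level classifiers for multiple instance learning.

A slide is a *bag* of patch-feature *instances*; only the bag carries a
label. Four aggregation strategies are implemented, all emitting a bag
probability plus a per-instance score vector for heatmapping:

ABMIL
    Gated attention pooling: per-instance gate
    g_i = tanh(V h_i) (.) sigmoid(U h_i), attention a = softmax_i(w . g_i),
    bag embedding z = sum_i a_i h_i, probability sigmoid(c(z)). Instance
    scores are the attention weights (nonnegative, summing to 1).

DSMIL
    Dual stream: an instance scorer s_i picks the critical instance
    c = argmax_i s_i (ties -> lowest index); a second stream attends to it
    with U_i = softmax_i(q_i . q_c) over query projections and aggregates
    value projections, b = sum_i U_i v_i. The bag logit is the mean of the
    max instance score and the bag-classifier score on b. Instance scores
    are per-instance probabilities sigmoid(s_i).

TransMIL
    Transformer aggregation with a class token, "sequence squaring" (tokens
    padded to the next perfect square M = ceil(sqrt(N))^2 by re-appending the
    first M - N tokens) so the non-class tokens tile a sqrt(M) x sqrt(M)
    grid, and a pyramid positional-encoding stage (PPEG: identity plus
    depthwise convolutions of kernel 7/5/3 on that grid) between two
    self-attention blocks. Because PPEG mixes neighboring tokens, TransMIL —
    unlike the other heads — is *not* permutation invariant, which is how it
    encodes patch-neighborhood structure. Instance scores are the class
    token's attention over the original N tokens in the final block
    (head-mean, renormalized).

TL baseline
    A per-instance classifier trained on pseudo-labels copied from the bag
    label; bag probability is the mean of the instance probabilities.

All heads operate on raw logits internally and produce probabilities only at
the :class:`MILOutput` boundary. Exact softmax attention is the default; a
Nystrom approximation (segment-mean landmarks, iterative pseudo-inverse) is
available for very long bags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, NumericError, ParameterError, ShapeError

__all__ = [
    "Bag",
    "MILOutput",
    "ABMIL",
    "DSMIL",
    "TransMIL",
    "TLClassifier",
    "create_model",
    "abmil_forward",
    "dsmil_forward",
    "transmil_forward",
    "tl_forward",
    "squared_length",
    "save_checkpoint",
    "load_checkpoint",
    "MIL_METHODS",
]


@dataclass
class Bag:
    """A slide as a bag: instance features, their coordinates, one label."""

    slide_id: str
    H: np.ndarray                       # N x d
    coords: np.ndarray                  # N x 2, level-0 frame
    label: int | None = None

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2 or self.H.shape[0] < 1:
            raise ShapeError("bag features must be a non-empty N x d matrix")
        self.coords = np.asarray(self.coords).reshape(-1, 2)

    @property
    def n_instances(self) -> int:
        return self.H.shape[0]

    @property
    def d(self) -> int:
        return self.H.shape[1]


@dataclass
class MILOutput:
    """Bag probability plus per-instance scores (attention or probabilities)."""

    bag_prob: float
    instance_scores: np.ndarray
    method: str


def _check_dim(model_d: int, bag: Bag) -> None:
    if bag.d != model_d:
        raise ShapeError(f"bag dimension {bag.d} != model dimension {model_d}")


# ---------------------------------------------------------------------------
# ABMIL

class ABMIL(nn.Module):
    def __init__(self, d: int, hidden: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d, self.hidden = d, hidden
        self.hparams = {"hidden": hidden}
        scale_v = np.sqrt(6.0 / (d + hidden))
        self.V = nn.Tensor(rng.uniform(-scale_v, scale_v, (hidden, d)),
                           requires_grad=True)
        self.U = nn.Tensor(rng.uniform(-scale_v, scale_v, (hidden, d)),
                           requires_grad=True)
        self.w = nn.Tensor(rng.uniform(-scale_v, scale_v, hidden),
                           requires_grad=True)
        self.classifier = nn.Linear(d, 1, rng)

    def forward(self, H: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        Ht = nn.Tensor(H)
        gate = (Ht @ self.V.T).tanh() * (Ht @ self.U.T).sigmoid()   # N x L
        attn = nn.softmax(gate @ self.w, axis=-1)                   # N
        z = attn @ Ht                                               # d
        logit = self.classifier(z.reshape(1, -1)).reshape(())
        return logit, attn

    def loss(self, bag: Bag) -> nn.Tensor:
        logit, _ = self.forward(bag.H)
        return nn.binary_cross_entropy_with_logit(logit, bag.label)

    def predict(self, bag: Bag) -> MILOutput:
        _check_dim(self.d, bag)
        logit, attn = self.forward(bag.H)
        return MILOutput(bag_prob=_sigmoid(logit.item()),
                         instance_scores=attn.data.copy(), method="abmil")


# ---------------------------------------------------------------------------
# DSMIL

class DSMIL(nn.Module):
    def __init__(self, d: int, q: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d, self.q = d, q
        self.hparams = {"q": q}
        self.instance_scorer = nn.Linear(d, 1, rng)
        self.Wq = nn.Linear(d, q, rng)
        self.Wv = nn.Linear(d, d, rng)
        self.bag_classifier = nn.Linear(d, 1, rng)

    def forward(self, H: np.ndarray) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor, int]:
        Ht = nn.Tensor(H)
        s = self.instance_scorer(Ht).reshape(-1)                    # N
        crit = int(np.argmax(s.data))                               # ties -> lowest
        qs = self.Wq(Ht)                                            # N x q
        attn = nn.softmax(qs @ qs[crit], axis=-1)                   # N
        b = attn @ self.Wv(Ht)                                      # d
        bag_score = self.bag_classifier(b.reshape(1, -1)).reshape(())
        logit = (s.max() + bag_score) * 0.5
        return logit, s, attn, crit

    def loss(self, bag: Bag) -> nn.Tensor:
        logit, _, _, _ = self.forward(bag.H)
        return nn.binary_cross_entropy_with_logit(logit, bag.label)

    def predict(self, bag: Bag) -> MILOutput:
        _check_dim(self.d, bag)
        logit, s, attn, crit = self.forward(bag.H)
        out = MILOutput(bag_prob=_sigmoid(logit.item()),
                        instance_scores=_sigmoid(s.data.copy()), method="dsmil")
        out.critical_index = crit          # extra diagnostic, not in the core contract
        out.attention = attn.data.copy()
        return out


# ---------------------------------------------------------------------------
# TransMIL

def squared_length(n: int) -> int:
    """Token count after sequence squaring: the next perfect square >= n."""
    return int(np.ceil(np.sqrt(n))) ** 2


def _segment_means(X: np.ndarray, m: int) -> np.ndarray:
    """Means of m near-equal contiguous segments of the rows of X."""
    splits = np.array_split(np.arange(X.shape[0]), m)
    return np.stack([X[idx].mean(axis=0) for idx in splits])


def _iterative_pinv(A: np.ndarray, iters: int = 6) -> np.ndarray:
    """Newton-Schulz style pseudo-inverse of a softmax kernel matrix."""
    I = np.eye(A.shape[0])
    Z = A.T / (np.abs(A).sum(axis=0).max() * np.abs(A).sum(axis=1).max())
    for _ in range(iters):
        AZ = A @ Z
        Z = 0.25 * Z @ (13 * I - AZ @ (15 * I - AZ @ (7 * I - AZ)))
    return Z


def _softmax_np(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class _SelfAttention(nn.Module):
    """Pre-norm multi-head self-attention block with residual connection."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.dim, self.heads = dim, heads
        self.ln_g = nn.Tensor(np.ones(dim), requires_grad=True)
        self.ln_b = nn.Tensor(np.zeros(dim), requires_grad=True)
        # small normal init (transformer convention): attention starts close
        # to uniform and sharpens during training
        self.Wq = nn.Linear(dim, dim, rng, bias=False)
        self.Wk = nn.Linear(dim, dim, rng, bias=False)
        self.Wv = nn.Linear(dim, dim, rng, bias=False)
        self.Wo = nn.Linear(dim, dim, rng, bias=False)
        for lin in (self.Wq, self.Wk, self.Wv, self.Wo):
            lin.W.data = rng.normal(0.0, 0.02, lin.W.data.shape)

    def forward(self, x: nn.Tensor, mode: str = "exact", landmarks: int = 64
                ) -> tuple[nn.Tensor, np.ndarray]:
        """Returns (output tokens, class-token attention weights per head).

        `mode` 'exact' uses full softmax attention (differentiable);
        'nystrom' uses the landmark approximation (inference only — the
        approximate path does not carry gradients).
        """
        h = self.heads
        dh = self.dim // h
        xn = nn.layer_norm(x, self.ln_g, self.ln_b)
        Q, K, V = self.Wq(xn), self.Wk(xn), self.Wv(xn)
        outs, cls_rows = [], []
        for i in range(h):
            sl = slice(i * dh, (i + 1) * dh)
            Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
            if mode == "exact":
                scores = (Qh @ Kh.T) * (1.0 / np.sqrt(dh))
                attn = nn.softmax(scores, axis=-1)
                outs.append(attn @ Vh)
                cls_rows.append(attn.data[0])
            elif mode == "nystrom":
                n = Qh.shape[0]
                if landmarks > n:
                    raise ParameterError(
                        f"nystrom landmarks {landmarks} > sequence length {n}")
                q, k, v = Qh.data, Kh.data, Vh.data
                scale = 1.0 / np.sqrt(dh)
                qt = _segment_means(q, landmarks)
                kt = _segment_means(k, landmarks)
                F1 = _softmax_np(q @ kt.T * scale)
                A = _softmax_np(qt @ kt.T * scale)
                F2 = _softmax_np(qt @ k.T * scale)
                out = F1 @ (_iterative_pinv(A) @ (F2 @ v))
                outs.append(nn.Tensor(out))
                cls_rows.append((F1 @ _iterative_pinv(A) @ F2)[0])
            else:
                raise ConfigurationError(f"unknown attention mode {mode!r}")
        merged = self.Wo(nn.concat(outs, axis=1))
        return x + merged, np.stack(cls_rows)


class _PPEG(nn.Module):
    """Pyramid positional encoding: identity + depthwise conv 7/5/3 on the grid."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.kernels = [
            nn.Tensor(rng.normal(0.0, 1.0 / k, (dim, k, k)), requires_grad=True)
            for k in (7, 5, 3)
        ]

    def forward(self, tokens: nn.Tensor) -> nn.Tensor:
        """tokens: (M, dim) with M a perfect square; returns (M, dim)."""
        M = tokens.shape[0]
        side = int(np.sqrt(M))
        grid = tokens.T.reshape(self.dim, side, side)
        out = grid
        for w in self.kernels:
            out = out + nn.depthwise_conv2d(grid, w)
        return out.reshape(self.dim, M).T


class TransMIL(nn.Module):
    def __init__(self, d: int, token_dim: int = 256, heads: int = 4,
                 seed: int = 0, attention_mode: str = "auto",
                 landmarks: int = 64, exact_max_len: int = 4096):
        if token_dim % heads:
            raise ConfigurationError("token_dim must be divisible by heads")
        rng = np.random.default_rng(seed)
        self.d, self.token_dim = d, token_dim
        self.hparams = {"token_dim": token_dim, "heads": heads,
                        "attention_mode": attention_mode,
                        "landmarks": landmarks, "exact_max_len": exact_max_len}
        self.attention_mode = attention_mode
        self.landmarks = landmarks
        self.exact_max_len = exact_max_len
        self.proj = nn.Linear(d, token_dim, rng)
        self.class_token = nn.Tensor(rng.normal(0, 0.02, (1, token_dim)),
                                     requires_grad=True)
        self.block1 = _SelfAttention(token_dim, heads, rng)
        self.ppeg = _PPEG(token_dim, rng)
        self.block2 = _SelfAttention(token_dim, heads, rng)
        self.ln_g = nn.Tensor(np.ones(token_dim), requires_grad=True)
        self.ln_b = nn.Tensor(np.zeros(token_dim), requires_grad=True)
        self.head = nn.Linear(token_dim, 1, rng)

    def _mode_for(self, seq_len: int, override: str | None) -> str:
        mode = override or self.attention_mode
        if mode == "auto":
            return "exact" if seq_len <= self.exact_max_len else "nystrom"
        return mode

    def forward(self, H: np.ndarray, attention_mode: str | None = None
                ) -> tuple[nn.Tensor, np.ndarray]:
        N = H.shape[0]
        tokens = self.proj(nn.Tensor(H)).relu()                     # N x C
        M = squared_length(N)
        if M > N:   # re-append the first M - N tokens
            tokens = nn.concat([tokens, tokens[:M - N]], axis=0)
        x = nn.concat([self.class_token, tokens], axis=0)           # (M+1) x C
        mode = self._mode_for(M + 1, attention_mode)
        x, _ = self.block1.forward(x, mode=mode, landmarks=self.landmarks)
        grid = self.ppeg.forward(x[1:])
        x = nn.concat([x[:1], grid], axis=0)
        x, cls_attn = self.block2.forward(x, mode=mode, landmarks=self.landmarks)
        x = nn.layer_norm(x, self.ln_g, self.ln_b)
        logit = self.head(x[:1]).reshape(())
        # class-token attention over the original N tokens, head-averaged
        scores = cls_attn.mean(axis=0)[1:N + 1]
        total = scores.sum()
        scores = scores / total if total > 0 else np.full(N, 1.0 / N)
        return logit, scores

    def loss(self, bag: Bag) -> nn.Tensor:
        logit, _ = self.forward(bag.H)
        return nn.binary_cross_entropy_with_logit(logit, bag.label)

    def predict(self, bag: Bag, attention_mode: str | None = None) -> MILOutput:
        _check_dim(self.d, bag)
        logit, scores = self.forward(bag.H, attention_mode=attention_mode)
        return MILOutput(bag_prob=_sigmoid(logit.item()),
                         instance_scores=scores, method="transmil")


# ---------------------------------------------------------------------------
# TL baseline

class TLClassifier(nn.Module):
    """Patch-level classifier trained on pseudo-labels copied from the bag."""

    def __init__(self, d: int, hidden: int = 0, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d = d
        self.hidden = hidden
        self.hparams = {"hidden": hidden}
        if hidden > 0:
            self.fc1 = nn.Linear(d, hidden, rng)
            self.fc2 = nn.Linear(hidden, 1, rng)
        else:                              # linear patch classifier
            self.fc = nn.Linear(d, 1, rng)

    def instance_logits(self, H: np.ndarray) -> nn.Tensor:
        t = nn.Tensor(H)
        if self.hidden > 0:
            return self.fc2(self.fc1(t).relu()).reshape(-1)
        return self.fc(t).reshape(-1)

    def loss(self, bag: Bag) -> nn.Tensor:
        # transfer-learning paradigm: every instance inherits the bag label
        logits = self.instance_logits(bag.H)
        y = float(bag.label)
        return (logits.softplus() - logits * y).mean()

    def predict(self, bag: Bag) -> MILOutput:
        _check_dim(self.d, bag)
        p = _sigmoid(self.instance_logits(bag.H).data)
        return MILOutput(bag_prob=float(p.mean()), instance_scores=p,
                         method="tl")


# ---------------------------------------------------------------------------
# functional wrappers and registry

def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def abmil_forward(model: ABMIL, bag: Bag) -> MILOutput:
    return model.predict(bag)


def dsmil_forward(model: DSMIL, bag: Bag) -> MILOutput:
    return model.predict(bag)


def transmil_forward(model: TransMIL, bag: Bag,
                     attention_mode: str | None = None) -> MILOutput:
    return model.predict(bag, attention_mode=attention_mode)


def tl_forward(model: TLClassifier, bag: Bag) -> MILOutput:
    return model.predict(bag)


MIL_METHODS = ("abmil", "dsmil", "transmil", "tl")

_FACTORIES = {
    "abmil": ABMIL,
    "dsmil": DSMIL,
    "transmil": TransMIL,
    "tl": TLClassifier,
}


def create_model(method: str, d: int, seed: int = 0, **kwargs):
    if method not in _FACTORIES:
        raise ConfigurationError(
            f"unknown MIL method {method!r}; available: {sorted(_FACTORIES)}")
    return _FACTORIES[method](d=d, seed=seed, **kwargs)


def save_checkpoint(model, path, method: str, seed: int = 0, **meta) -> None:
    """Single-file archive: parameter arrays + a JSON header."""
    header = nn.params_header(method, d=model.d, seed=seed,
                              hparams=getattr(model, "hparams", {}), **meta)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Rebuild the model named in the checkpoint header and load its arrays."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        n = len([k for k in z.files if k.startswith("p")])
        arrays = [z[f"p{i}"] for i in range(n)]
    if any(not np.all(np.isfinite(a)) for a in arrays):
        raise NumericError("checkpoint contains non-finite parameters")
    model = create_model(header["method"], d=header["d"],
                         seed=header.get("seed", 0), **header.get("hparams", {}))
    model.load_state_arrays(arrays)
    return model, header
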