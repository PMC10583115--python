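"""Patch-feature encoders and self-supervised pre-training losses.

MIL training is dominated by feature extraction, so features are computed
once per slide and persisted next to the patch grid in the per-slide HDF5
store (`/features`). Every FeatureBag records an `encoder_fingerprint` — a
hash of the encoder spec plus a checksum of its weights — so bags produced by
different encoders can never be silently mixed in one cohort.

Two encoder families are registered:

``tiny``
    A small, deterministic, randomly initialized convolutional network
    (block-mean downsample to 32 x 32, two 3 x 3 conv + ReLU + pool stages,
    global average pooling, linear map to `embed_dim`). Inference-only; its
    weights are a pure function of the spec seed.
``mlp``
    A trainable two-layer perceptron over flattened patches, used as the
    backbone for self-supervised pre-training.

Additional backbones plug in through :func:`register_encoder`.

The SSL losses follow the two canonical contrastive formulations: the
SimCLR NT-Xent loss over augmentation pairs, and the MoCo momentum-encoder /
negatives-queue InfoNCE objective. Augmentations are restricted to flips,
90-degree rotations and color jitter — croppings aggressive enough to cut a
patch's tissue context are deliberately excluded, since a 224 px tile is
already a small crop of the slide.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import h5py
import numpy as np

from . import nn
from .errors import ConfigurationError, FormatError, NumericError, ParameterError
from .preprocess import PatchGrid
from .slide_io import RegionRequest, SlideHandle, block_mean_downsample, read_region

__all__ = [
    "EncoderSpec",
    "FeatureBag",
    "TinyConvEncoder",
    "MLPEncoder",
    "register_encoder",
    "build_encoder",
    "encode_bag",
    "load_features",
    "nt_xent_loss",
    "MoCoState",
    "init_moco",
    "moco_step",
    "augment_patch",
    "train_simclr",
]


@dataclass(frozen=True)
class EncoderSpec:
    """What encoder to build and how it was initialized."""

    name: str = "tiny"
    embed_dim: int = 32
    weights: str = "random"            # "random" | "file:<path>"
    input_size: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim < 1:
            raise ParameterError("embed_dim must be >= 1")


@dataclass
class FeatureBag:
    """Per-slide instance embeddings aligned with their patch coordinates."""

    slide_id: str
    features: np.ndarray               # N x d float32
    coords: np.ndarray                 # N x 2 int64, level-0 frame
    encoder_fingerprint: str

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        bad = ~np.isfinite(self.features)
        if bad.any():
            idx = int(np.argwhere(bad.any(axis=1))[0, 0])
            raise NumericError(f"non-finite embedding at patch index {idx}")
        if self.features.shape[0] != self.coords.shape[0]:
            raise NumericError("features and coords row counts differ")

    @property
    def d(self) -> int:
        return self.features.shape[1]


# ---------------------------------------------------------------------------
# encoders

# fixed input normalization applied before every encoder
_NORM_MEAN, _NORM_STD = 0.5, 0.25


def _prep(patches: np.ndarray) -> np.ndarray:
    x = np.asarray(patches, dtype=np.float64) / 255.0
    return (x - _NORM_MEAN) / _NORM_STD


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x: (N, H, W, Cin); w: (k, k, Cin, Cout); 'same' zero padding."""
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    N, H, W, _ = x.shape
    out = np.zeros((N, H, W, w.shape[3]))
    for i in range(k):
        for j in range(k):
            out += xp[:, i:i + H, j:j + W, :] @ w[i, j]
    return out + b


class TinyConvEncoder:
    """Deterministic random-weight conv net producing d-dim patch embeddings."""

    def __init__(self, spec: EncoderSpec):
        if spec.input_size % 32:
            raise ConfigurationError(
                f"tiny encoder needs input_size divisible by 32, got {spec.input_size}")
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        d = spec.embed_dim
        self.w1 = rng.normal(0, 0.2, (3, 3, 3, 8))
        self.b1 = np.zeros(8)
        self.w2 = rng.normal(0, 0.2, (3, 3, 8, 16))
        self.b2 = np.zeros(16)
        self.w3 = rng.normal(0, 0.3, (16, d))
        self.b3 = np.zeros(d)
        if spec.weights.startswith("file:"):
            with np.load(spec.weights[5:]) as z:
                for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
                    setattr(self, name, z[name])

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        """patches: (N, s, s, 3) uint8 with s == spec.input_size -> (N, d)."""
        if patches.shape[1] != self.spec.input_size:
            raise ConfigurationError(
                f"encoder expects {self.spec.input_size} px patches, "
                f"got {patches.shape[1]}")
        factor = self.spec.input_size // 32
        small = np.stack([block_mean_downsample(p, factor) for p in patches])
        x = _prep(small)                                     # N x 32 x 32 x 3
        x = np.maximum(_conv2d(x, self.w1, self.b1), 0.0)
        x = x.reshape(-1, 16, 2, 16, 2, 8).mean(axis=(2, 4))  # avg pool 2x2
        x = np.maximum(_conv2d(x, self.w2, self.b2), 0.0)
        x = x.mean(axis=(1, 2))                              # global avg pool
        return (x @ self.w3 + self.b3).astype(np.float64)

    def weight_checksum(self) -> str:
        h = hashlib.sha1()
        for a in (self.w1, self.b1, self.w2, self.b2, self.w3, self.b3):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


class MLPEncoder(nn.Module):
    """Trainable flatten -> hidden -> d perceptron (the SSL backbone)."""

    def __init__(self, spec: EncoderSpec, in_features: int, hidden: int = 64):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.in_features = in_features
        self.fc1 = nn.Linear(in_features, hidden, rng)
        self.fc2 = nn.Linear(hidden, spec.embed_dim, rng)

    def forward(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        t = x if isinstance(x, nn.Tensor) else nn.Tensor(
            _prep(x).reshape(len(x), -1))
        return self.fc2(self.fc1(t).relu())

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return self.forward(patches).data

    def forward_numpy(self, arrays: list[np.ndarray], x: np.ndarray) -> np.ndarray:
        """Forward pass with externally supplied parameters (momentum encoder)."""
        flat = _prep(x).reshape(len(x), -1)
        W1, b1, W2, b2 = arrays
        h = np.maximum(flat @ W1.T + b1, 0.0)
        return h @ W2.T + b2

    def weight_checksum(self) -> str:
        h = hashlib.sha1()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


_ENCODERS = {}


def register_encoder(name: str, factory) -> None:
    """Register an encoder factory: factory(spec) -> callable(patches)->(N,d)."""
    _ENCODERS[name] = factory


register_encoder("tiny", TinyConvEncoder)


def build_encoder(spec: EncoderSpec):
    if spec.name not in _ENCODERS:
        raise ConfigurationError(
            f"unknown encoder {spec.name!r}; registered: {sorted(_ENCODERS)}. "
            "Production backbones (e.g. a ResNet) can be plugged in through "
            "register_encoder().")
    return _ENCODERS[spec.name](spec)


def encoder_fingerprint(spec: EncoderSpec, encoder) -> str:
    h = hashlib.sha1()
    h.update(f"{spec.name}|{spec.embed_dim}|{spec.input_size}|".encode())
    if hasattr(encoder, "weight_checksum"):
        h.update(encoder.weight_checksum().encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# feature bags

def encode_bag(handle: SlideHandle, grid: PatchGrid,
               spec: EncoderSpec = EncoderSpec(), store=None,
               batch_size: int = 64) -> FeatureBag:
    """Encode every retained patch of a grid into one embedding row.

    Deterministic given the encoder weights and the slide pixels. When
    `store` is given, features are persisted under `/features` in the
    per-slide HDF5 store.
    """
    if len(grid) == 0:
        raise ParameterError("cannot encode an empty patch grid")
    pw, ph = grid.patch_size
    if spec.input_size != pw:
        raise ConfigurationError(
            f"encoder input_size {spec.input_size} != patch width {pw}")
    enc = build_encoder(spec)
    feats = []
    for start in range(0, len(grid), batch_size):
        chunk = grid.coords[start:start + batch_size]
        patches = np.stack([
            read_region(handle, RegionRequest(level=grid.patch_level,
                                              origin=(int(x), int(y)),
                                              size=(pw, ph)))
            for x, y in chunk])
        feats.append(enc(patches))
    features = np.concatenate(feats, axis=0).astype(np.float32)
    bag = FeatureBag(slide_id=grid.slide_id, features=features,
                     coords=grid.coords.copy(),
                     encoder_fingerprint=encoder_fingerprint(spec, enc))
    if store is not None:
        save_features(bag, store)
    return bag


def save_features(bag: FeatureBag, store) -> None:
    with h5py.File(store, "a") as f:
        f.attrs.setdefault("schema_version", 1)
        if "features" in f:
            del f["features"]
        g = f.create_group("features")
        g.create_dataset("features", data=bag.features, dtype=np.float32)
        g.create_dataset("coords", data=bag.coords, dtype=np.int64)
        g.attrs["encoder_fingerprint"] = bag.encoder_fingerprint
        g.attrs["d"] = bag.d
        g.attrs["slide_id"] = bag.slide_id


def load_features(store) -> FeatureBag:
    with h5py.File(store, "r") as f:
        if "features" not in f:
            raise FormatError("store is missing the 'features' group")
        g = f["features"]
        return FeatureBag(slide_id=str(g.attrs["slide_id"]),
                          features=g["features"][()],
                          coords=g["coords"][()],
                          encoder_fingerprint=str(g.attrs["encoder_fingerprint"]))


# ---------------------------------------------------------------------------
# SimCLR NT-Xent

def nt_xent_loss(z, tau: float = 0.5) -> nn.Tensor:
    """Normalized-temperature cross entropy over cosine similarities.

    `z` holds 2N embeddings where rows (2k, 2k+1) are the two augmented views
    of sample k. Rows are L2-normalized internally. For each anchor the
    positive is its partner; the other 2N - 2 rows are negatives; the loss is
    averaged over all 2N anchors.
    """
    zt = z if isinstance(z, nn.Tensor) else nn.Tensor(z)
    two_n = zt.shape[0]
    if two_n < 4 or two_n % 2:
        raise ParameterError(
            "nt_xent_loss needs at least 2 pairs (an even row count >= 4)")
    if tau <= 0:
        raise ParameterError("temperature must be positive")
    norm = (zt * zt).sum(axis=1, keepdims=True) ** 0.5
    zn = zt / norm
    sims = (zn @ zn.T) * (1.0 / tau)
    # exclude self-similarity from every softmax
    sims = sims + nn.Tensor(np.diag(np.full(two_n, -1e9)))
    pos = np.arange(two_n) ^ 1                      # partner of each anchor
    shift = nn.Tensor(sims.data.max(axis=1, keepdims=True))
    lse = ((sims - shift).exp().sum(axis=1)).log() + shift.reshape(-1)
    pos_sim = sims[np.arange(two_n), pos]
    return (lse - pos_sim).mean()


# ---------------------------------------------------------------------------
# MoCo

@dataclass
class MoCoState:
    """Momentum-contrast state: query/key encoders, FIFO queue of negatives."""

    query_encoder: MLPEncoder
    key_arrays: list[np.ndarray]
    queue: np.ndarray                  # K x d, unit rows
    momentum: float = 0.999
    tau: float = 0.07
    ptr: int = 0


def init_moco(encoder: MLPEncoder, queue_size: int = 4096,
              momentum: float = 0.999, tau: float = 0.07,
              seed: int = 0) -> MoCoState:
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((queue_size, encoder.spec.embed_dim))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return MoCoState(query_encoder=encoder,
                     key_arrays=[p.data.copy() for p in encoder.parameters()],
                     queue=q, momentum=momentum, tau=tau)


def _l2n(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def moco_step(state: MoCoState, query_batch: np.ndarray,
              key_batch: np.ndarray) -> nn.Tensor:
    """One MoCo update; returns the InfoNCE loss (query side differentiable).

    Order of operations: the key encoder receives its momentum update
    (key <- m * key + (1 - m) * query) *before* encoding the key batch; new
    keys are enqueued FIFO so the queue size never changes. The caller
    backpropagates the returned loss and steps the query encoder.
    """
    m = state.momentum
    if not (0.0 <= m <= 1.0):
        raise ParameterError(f"momentum must lie in [0, 1], got {m}")
    B = len(query_batch)
    K = state.queue.shape[0]
    if B > K:
        raise ParameterError("batch size exceeds queue size")

    q_params = state.query_encoder.parameters()
    state.key_arrays = [m * k + (1.0 - m) * p.data
                        for k, p in zip(state.key_arrays, q_params)]

    q = state.query_encoder.forward(query_batch)             # B x d, grad
    qn = q / ((q * q).sum(axis=1, keepdims=True) ** 0.5)
    keys = _l2n(state.query_encoder.forward_numpy(state.key_arrays, key_batch))

    l_pos = (qn * nn.Tensor(keys)).sum(axis=1)               # B
    l_neg = qn @ nn.Tensor(state.queue.T)                    # B x K
    logits = nn.concat([l_pos.reshape(-1, 1), l_neg], axis=1) * (1.0 / state.tau)
    shift = nn.Tensor(logits.data.max(axis=1, keepdims=True))
    lse = ((logits - shift).exp().sum(axis=1)).log() + shift.reshape(-1)
    loss = (lse - logits[:, 0]).mean()                       # positive at col 0

    idx = (state.ptr + np.arange(B)) % K
    state.queue[idx] = keys
    state.ptr = int((state.ptr + B) % K)
    return loss


# ---------------------------------------------------------------------------
# augmentations and the SimCLR loop

def augment_patch(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flips, 90-degree rotations and color jitter; no aggressive cropping."""
    out = img.astype(np.float64)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    out = np.rot90(out, k=int(rng.integers(0, 4)))
    # color jitter: global brightness plus independent channel gains
    out = out + rng.uniform(-40, 40)
    out = out * (1.0 + rng.uniform(-0.15, 0.15, 3))
    return np.clip(out, 0, 255).astype(np.uint8)


def train_simclr(patches: np.ndarray, encoder: MLPEncoder, epochs: int = 5,
                 batch_pairs: int = 32, lr: float = 1e-2, tau: float = 0.5,
                 seed: int = 0) -> list[float]:
    """SimCLR pre-training of a trainable encoder on raw patches.

    Each step draws a batch of patches, produces two augmented views per
    patch, and minimizes the NT-Xent loss. Returns the per-epoch mean loss.
    """
    rng = np.random.default_rng(seed)
    opt = nn.Adam(encoder.parameters(), lr=lr)
    n = len(patches)
    history = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - batch_pairs + 1, batch_pairs):
            idx = order[start:start + batch_pairs]
            views = []
            for i in idx:
                views.append(augment_patch(patches[i], rng))
                views.append(augment_patch(patches[i], rng))
            z = encoder.forward(np.stack(views))
            loss = nt_xent_loss(z, tau=tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history
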