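"""Distance- and distance+angle-aware message-passing classifiers.

Two architectures over :class:`~pocketec.graph_build.ProteinGraph` inputs:

``distances``
    Continuous-filter convolutions: each interaction block modulates
    neighbor features with a filter generated from a Gaussian radial basis
    expansion of the interatomic distance, x_i' = Σ_j x_j ∘ W(d_ij).

``distances_angles``
    Directional message passing: per-edge messages m_ji are updated from
    incoming messages m_kj modulated by a radial basis of d_ji and a
    spherical Fourier–Bessel basis of (d_kj, α_(kj,ji)), combined by Hadamard
    products with small MLPs on the basis representations; every embedding and
    interaction block feeds an output block and the block outputs are summed
    into the prediction.

Both are invariant to global rotations and translations by construction
(geometry enters only through distances and angles) and to node permutation
(sum pooling).  Geometry featurization is plain NumPy; learnable paths run on
the :mod:`pocketec.autodiff` tape.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import eval_legendre, spherical_jn

from .autodiff import Tensor, concat, constant, dropout, gather, matmul, parameter, segment_sum, ssp
from .eclabel import ECLabel
from .graph_build import GraphBatch, ProteinGraph

__all__ = [
    "RBFConfig",
    "SBFConfig",
    "ModelConfig",
    "rbf_expand",
    "sbf_expand",
    "cfconv",
    "atomwise",
    "dimenet_message_update",
    "Model",
    "build_model",
    "predict_ec",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Basis expansions


@dataclasses.dataclass(frozen=True)
class RBFConfig:
    """Gaussian radial basis: component k is exp(−γ (d − μ_k)²)."""

    centers: np.ndarray           # strictly increasing, Å
    gamma: float = 10.0           # Å⁻²

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=np.float64)
        if centers.ndim != 1 or np.any(np.diff(centers) <= 0):
            raise ValueError("RBF centers must be strictly increasing")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        object.__setattr__(self, "centers", centers)

    @property
    def count(self) -> int:
        return len(self.centers)

    @classmethod
    def uniform(cls, count: int = 50, cutoff: float = 15.0, gamma: float = 10.0) -> "RBFConfig":
        """``count`` centers evenly spaced on [0, cutoff] (the default mode)."""
        return cls(centers=np.linspace(0.0, cutoff, count), gamma=gamma)

    @classmethod
    def grid(cls, spacing: float = 0.1, maximum: float = 30.0, gamma: float = 10.0) -> "RBFConfig":
        """Dense fixed grid 0..maximum Å every ``spacing`` Å (301 centers by default)."""
        n = int(round(maximum / spacing)) + 1
        return cls(centers=np.linspace(0.0, maximum, n), gamma=gamma)


def rbf_expand(d, cfg: RBFConfig) -> np.ndarray:
    """Expand distances (scalar or array) into Gaussian basis values."""
    d = np.asarray(d, dtype=np.float64)
    diff = d[..., None] - cfg.centers
    return np.exp(-cfg.gamma * diff * diff)


@dataclasses.dataclass(frozen=True)
class SBFConfig:
    """Spherical Fourier–Bessel basis over (distance, angle) pairs."""

    num_spherical: int = 7
    num_radial: int = 6
    cutoff: float = 15.0

    def __post_init__(self):
        if self.num_spherical < 1 or self.num_radial < 1:
            raise ValueError("num_spherical and num_radial must be >= 1")

    @property
    def count(self) -> int:
        return self.num_spherical * self.num_radial


_BESSEL_ZERO_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _spherical_bessel_zeros(l: int, n_zeros: int) -> np.ndarray:
    """First ``n_zeros`` positive roots of the spherical Bessel function j_l."""
    key = (l, n_zeros)
    if key in _BESSEL_ZERO_CACHE:
        return _BESSEL_ZERO_CACHE[key]
    if l == 0:
        zeros = np.arange(1, n_zeros + 1) * np.pi
    else:
        f = lambda x: spherical_jn(l, x)
        zeros_list: list[float] = []
        x, step = max(l, 1) * 1.0, 0.1
        prev = f(x)
        while len(zeros_list) < n_zeros:
            x += step
            cur = f(x)
            if prev == 0.0:
                zeros_list.append(x - step)
            elif prev * cur < 0:
                zeros_list.append(brentq(f, x - step, x))
            prev = cur
        zeros = np.array(zeros_list[:n_zeros])
    _BESSEL_ZERO_CACHE[key] = zeros
    return zeros


def sbf_expand(d, alpha, cfg: SBFConfig) -> np.ndarray:
    """2D basis j_l(z_{ln} d / cutoff) · P_l(cos α), flattened to (…, L·N)."""
    d = np.asarray(d, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    cos_a = np.cos(alpha)
    scaled = np.clip(d / cfg.cutoff, 0.0, 1.0)
    cols = []
    for l in range(cfg.num_spherical):
        zeros = _spherical_bessel_zeros(l, cfg.num_radial)
        ang = eval_legendre(l, cos_a) * np.sqrt((2 * l + 1) / (4 * np.pi))
        for z in zeros:
            cols.append(spherical_jn(l, z * scaled) * ang)
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# Model configuration


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of either architecture.

    Defaults are the full-scale settings (128-dimensional embeddings, six
    interaction blocks for ``distances``, four building blocks for
    ``distances_angles``); tests and the synthetic benchmark use smaller
    instances through these same fields.
    """

    architecture: str                  # "distances" | "distances_angles"
    n_classes: int
    n_node_types: int
    embedding_dim: int = 128
    hidden_dim: int = 128
    n_filters: int = 128
    n_interactions: int = 6            # distances architecture
    n_blocks: int = 4                  # distances_angles: embedding + interaction blocks
    basis_embedding: int = 8
    interaction_embedding: int = 64
    output_embedding: int = 256
    max_neighbors: int = 32
    dropout: float = 0.25
    pooling: str = "sum"               # "sum" | "mean"
    n_rbf: int = 50
    rbf_gamma: float = 10.0
    cutoff: float = 15.0               # basis support, Å; match the graph radius
    num_spherical: int = 7
    num_radial: int = 6

    def __post_init__(self):
        if self.architecture not in ("distances", "distances_angles"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.pooling not in ("sum", "mean"):
            raise ValueError("pooling must be sum|mean")
        if min(self.n_classes, self.n_node_types, self.embedding_dim, self.hidden_dim) < 1:
            raise ValueError("all dimensions must be >= 1")

    def rbf(self) -> RBFConfig:
        return RBFConfig.uniform(self.n_rbf, self.cutoff, self.rbf_gamma)

    def sbf(self) -> SBFConfig:
        return SBFConfig(self.num_spherical, self.num_radial, self.cutoff)


# ---------------------------------------------------------------------------
# Primitive layers (spec surface, reused by the models)


def atomwise(x: Tensor, W: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Per-node dense layer with shared weights: x_i ← W x_i + b."""
    out = matmul(x, W)
    return out + b if b is not None else out


def cfconv(node_feats: Tensor, edge_filters: Tensor, edge_index: np.ndarray, n_nodes: int) -> Tensor:
    """Continuous-filter convolution x_i' = Σ_{j→i} x_j ∘ W(d_ij).

    ``edge_filters`` is the filter network's output, one F-vector per edge;
    rotational invariance holds because filters depend on positions only
    through d_ij.  Nodes without in-edges get a zero row (empty sum).
    """
    j, i = edge_index
    messages = gather(node_feats, j) * edge_filters
    return segment_sum(messages, i, n_nodes)


def dimenet_message_update(
    messages: Tensor,
    rbf_feat: np.ndarray,
    sbf_feat: np.ndarray,
    trip_kj: np.ndarray,
    trip_ji: np.ndarray,
    params: dict,
) -> Tensor:
    """One directional message-passing update m_ji ← f_update(m_ji, Σ_k …).

    The directional sum runs over triplets (k→j, j→i): incoming messages are
    modulated by the radial basis of their own edge (Hadamard product with an
    MLP-transformed basis) and by the spherical basis of the (distance, angle)
    pair, down-projected, aggregated per receiving edge, and up-projected.
    Edges with no triplets receive only the self/RBF path (empty sum).
    """
    n_edges = messages.shape[0]
    rbf_t = constant(rbf_feat)
    sbf_t = constant(sbf_feat)
    x_ji = ssp(atomwise(messages, params["W_src"], params["b_src"]))
    rbf_emb = matmul(matmul(rbf_t, params["W_rb1"]), params["W_rb2"])
    x_kj = ssp(atomwise(messages, params["W_kj"], params["b_kj"])) * rbf_emb
    x_kj = ssp(matmul(x_kj, params["W_down"]))
    sbf_emb = matmul(matmul(sbf_t, params["W_sb1"]), params["W_sb2"])
    t = gather(x_kj, trip_kj) * sbf_emb
    agg = segment_sum(t, trip_ji, n_edges)
    agg = ssp(matmul(agg, params["W_up"]))
    m_new = x_ji + agg
    m_new = m_new + ssp(atomwise(m_new, params["W_res"], params["b_res"]))
    return m_new


# ---------------------------------------------------------------------------
# Parameter initialisation helpers


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


def _zeros(n: int) -> Tensor:
    return parameter(np.zeros(n))


# ---------------------------------------------------------------------------
# Featurization (NumPy constants shared by both architectures)


def _batch_triplets(edge_index: np.ndarray, positions: np.ndarray):
    """Triplets (k→j, j→i), k ≠ i, over a (possibly batched) edge list."""
    j_arr, i_arr = edge_index
    n_edges = edge_index.shape[1]
    incoming: dict[int, list[int]] = {}
    for e in range(n_edges):
        incoming.setdefault(int(i_arr[e]), []).append(e)
    kj_ids, ji_ids = [], []
    for e in range(n_edges):
        j, i = int(j_arr[e]), int(i_arr[e])
        for f in incoming.get(j, ()):
            if int(j_arr[f]) == i:
                continue
            kj_ids.append(f)
            ji_ids.append(e)
    kj = np.array(kj_ids, dtype=np.intp)
    ji = np.array(ji_ids, dtype=np.intp)
    if len(kj) == 0:
        return kj, ji, np.zeros(0)
    jj = j_arr[ji]
    v1 = positions[j_arr[kj]] - positions[jj]
    v2 = positions[i_arr[ji]] - positions[jj]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    cosang = np.clip((v1 * v2).sum(axis=1) / np.maximum(n1 * n2, 1e-300), -1.0, 1.0)
    return kj, ji, np.arccos(cosang)


def featurize(batch: GraphBatch, cfg: ModelConfig) -> dict:
    """Precompute geometry features (all plain NumPy, treated as constants)."""
    j, i = batch.edge_index
    d = np.linalg.norm(batch.positions[i] - batch.positions[j], axis=1)
    feats = {
        "edge_index": batch.edge_index,
        "node_types": batch.node_types,
        "node2graph": batch.node2graph,
        "n_nodes": batch.n_nodes,
        "n_graphs": batch.n_graphs,
        "rbf": rbf_expand(d, cfg.rbf()),
    }
    if cfg.architecture == "distances_angles":
        kj, ji, alpha = _batch_triplets(batch.edge_index, batch.positions)
        feats["trip_kj"] = kj
        feats["trip_ji"] = ji
        feats["sbf"] = (
            sbf_expand(d[kj], alpha, cfg.sbf()) if len(kj) else np.zeros((0, cfg.sbf().count))
        )
    return feats


# ---------------------------------------------------------------------------
# Models


class Model:
    """Base: a parameter dict plus a forward pass producing per-graph logits."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.params: dict[str, Tensor] = {}

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def forward(self, feats: dict, training: bool = False,
                rng: Optional[np.random.Generator] = None,
                node_mask: Optional[Tensor] = None) -> Tensor:
        raise NotImplementedError

    def logits(self, graphs: Sequence[ProteinGraph] | GraphBatch) -> np.ndarray:
        """Eval-mode logits as a (n_graphs, C) array."""
        batch = graphs if isinstance(graphs, GraphBatch) else GraphBatch.from_graphs(list(graphs))
        return self.forward(featurize(batch, self.cfg), training=False).data

    def _embed(self, feats: dict, node_mask: Optional[Tensor]) -> Tensor:
        x = gather(self.params["type_embedding"], feats["node_types"])
        if node_mask is not None:
            x = x * node_mask
        return x

    def _pool(self, node_out: Tensor, feats: dict) -> Tensor:
        pooled = segment_sum(node_out, feats["node2graph"], feats["n_graphs"])
        if self.cfg.pooling == "mean":
            counts = np.bincount(feats["node2graph"], minlength=feats["n_graphs"]).astype(float)
            pooled = pooled * constant(1.0 / np.maximum(counts, 1.0)[:, None])
        return pooled


class DistanceNet(Model):
    """Continuous-filter convolution classifier (distances architecture)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        F, K, C = cfg.embedding_dim, cfg.n_rbf, cfg.n_classes
        nf = cfg.n_filters
        p = self.params
        p["type_embedding"] = parameter(rng.normal(0.0, 1.0, size=(cfg.n_node_types, F)))
        for l in range(cfg.n_interactions):
            p[f"b{l}.W_in"] = _glorot(rng, F, nf)
            p[f"b{l}.W_f1"] = _glorot(rng, K, nf)
            p[f"b{l}.b_f1"] = _zeros(nf)
            p[f"b{l}.W_f2"] = _glorot(rng, nf, nf)
            p[f"b{l}.b_f2"] = _zeros(nf)
            p[f"b{l}.W_o1"] = _glorot(rng, nf, F)
            p[f"b{l}.b_o1"] = _zeros(F)
            p[f"b{l}.W_o2"] = _glorot(rng, F, F)
            p[f"b{l}.b_o2"] = _zeros(F)
        p["W_r1"] = _glorot(rng, F, F)
        p["b_r1"] = _zeros(F)
        p["W_r2"] = _glorot(rng, F, C)
        p["b_r2"] = _zeros(C)

    def forward(self, feats, training=False, rng=None, node_mask=None):
        p = self.params
        rbf = constant(feats["rbf"])
        x = self._embed(feats, node_mask)
        for l in range(self.cfg.n_interactions):
            filt = ssp(atomwise(rbf, p[f"b{l}.W_f1"], p[f"b{l}.b_f1"]))
            filt = ssp(atomwise(filt, p[f"b{l}.W_f2"], p[f"b{l}.b_f2"]))
            v = matmul(x, p[f"b{l}.W_in"])
            agg = cfconv(v, filt, feats["edge_index"], feats["n_nodes"])
            y = ssp(atomwise(agg, p[f"b{l}.W_o1"], p[f"b{l}.b_o1"]))
            y = atomwise(y, p[f"b{l}.W_o2"], p[f"b{l}.b_o2"])
            x = x + y
        h = ssp(atomwise(x, p["W_r1"], p["b_r1"]))
        h = dropout(h, self.cfg.dropout, rng, training)
        node_logits = atomwise(h, p["W_r2"], p["b_r2"])
        return self._pool(node_logits, feats)


class DirectionalNet(Model):
    """Directional message-passing classifier (distances_angles architecture)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__(cfg)
        H, K, C = cfg.hidden_dim, cfg.n_rbf, cfg.n_classes
        S = cfg.num_spherical * cfg.num_radial
        B, I, O = cfg.basis_embedding, cfg.interaction_embedding, cfg.output_embedding
        p = self.params
        p["type_embedding"] = parameter(rng.normal(0.0, 1.0, size=(cfg.n_node_types, H)))
        p["W_e0"] = _glorot(rng, K, H)
        p["W_emb"] = _glorot(rng, 3 * H, H)
        p["b_emb"] = _zeros(H)
        n_int = cfg.n_blocks - 1
        for l in range(n_int):
            p[f"i{l}.W_rb1"] = _glorot(rng, K, B)
            p[f"i{l}.W_rb2"] = _glorot(rng, B, H)
            p[f"i{l}.W_sb1"] = _glorot(rng, S, B)
            p[f"i{l}.W_sb2"] = _glorot(rng, B, I)
            p[f"i{l}.W_src"] = _glorot(rng, H, H)
            p[f"i{l}.b_src"] = _zeros(H)
            p[f"i{l}.W_kj"] = _glorot(rng, H, H)
            p[f"i{l}.b_kj"] = _zeros(H)
            p[f"i{l}.W_down"] = _glorot(rng, H, I)
            p[f"i{l}.W_up"] = _glorot(rng, I, H)
            p[f"i{l}.W_res"] = _glorot(rng, H, H)
            p[f"i{l}.b_res"] = _zeros(H)
        for l in range(cfg.n_blocks):  # one output block per building block
            p[f"o{l}.W_or"] = _glorot(rng, K, H)
            p[f"o{l}.W_up"] = _glorot(rng, H, O)
            p[f"o{l}.W_h"] = _glorot(rng, O, O)
            p[f"o{l}.b_h"] = _zeros(O)
            p[f"o{l}.W_c"] = _glorot(rng, O, C)
            p[f"o{l}.b_c"] = _zeros(C)

    def _interaction_params(self, l: int) -> dict:
        prefix = f"i{l}."
        return {k[len(prefix):]: v for k, v in self.params.items() if k.startswith(prefix)}

    def _output_block(self, l: int, m: Tensor, rbf: Tensor, feats: dict,
                      training: bool, rng) -> Tensor:
        p = self.params
        g = m * matmul(rbf, p[f"o{l}.W_or"])
        node = segment_sum(g, feats["edge_index"][1], feats["n_nodes"])
        u = matmul(node, p[f"o{l}.W_up"])
        u = ssp(atomwise(u, p[f"o{l}.W_h"], p[f"o{l}.b_h"]))
        u = dropout(u, self.cfg.dropout, rng, training)
        return atomwise(u, p[f"o{l}.W_c"], p[f"o{l}.b_c"])

    def forward(self, feats, training=False, rng=None, node_mask=None):
        p = self.params
        rbf = constant(feats["rbf"])
        z = self._embed(feats, node_mask)
        j, i = feats["edge_index"]
        m = ssp(
            atomwise(
                concat([gather(z, j), gather(z, i), matmul(rbf, p["W_e0"])], axis=1),
                p["W_emb"],
                p["b_emb"],
            )
        )
        node_out = self._output_block(0, m, rbf, feats, training, rng)
        for l in range(self.cfg.n_blocks - 1):
            m = m + dimenet_message_update(
                m, feats["rbf"], feats["sbf"], feats["trip_kj"], feats["trip_ji"],
                self._interaction_params(l),
            )
            node_out = node_out + self._output_block(l + 1, m, rbf, feats, training, rng)
        return self._pool(node_out, feats)


def build_model(cfg: ModelConfig, seed: int = 0) -> Model:
    rng = np.random.default_rng(seed)
    if cfg.architecture == "distances":
        return DistanceNet(cfg, rng)
    return DirectionalNet(cfg, rng)


# ---------------------------------------------------------------------------
# Prediction and checkpointing


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def predict_ec(logits: np.ndarray, vocab: Sequence[ECLabel]) -> tuple[ECLabel, float]:
    """Argmax class with its softmax confidence.

    Upper hierarchy levels follow by truncating the returned designation.
    Exact ties resolve to the lowest index (with a warning).
    """
    logits = np.asarray(logits, dtype=np.float64).reshape(-1)
    if len(logits) != len(vocab):
        raise ValueError(f"config error: {len(logits)} logits vs {len(vocab)} vocabulary entries")
    best = int(np.argmax(logits))
    if np.sum(logits == logits[best]) > 1:
        warnings.warn("tie at argmax; returning the lowest class index")
    conf = float(softmax(logits)[best])
    return vocab[best], conf


def save_checkpoint(path, model: Model, vocab: Sequence[ECLabel], scheme_version: str) -> None:
    """Self-describing checkpoint: parameters + config + vocab + scheme version."""
    meta = {
        "config": dataclasses.asdict(model.cfg),
        "vocab": [str(v) for v in vocab],
        "scheme_version": scheme_version,
    }
    arrays = {f"param:{k}": v.data for k, v in model.params.items()}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path, expected_vocab: Optional[Sequence[ECLabel]] = None):
    """Load (model, vocab, scheme_version); refuses on vocabulary mismatch."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        vocab = [ECLabel.parse(v) for v in meta["vocab"]]
        if expected_vocab is not None and [str(v) for v in vocab] != [str(v) for v in expected_vocab]:
            raise ValueError("checkpoint vocabulary does not match the expected class vocabulary")
        cfg = ModelConfig(**meta["config"])
        model = build_model(cfg, seed=0)
        for k in model.params:
            model.params[k] = parameter(np.array(data[f"param:{k}"]))
    return model, vocab, meta["scheme_version"]
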