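"""GCMM network: multi-view GCN encoder, channel attention, extractor, decoder.

The model scores drug-disease pairs by matrix completion.  Per node family
(drugs, diseases) each similarity view is encoded by its own GCN stack

    X^(l+1) = sigma( D~^{-1/2} (I + A) D~^{-1/2} X^(l) W^(l) ),   sigma = ReLU,

run full-batch on the dense similarity matrix used directly as weighted
adjacency.  A squeeze-and-excitation style attention layer pools each view
embedding to a scalar channel statistic (global average), maps the statistic
vector through relu/sigmoid bottleneck weights, and rescales each view by
its attention weight.  The rescaled channels are concatenated and reduced
by a fully connected ReLU extractor to the final per-node features; the
decoder scores every pair by the inner product U = X' Y'^T, and training
minimizes the squared Frobenius norm of U - U' on the observed-pair mask.

Everything here is plain NumPy; gradients are derived by hand and checked
against finite differences in the test suite.  The forward pass is
deterministic given the initialization seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DimensionError
from .hetnet import HeterogeneousNetwork, SimilarityMatrix


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# graph operator
# ---------------------------------------------------------------------------


def normalized_adjacency(G: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Symmetrically normalized self-looped adjacency D~^{-1/2}(I+A)D~^{-1/2}.

    The similarity matrix is used directly as a dense weighted adjacency;
    the added identity guarantees strictly positive degrees.
    """
    A = G.values if isinstance(G, SimilarityMatrix) else np.asarray(G, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError(f"adjacency must be square, got {A.shape}")
    if A.size and A.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * np.outer(inv_sqrt, inv_sqrt)


def topk_sparsify(A: np.ndarray, k: int) -> np.ndarray:
    """Keep each node's k strongest off-diagonal similarities, symmetrized.

    Dense similarity graphs make the normalized operator close to a global
    average, which oversmooths node features; restricting to the k nearest
    neighbours preserves local structure.  The diagonal is kept as is and
    the result is symmetrized by the elementwise maximum.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise DimensionError("adjacency must be square")
    if k <= 0:
        raise ConfigError("k must be positive")
    off = A.copy()
    np.fill_diagonal(off, -np.inf)
    keep = np.zeros_like(A)
    idx = np.argsort(off, axis=1)[:, -k:]
    rows = np.repeat(np.arange(A.shape[0]), idx.shape[1])
    keep[rows, idx.ravel()] = A[rows, idx.ravel()]
    keep = np.maximum(keep, keep.T)
    np.fill_diagonal(keep, np.diag(A))
    return keep


def gcn_layer(
    L: np.ndarray, X: np.ndarray, W: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One graph convolution sigma(L X W)."""
    if L.shape[0] != L.shape[1] or L.shape[1] != X.shape[0]:
        raise DimensionError(f"L {L.shape} incompatible with X {X.shape}")
    if X.shape[1] != W.shape[0]:
        raise DimensionError(f"X {X.shape} incompatible with W {W.shape}")
    pre = L @ X @ W
    if activation == "relu":
        return relu(pre)
    if activation in (None, "linear"):
        return pre
    raise ConfigError(f"unknown activation {activation!r}")


# ---------------------------------------------------------------------------
# parameter bundle
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class GcmmModel:
    """All trainable parameters plus the fixed initial feature matrices.

    ``params`` maps flat names to arrays:

    * ``gcn/<view>/<layer>`` — GCN weight matrices per similarity view,
    * ``att/<family>/W1``, ``att/<family>/W2`` — attention bottleneck,
    * ``lin/<family>/W``, ``lin/<family>/b`` — extractor weights and bias,
    * ``x0/drug``, ``x0/disease`` — only present when ``x0_trainable``.
    """

    drug_views: tuple[str, ...]
    disease_views: tuple[str, ...]
    n_layers: int
    params: dict[str, np.ndarray]
    x0_drug: np.ndarray
    x0_disease: np.ndarray
    attention: bool = True
    extractor: bool = True
    x0_trainable: bool = False

    @property
    def trainable(self) -> dict[str, np.ndarray]:
        return self.params

    def copy(self) -> "GcmmModel":
        return GcmmModel(
            self.drug_views,
            self.disease_views,
            self.n_layers,
            {k: v.copy() for k, v in self.params.items()},
            self.x0_drug.copy(),
            self.x0_disease.copy(),
            self.attention,
            self.extractor,
            self.x0_trainable,
        )


def init_model(
    n_drugs: int,
    n_diseases: int,
    drug_views: Sequence[str] = ("C", "T"),
    disease_views: Sequence[str] = ("M", "A"),
    n_layers: int = 2,
    init_dim: int = 256,
    embedding_dim: int = 256,
    n_out_channels: int = 128,
    attention_reduction: int = 2,
    attention: bool = True,
    extractor: bool = True,
    x0_trainable: bool = False,
    rng: np.random.Generator | None = None,
) -> GcmmModel:
    """Glorot-uniform parameter initialization; X^(0)/Y^(0) uniform [0, 1)."""
    if not drug_views or not disease_views:
        raise ConfigError("need at least one view per node family")
    if n_layers < 0:
        raise ConfigError("n_layers must be >= 0")
    rng = rng or np.random.default_rng()
    dims = [init_dim] + [embedding_dim] * n_layers
    params: dict[str, np.ndarray] = {}
    for view in (*drug_views, *disease_views):
        for l in range(n_layers):
            params[f"gcn/{view}/{l}"] = _glorot(rng, dims[l], dims[l + 1])
    emb = dims[-1]
    for family, views in (("drug", drug_views), ("disease", disease_views)):
        n_ch = len(views)
        if attention:
            reduced = max(1, n_ch // attention_reduction)
            params[f"att/{family}/W1"] = _glorot(rng, reduced, n_ch)
            params[f"att/{family}/W2"] = _glorot(rng, n_ch, reduced)
        if extractor:
            params[f"lin/{family}/W"] = _glorot(rng, n_ch * emb, n_out_channels)
            params[f"lin/{family}/b"] = np.zeros(n_out_channels)
    x0_drug = rng.uniform(0.0, 1.0, size=(n_drugs, init_dim))
    x0_disease = rng.uniform(0.0, 1.0, size=(n_diseases, init_dim))
    model = GcmmModel(
        tuple(drug_views),
        tuple(disease_views),
        n_layers,
        params,
        x0_drug,
        x0_disease,
        attention,
        extractor,
        x0_trainable,
    )
    if x0_trainable:
        model.params["x0/drug"] = x0_drug
        model.params["x0/disease"] = x0_disease
    return model


# ---------------------------------------------------------------------------
# forward pieces (exposed individually for testing and ablation)
# ---------------------------------------------------------------------------


def channel_statistic(X: np.ndarray) -> float:
    """Global average pooling: mean over every entry of a view embedding."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot pool an empty embedding")
    return float(X.mean())


def attention_weights(Z_g: np.ndarray, W1: np.ndarray, W2: np.ndarray) -> np.ndarray:
    """Squeeze-and-excitation weights sigmoid(W2 relu(W1 Z_g)), in (0, 1)."""
    Z_g = np.asarray(Z_g, dtype=float)
    if W1.shape[1] != Z_g.shape[0] or W2.shape[1] != W1.shape[0]:
        raise DimensionError("attention weight shapes do not compose")
    return sigmoid(W2 @ relu(W1 @ Z_g))


def apply_attention(
    views: Sequence[np.ndarray], Z_att: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Rescale each view by its attention weight and stack the channels."""
    if len(views) != len(Z_att):
        raise DimensionError("one attention weight required per view channel")
    scaled = [w * X for X, w in zip(views, Z_att)]
    return scaled, np.hstack(scaled)


def decode(X_final: np.ndarray, Y_final: np.ndarray) -> np.ndarray:
    """Inner-product decoder: U_ij = <drug i features, disease j features>."""
    if X_final.shape[1] != Y_final.shape[1]:
        raise DimensionError(
            f"feature dims differ: {X_final.shape[1]} vs {Y_final.shape[1]}"
        )
    return X_final @ Y_final.T


def loss(U: np.ndarray, U_label: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Squared Frobenius norm of U - U', optionally restricted to a mask."""
    U_label = np.asarray(U_label, dtype=float)
    if U.shape != U_label.shape:
        raise DimensionError(f"score {U.shape} vs label {U_label.shape}")
    diff = U - U_label
    if mask is not None:
        if mask.shape != U.shape:
            raise DimensionError("mask shape must match score matrix")
        diff = diff * mask
    return float((diff * diff).sum())


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------


def _encode_family(model, params, x0, views, adjacencies, cache):
    """GCN stacks + attention + extractor for one node family."""
    embeddings = {}
    for view in views:
        L = adjacencies[view]
        hidden = [x0]
        pre_acts = []
        H = x0
        for l in range(model.n_layers):
            W = params[f"gcn/{view}/{l}"]
            P = L @ H @ W
            H = relu(P)
            pre_acts.append(P)
            hidden.append(H)
        cache[f"hidden/{view}"] = hidden
        cache[f"pre/{view}"] = pre_acts
        embeddings[view] = H
    X_list = [embeddings[v] for v in views]
    family = cache["family"]
    if model.attention:
        Z_g = np.array([channel_statistic(X) for X in X_list])
        W1 = params[f"att/{family}/W1"]
        W2 = params[f"att/{family}/W2"]
        q = W1 @ Z_g
        a = relu(q)
        s = sigmoid(W2 @ a)
        cache.update({"Z_g": Z_g, "q": q, "a": a, "s": s})
    else:
        s = np.ones(len(views))
        cache["s"] = s
    scaled, stacked = apply_attention(X_list, s)
    cache["X_list"] = X_list
    cache["stacked"] = stacked
    if model.extractor:
        W = params[f"lin/{family}/W"]
        b = params[f"lin/{family}/b"]
        pre = stacked @ W + b
        final = relu(pre)
        cache["lin_pre"] = pre
    else:
        final = np.mean(scaled, axis=0)
    cache["final"] = final
    return final


def forward(
    model: GcmmModel,
    adjacencies: Mapping[str, np.ndarray],
    return_cache: bool = False,
):
    """Full forward pass; returns the score matrix U (and caches if asked)."""
    params = model.params
    x0_drug = params.get("x0/drug", model.x0_drug)
    x0_disease = params.get("x0/disease", model.x0_disease)
    cache_g: dict = {"family": "drug"}
    cache_s: dict = {"family": "disease"}
    X_final = _encode_family(
        model, params, x0_drug, model.drug_views, adjacencies, cache_g
    )
    Y_final = _encode_family(
        model, params, x0_disease, model.disease_views, adjacencies, cache_s
    )
    U = decode(X_final, Y_final)
    if return_cache:
        return U, cache_g, cache_s
    return U


def encode_views(
    net: HeterogeneousNetwork, model: GcmmModel
) -> dict[str, np.ndarray]:
    """Per-view GCN embeddings X^C, X^T, Y^M, Y^A for a network."""
    adjacencies = network_adjacencies(net)
    out = {}
    for view, x0 in [(v, model.x0_drug) for v in model.drug_views] + [
        (v, model.x0_disease) for v in model.disease_views
    ]:
        H = x0
        for l in range(model.n_layers):
            H = gcn_layer(adjacencies[view], H, model.params[f"gcn/{view}/{l}"])
        out[view] = H
    return out


def network_adjacencies(net: HeterogeneousNetwork) -> dict[str, np.ndarray]:
    """Normalized adjacency operator for each of the four views."""
    return {
        "C": normalized_adjacency(net.G_C),
        "T": normalized_adjacency(net.G_T),
        "M": normalized_adjacency(net.G_M),
        "A": normalized_adjacency(net.G_A),
    }


def _backward_family(model, params, grads, cache, views, adjacencies, d_final, x0_key):
    family = cache["family"]
    if model.extractor:
        pre = cache["lin_pre"]
        d_pre = d_final * (pre > 0)
        grads[f"lin/{family}/W"] = cache["stacked"].T @ d_pre
        grads[f"lin/{family}/b"] = d_pre.sum(axis=0)
        d_stacked = d_pre @ params[f"lin/{family}/W"].T
        emb = cache["X_list"][0].shape[1]
        d_scaled = [
            d_stacked[:, i * emb : (i + 1) * emb] for i in range(len(views))
        ]
    else:
        d_scaled = [d_final / len(views) for _ in views]

    s = cache["s"]
    X_list = cache["X_list"]
    d_X = [s[i] * d_scaled[i] for i in range(len(views))]
    if model.attention:
        ds = np.array(
            [float((d_scaled[i] * X_list[i]).sum()) for i in range(len(views))]
        )
        dp = ds * s * (1.0 - s)
        W2 = params[f"att/{family}/W2"]
        W1 = params[f"att/{family}/W1"]
        grads[f"att/{family}/W2"] = np.outer(dp, cache["a"])
        da = W2.T @ dp
        dq = da * (cache["q"] > 0)
        grads[f"att/{family}/W1"] = np.outer(dq, cache["Z_g"])
        dZ = W1.T @ dq
        for i, X in enumerate(X_list):
            d_X[i] = d_X[i] + dZ[i] / X.size

    for i, view in enumerate(views):
        L = adjacencies[view]
        hidden = cache[f"hidden/{view}"]
        pre_acts = cache[f"pre/{view}"]
        dH = d_X[i]
        for l in range(model.n_layers - 1, -1, -1):
            dP = dH * (pre_acts[l] > 0)
            W = params[f"gcn/{view}/{l}"]
            grads[f"gcn/{view}/{l}"] = (L @ hidden[l]).T @ dP
            dH = L.T @ dP @ W.T
        if model.x0_trainable:
            grads[x0_key] = grads.get(x0_key, 0.0) + dH


def loss_and_grads(
    model: GcmmModel,
    adjacencies: Mapping[str, np.ndarray],
    U_label: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Masked Frobenius loss with analytic gradients for every parameter."""
    U, cache_g, cache_s = forward(model, adjacencies, return_cache=True)
    value = loss(U, U_label, mask)
    diff = U - np.asarray(U_label, dtype=float)
    if mask is not None:
        diff = diff * mask
    dU = 2.0 * diff
    X_final, Y_final = cache_g["final"], cache_s["final"]
    grads: dict[str, np.ndarray] = {}
    _backward_family(
        model, model.params, grads, cache_g, model.drug_views, adjacencies,
        dU @ Y_final, "x0/drug",
    )
    _backward_family(
        model, model.params, grads, cache_s, model.disease_views, adjacencies,
        dU.T @ X_final, "x0/disease",
    )
    return value, grads, U


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


@dataclass
class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]):
        self._t += 1
        for name, g in grads.items():
            m = self._m.setdefault(name, np.zeros_like(params[name]))
            v = self._v.setdefault(name, np.zeros_like(params[name]))
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            m_hat = m / (1.0 - self.beta1**self._t)
            v_hat = v / (1.0 - self.beta2**self._t)
            params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: GcmmModel, path) -> None:
    """Serialize all arrays plus structure into one .npz archive."""
    meta = dict(
        drug_views=",".join(model.drug_views),
        disease_views=",".join(model.disease_views),
        n_layers=model.n_layers,
        attention=int(model.attention),
        extractor=int(model.extractor),
        x0_trainable=int(model.x0_trainable),
    )
    arrays = {f"param:{k}": v for k, v in model.params.items()}
    arrays["x0_drug"] = model.x0_drug
    arrays["x0_disease"] = model.x0_disease
    np.savez(path, _meta=np.array([repr(meta)]), **arrays)


def load_model(path) -> GcmmModel:
    with np.load(path, allow_pickle=False) as data:
        meta = eval(str(data["_meta"][0]))  # repr of a plain dict of str/int
        params = {
            k.split(":", 1)[1]: data[k] for k in data.files if k.startswith("param:")
        }
        return GcmmModel(
            tuple(meta["drug_views"].split(",")),
            tuple(meta["disease_views"].split(",")),
            int(meta["n_layers"]),
            params,
            data["x0_drug"],
            data["x0_disease"],
            bool(meta["attention"]),
            bool(meta["extractor"]),
            bool(meta["x0_trainable"]),
        )
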