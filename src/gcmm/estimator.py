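"""Scikit-learn style estimator wrapping the GCMM network.

The estimator is transductive: ``fit`` takes the heterogeneous network
itself (similarity views plus the partially observed association labels)
and a training-pair mask, optimizes all model parameters with Adam against
the masked squared-Frobenius reconstruction loss, and stores the completed
score matrix.  ``decision_function`` then reads scores for any drug-disease
pairs off that matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigError, TrainingFailureError
from .hetnet import HeterogeneousNetwork
from .model import (
    Adam,
    forward,
    init_model,
    loss_and_grads,
    normalized_adjacency,
    topk_sparsify,
)


class GCMM(BaseEstimator):
    """Multi-view GCN + channel attention + matrix-completion scorer.

    Parameters
    ----------
    n_layers : int, default 2
        GCN layers per similarity view.  Two layers propagate each node's
        features through its two-hop similarity neighbourhood; more layers
        over-smooth on these dense graphs.
    init_dim : int, default 256
        Width of the random initial feature matrices X^(0)/Y^(0).
    embedding_dim : int, default 256
        Output width of every GCN layer (the per-view embedding size).
    n_out_channels : int, default 128
        Final feature dimension produced by the fully connected extractor.
    attention, extractor : bool
        Ablation switches.  ``attention=False`` replaces the channel
        attention weights with unit weights; ``extractor=False`` averages
        the (rescaled) view channels instead of applying the linear layer.
    attention_reduction : int, default 2
        Bottleneck reduction factor of the attention layer.
    drug_views, disease_views : tuple of str
        Similarity views to use per family, subsets of ("C", "T") and
        ("M", "A").
    learning_rate : float, default 0.001
    n_epochs : int, default 1000
    adjacency_top_k : int or None, default None
        If set, each similarity graph keeps only every node's k strongest
        neighbours before normalization.  Dense similarity graphs make the
        propagation operator close to a global average, which oversmooths
        node features; sparsification preserves cluster structure and
        speeds convergence at short epoch budgets.
    x0_trainable : bool, default False
        Whether the initial feature matrices receive gradient updates.
    random_state : int or None
        Seeds parameter and feature initialization; fixing it makes the
        whole training trajectory reproducible.

    Attributes
    ----------
    model_ : GcmmModel             trained parameter bundle
    U_ : ndarray (n_drugs, n_diseases)   completed association scores
    loss_curve_ : ndarray          per-epoch training loss
    drug_ids_, disease_ids_ : tuple of str
    """

    def __init__(
        self,
        n_layers: int = 2,
        init_dim: int = 256,
        embedding_dim: int = 256,
        n_out_channels: int = 128,
        attention: bool = True,
        extractor: bool = True,
        attention_reduction: int = 2,
        drug_views: tuple = ("C", "T"),
        disease_views: tuple = ("M", "A"),
        learning_rate: float = 0.001,
        n_epochs: int = 1000,
        adjacency_top_k: int | None = None,
        x0_trainable: bool = False,
        random_state: int | None = None,
    ):
        self.n_layers = n_layers
        self.init_dim = init_dim
        self.embedding_dim = embedding_dim
        self.n_out_channels = n_out_channels
        self.attention = attention
        self.extractor = extractor
        self.attention_reduction = attention_reduction
        self.drug_views = drug_views
        self.disease_views = disease_views
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.adjacency_top_k = adjacency_top_k
        self.x0_trainable = x0_trainable
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _validate_views(self):
        dv = tuple(self.drug_views)
        sv = tuple(self.disease_views)
        if not dv or not set(dv) <= {"C", "T"}:
            raise ConfigError(f"drug_views must be a nonempty subset of C,T: {dv}")
        if not sv or not set(sv) <= {"M", "A"}:
            raise ConfigError(f"disease_views must be a nonempty subset of M,A: {sv}")
        return dv, sv

    @staticmethod
    def _as_mask(mask, shape) -> np.ndarray | None:
        if mask is None:
            return None
        mask = np.asarray(mask)
        if mask.dtype == bool or (mask.ndim == 2 and mask.shape == shape):
            return mask.astype(float)
        pairs = mask.reshape(-1, 2).astype(int)  # (i, j) index pairs
        out = np.zeros(shape)
        out[pairs[:, 0], pairs[:, 1]] = 1.0
        return out

    # -- estimator API ----------------------------------------------------

    def fit(self, X: HeterogeneousNetwork, y=None, mask=None):
        """Train on a heterogeneous network.

        Parameters
        ----------
        X : HeterogeneousNetwork
        y : ignored (labels live in ``X.assoc``); present for API symmetry
        mask : optional bool matrix or (n, 2) index array
            Training pairs over which the reconstruction loss is evaluated;
            ``None`` trains on the full label matrix.
        """
        if not isinstance(X, HeterogeneousNetwork):
            raise TypeError("X must be a HeterogeneousNetwork")
        if self.learning_rate < 0 or self.n_epochs < 0:
            raise ConfigError("learning_rate and n_epochs must be nonnegative")
        dv, sv = self._validate_views()
        labels = X.assoc.values.astype(float)
        mask_arr = self._as_mask(mask, labels.shape)
        rng = np.random.default_rng(self.random_state)
        model = init_model(
            n_drugs=labels.shape[0],
            n_diseases=labels.shape[1],
            drug_views=dv,
            disease_views=sv,
            n_layers=self.n_layers,
            init_dim=self.init_dim,
            embedding_dim=self.embedding_dim,
            n_out_channels=self.n_out_channels,
            attention_reduction=self.attention_reduction,
            attention=self.attention,
            extractor=self.extractor,
            x0_trainable=self.x0_trainable,
            rng=rng,
        )
        adjacencies = _adjacency_subset(X, dv + sv, self.adjacency_top_k)
        opt = Adam(lr=self.learning_rate)
        curve = np.empty(self.n_epochs)
        for epoch in range(self.n_epochs):
            value, grads, U = loss_and_grads(model, adjacencies, labels, mask_arr)
            if not np.isfinite(value):
                raise TrainingFailureError(epoch, value)
            curve[epoch] = value
            if self.learning_rate > 0:
                opt.step(model.params, grads)
        # scores after the final update
        U = forward(model, adjacencies)
        self.model_ = model
        self.U_ = U
        self.loss_curve_ = curve
        self.n_iter_ = self.n_epochs
        self.drug_ids_ = X.drug_ids
        self.disease_ids_ = X.disease_ids
        return self

    def decision_function(self, pairs=None) -> np.ndarray:
        """Scores for (drug index, disease index) pairs, or the full matrix."""
        if not hasattr(self, "U_"):
            raise RuntimeError("estimator is not fitted")
        if pairs is None:
            return self.U_
        pairs = np.asarray(pairs).reshape(-1, 2).astype(int)
        return self.U_[pairs[:, 0], pairs[:, 1]]

    def predict(self, pairs=None, threshold: float = 0.5) -> np.ndarray:
        """Binary calls from min-max scaled scores at the given threshold."""
        scores = self.decision_function(pairs)
        lo, hi = scores.min(), scores.max()
        scaled = (scores - lo) / (hi - lo) if hi > lo else np.full_like(scores, 0.5)
        return (scaled >= threshold).astype(int)


def _adjacency_subset(
    net: HeterogeneousNetwork, views, top_k: int | None = None
) -> dict[str, np.ndarray]:
    out = {}
    for v in views:
        mat = net.drug_view(v) if v in ("C", "T") else net.disease_view(v)
        A = mat.values
        if top_k is not None:
            A = topk_sparsify(A, top_k)
        out[v] = normalized_adjacency(A)
    return out
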