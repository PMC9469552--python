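"""Canonical synthetic benchmark: conditions and model configuration.

The benchmark trains the full pipeline on the default planted network
(100 drugs, 60 diseases, 5 clusters, 5% association noise) under 5-fold
balanced cross-validation.  The estimator uses 300 epochs at the standard
learning rate 0.001 with 32/64/32 feature widths, k=10 adjacency
sparsification and trainable initial features -- a configuration sized for
a 160-node graph (the 256/128 widths that suit a full drug-repurposing
dataset remain the estimator defaults).
"""

from __future__ import annotations

from .estimator import GCMM
from .hetnet import HeterogeneousNetwork
from .similarity import build_network
from .synthetic import SyntheticSpec, generate


def benchmark_spec(seed: int = 0) -> SyntheticSpec:
    return SyntheticSpec(seed=seed)


def benchmark_network(seed: int = 0) -> HeterogeneousNetwork:
    """Generate the benchmark bundle and assemble its similarity views."""
    b = generate(benchmark_spec(seed))
    return build_network(b.drugs, b.diseases, b.dag, b.target_sequences, b.assoc)


def benchmark_estimator(seed: int = 0, n_epochs: int = 300) -> GCMM:
    return GCMM(
        n_epochs=n_epochs,
        learning_rate=0.001,
        init_dim=32,
        embedding_dim=64,
        n_out_channels=32,
        adjacency_top_k=10,
        x0_trainable=True,
        random_state=seed,
    )
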