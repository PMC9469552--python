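"""The four similarity measures that populate the heterogeneous network.

Drug side
    chemical (C):     Tanimoto coefficient c / (a + b - c) on fingerprint bits.
    therapeutic (T):  mean normalized Smith-Waterman similarity over all
                      cross pairs of the two drugs' protein targets,
                      excluding pairs of the identical target token.

Disease side
    semantic (M):     shared-ancestry similarity over the ontology DAG,
                      sum of ancestor contributions F_s(n) over the shared
                      closure divided by the two semantic values DV(s).
    target (A):       Jaccard coefficient of the disease target-gene sets.

Degenerate-input conventions (0/0 cases): two all-zero fingerprints and two
empty target sets are treated as identical objects (similarity 1); one empty
against one non-empty scores 0; a therapeutic pair set emptied by the
identical-token exclusion scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, DimensionError, ResolutionError
from .hetnet import (
    DiseaseDAG,
    DiseaseRecord,
    DrugRecord,
    HeterogeneousNetwork,
    SimilarityMatrix,
)

# ---------------------------------------------------------------------------
# drug side
# ---------------------------------------------------------------------------


def chemical_similarity(fp_i: np.ndarray, fp_j: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length 0/1 fingerprints."""
    fp_i = np.asarray(fp_i, dtype=bool)
    fp_j = np.asarray(fp_j, dtype=bool)
    if fp_i.shape != fp_j.shape:
        raise DimensionError(
            f"fingerprint lengths differ: {fp_i.size} vs {fp_j.size}"
        )
    a = int(fp_i.sum())
    b = int(fp_j.sum())
    c = int((fp_i & fp_j).sum())
    if a + b == 0:
        return 1.0  # two empty fingerprints: identical objects
    union = a + b - c
    return c / union


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for local protein alignment.

    Defaults are the community-standard BLOSUM62 with affine gap penalties
    of 10 to open and 1 to extend (both expressed as non-negative costs).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


@lru_cache(maxsize=8)
def _make_aligner(matrix: str, gap_open: float, gap_extend: float):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # first residue of a gap costs gap_open, each further residue gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate_sequence(seq: str, alphabet: str) -> None:
    if not seq:
        raise AlignmentError("empty protein sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise AlignmentError(f"illegal residue(s) {sorted(bad)} for this matrix")


def smith_waterman_score(seq1: str, seq2: str, params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal local-alignment score (raw, unnormalized)."""
    aligner = _make_aligner(params.matrix, params.gap_open, params.gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    _validate_sequence(seq1, alphabet)
    _validate_sequence(seq2, alphabet)
    return float(aligner.score(seq1, seq2))


def smith_waterman_similarity(
    seq1: str, seq2: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Local-alignment similarity normalized into [0, 1].

    The raw score is divided by the geometric mean of the two self-alignment
    scores, so self-similarity is exactly 1 and the value cannot exceed 1.
    """
    raw = smith_waterman_score(seq1, seq2, params)
    if raw <= 0.0:
        return 0.0
    self1 = smith_waterman_score(seq1, seq1, params)
    self2 = smith_waterman_score(seq2, seq2, params)
    return raw / np.sqrt(self1 * self2)


def therapeutic_similarity(
    targets_i: Sequence[str],
    targets_j: Sequence[str],
    sequences: Mapping[str, str],
    params: AlignmentParams = AlignmentParams(),
    _cache: dict | None = None,
) -> float:
    """Mean pairwise target-sequence similarity between two drugs.

    Averages :func:`smith_waterman_similarity` over all cross pairs
    ``(e1, e2)`` of the two target sets, skipping pairs where ``e1`` and
    ``e2`` are the same target token.  Returns 0 when no pair survives.
    ``_cache`` may hold already-computed pair scores keyed by sorted token
    pair; it is filled in place.
    """
    missing = [t for t in (*targets_i, *targets_j) if t not in sequences]
    if missing:
        raise ResolutionError("target", missing)
    total, n_pairs = 0.0, 0
    for e1 in targets_i:
        for e2 in targets_j:
            if e1 == e2:
                continue
            key = (e1, e2) if e1 <= e2 else (e2, e1)
            if _cache is not None and key in _cache:
                score = _cache[key]
            else:
                score = smith_waterman_similarity(sequences[e1], sequences[e2], params)
                if _cache is not None:
                    _cache[key] = score
            total += score
            n_pairs += 1
    return total / n_pairs if n_pairs else 0.0


# ---------------------------------------------------------------------------
# disease side
# ---------------------------------------------------------------------------


def semantic_value(
    dag: DiseaseDAG, s: str, delta: float = 1.0
) -> tuple[dict[str, float], float]:
    """Ancestor contributions ``F_s`` and semantic value ``DV(s)``.

    ``F_s(s) = 1`` and for each ancestor ``n`` the contribution is
    ``delta * max(F_s(n'))`` over the children ``n'`` of ``n`` inside the
    closure.  ``delta = 1`` (the default) makes every contribution 1; the
    conventional decayed variant uses ``delta = 0.5``.
    """
    closure = dag.closure(s)
    memo: dict[str, float] = {}

    def contribution(n: str) -> float:
        if n == s:
            return 1.0
        if n not in memo:
            kids = [c for c in dag.children(n) if c in closure]
            memo[n] = delta * max(contribution(c) for c in kids)
        return memo[n]

    f = {n: contribution(n) for n in closure}
    return f, float(sum(f.values()))


def semantic_similarity(
    dag: DiseaseDAG, s_i: str, s_j: str, delta: float = 1.0
) -> float:
    """Shared-ancestry similarity of two ontology terms.

    Sums ``F_{s_i}(n) + F_{s_j}(n)`` over the shared closure and divides by
    ``DV(s_i) + DV(s_j)``; terms with disjoint closures score 0, identical
    terms score 1.
    """
    f_i, dv_i = semantic_value(dag, s_i, delta)
    f_j, dv_j = semantic_value(dag, s_j, delta)
    shared = f_i.keys() & f_j.keys()
    if not shared:
        return 0.0
    return sum(f_i[n] + f_j[n] for n in shared) / (dv_i + dv_j)


def target_jaccard(targets_i, targets_j) -> float:
    """Jaccard coefficient |E_i ∩ E_j| / |E_i ∪ E_j| of two target sets."""
    e_i, e_j = set(targets_i), set(targets_j)
    if not e_i and not e_j:
        return 1.0  # two empty sets: identical objects
    union = e_i | e_j
    return len(e_i & e_j) / len(union)


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------


def build_similarity_matrix(
    ids: Sequence[str],
    measure: Callable[[str, str], float],
    view: str,
    diagonal: float | None = 1.0,
) -> SimilarityMatrix:
    """Apply a pairwise measure over the upper triangle and mirror it.

    ``diagonal`` fixes the self-similarity explicitly; pass ``None`` to
    compute it with the measure (needed for the therapeutic view, whose
    self-value is governed by the identical-token exclusion).
    """
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = measure(ids[i], ids[i]) if diagonal is None else diagonal
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = measure(ids[i], ids[j])
    return SimilarityMatrix(view, tuple(ids), values)


def build_chemical_matrix(drugs: Mapping[str, DrugRecord]) -> SimilarityMatrix:
    ids = list(drugs)
    return build_similarity_matrix(
        ids,
        lambda a, b: chemical_similarity(drugs[a].fingerprint, drugs[b].fingerprint),
        view="C",
    )


def build_therapeutic_matrix(
    drugs: Mapping[str, DrugRecord],
    sequences: Mapping[str, str],
    params: AlignmentParams = AlignmentParams(),
) -> SimilarityMatrix:
    ids = list(drugs)
    cache: dict = {}
    return build_similarity_matrix(
        ids,
        lambda a, b: therapeutic_similarity(
            sorted(drugs[a].target_ids),
            sorted(drugs[b].target_ids),
            sequences,
            params,
            _cache=cache,
        ),
        view="T",
        diagonal=None,
    )


def build_semantic_matrix(
    diseases: Mapping[str, DiseaseRecord], dag: DiseaseDAG, delta: float = 1.0
) -> SimilarityMatrix:
    ids = list(diseases)
    return build_similarity_matrix(
        ids,
        lambda a, b: semantic_similarity(
            dag, diseases[a].dag_node, diseases[b].dag_node, delta
        ),
        view="M",
    )


def build_target_matrix(diseases: Mapping[str, DiseaseRecord]) -> SimilarityMatrix:
    ids = list(diseases)
    return build_similarity_matrix(
        ids,
        lambda a, b: target_jaccard(diseases[a].target_ids, diseases[b].target_ids),
        view="A",
    )


def build_network(
    drugs: Mapping[str, DrugRecord],
    diseases: Mapping[str, DiseaseRecord],
    dag: DiseaseDAG,
    sequences: Mapping[str, str],
    assoc,
    alignment_params: AlignmentParams = AlignmentParams(),
    delta: float = 1.0,
) -> HeterogeneousNetwork:
    """Assemble the full heterogeneous network from raw registries."""
    return HeterogeneousNetwork(
        G_C=build_chemical_matrix(drugs),
        G_T=build_therapeutic_matrix(drugs, sequences, alignment_params),
        G_M=build_semantic_matrix(diseases, dag, delta),
        G_A=build_target_matrix(diseases),
        assoc=assoc,
    )
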