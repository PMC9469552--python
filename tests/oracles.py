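"""Independent brute-force oracles used only for cross-checking.

Deliberately naive implementations: explicit loops, no shared code with the
package internals.
"""

import numpy as np

NEG = float("-inf")


def sw_affine_score(seq1, seq2, score, gap_open, gap_extend):
    """Local alignment via the explicit 3-matrix (Gotoh) recurrence.

    ``score(a, b)`` is the substitution score; the first residue of a gap
    costs ``gap_open`` and each further residue ``gap_extend``.
    """
    n, m = len(seq1), len(seq2)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq2 (consumes seq1)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq1 (consumes seq2)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = score(seq1[i - 1], seq2[j - 1]) + diag
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def gcn_layer_triple_loop(L, X, W):
    """sigma(L X W) with explicit summation loops and ReLU."""
    n, d_in = X.shape
    d_out = W.shape[1]
    LX = [[sum(L[i][k] * X[k][f] for k in range(n)) for f in range(d_in)]
          for i in range(n)]
    out = np.zeros((n, d_out))
    for i in range(n):
        for o in range(d_out):
            v = sum(LX[i][f] * W[f][o] for f in range(d_in))
            out[i][o] = v if v > 0 else 0.0
    return out


def decode_double_loop(X, Y):
    """Inner-product scores by explicit double loop."""
    out = np.zeros((X.shape[0], Y.shape[0]))
    for i in range(X.shape[0]):
        for j in range(Y.shape[0]):
            out[i][j] = float(np.dot(X[i], Y[j]))
    return out


def auc_pairwise(scores, labels):
    """Rank-statistic AUC: fraction of (positive, negative) pairs ordered
    correctly, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total, wins = 0, 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / total


def semantic_closed_form(closure_i, closure_j):
    """With unit contributions, similarity is 2|Ni ∩ Nj| / (|Ni| + |Nj|)."""
    shared = len(set(closure_i) & set(closure_j))
    return 2.0 * shared / (len(closure_i) + len(closure_j))
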