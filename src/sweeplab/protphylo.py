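"""Protein distance matrices, neighbor joining and bootstrap supports.

Pairwise distances are maximum-likelihood branch lengths under the WAG
empirical substitution model (eigendecomposition of the reversible rate
matrix, scalar likelihood optimization per pair, pairwise deletion of gap
columns).  Trees are built with the canonical neighbor-joining algorithm
(Q-criterion, deterministic lexicographic tie-break, negative branch
lengths clamped to zero) and bootstrap supports are the percentage of
column-resampled replicates containing each internal bipartition of the
tree from the full alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._wag import AMINO_ACIDS, WAG_EXCHANGEABILITIES, WAG_FREQUENCIES

__all__ = [
    "ProteinAlignment",
    "percent_identity_matrix",
    "wag_ml_distance",
    "ml_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
]

_MIN_T, _MAX_T = 1e-6, 10.0


@dataclass
class ProteinAlignment:
    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise ValueError("one name per sequence required")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("aligned sequences must share a length")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def columns(self, idx: np.ndarray) -> "ProteinAlignment":
        seqs = ["".join(s[j] for j in idx) for s in self.sequences]
        return ProteinAlignment(list(self.names), seqs)


def percent_identity_matrix(aln: ProteinAlignment) -> pd.DataFrame:
    """% identical residues per pair over columns where neither sequence
    has a gap."""
    n = len(aln.names)
    m = np.array([list(s.upper()) for s in aln.sequences])
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] != "-") & (m[j] != "-")
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise ValueError(f"no comparable columns for pair "
                                 f"({aln.names[i]}, {aln.names[j]})")
            out[i, j] = out[j, i] = 100.0 * np.mean(m[i, ok] == m[j, ok])
    return pd.DataFrame(out, index=aln.names, columns=aln.names)


class _SubstModel:
    """Reversible amino-acid model with precomputed eigendecomposition."""

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray):
        pi = np.asarray(frequencies, dtype=float)
        pi = pi / pi.sum()
        k = len(pi)
        R = np.zeros((k, k))
        idx = 0
        for i in range(1, k):
            for j in range(i):
                R[i, j] = R[j, i] = exchangeabilities[idx]
                idx += 1
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize to one expected substitution per unit time
        Q /= -np.sum(pi * np.diag(Q))
        # symmetrize: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self.pi = pi
        self._left = U * (1.0 / sq)[:, None]
        self._right = (U * sq[:, None]).T
        self._w = w

    def transition(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * t)) @ self._right
        return np.clip(P, 1e-300, None)  # guard log of tiny negatives

    def aa_index(self, alphabet: str) -> dict[str, int]:
        return {a: i for i, a in enumerate(alphabet)}


_WAG = _SubstModel(WAG_EXCHANGEABILITIES, WAG_FREQUENCIES)


def _pair_counts(seq_a: str, seq_b: str, alphabet: str = AMINO_ACIDS) -> np.ndarray:
    lut = {a: i for i, a in enumerate(alphabet)}
    k = len(alphabet)
    C = np.zeros((k, k))
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        i, j = lut.get(x), lut.get(y)
        if i is None or j is None:
            continue            # gaps and ambiguous residues: pairwise deletion
        C[i, j] += 1
    if C.sum() == 0:
        raise ValueError("no comparable columns between the sequences")
    return C


def wag_ml_distance(seq_a: str, seq_b: str,
                    exchangeabilities: np.ndarray | None = None,
                    frequencies: np.ndarray | None = None) -> float:
    """ML pairwise distance under WAG (or a caller-supplied reversible
    model), maximizing sum C_ab log(pi_a P_ab(t)) over t in [1e-6, 10]."""
    if exchangeabilities is None and frequencies is None:
        model = _WAG
    else:
        model = _SubstModel(
            WAG_EXCHANGEABILITIES if exchangeabilities is None else exchangeabilities,
            WAG_FREQUENCIES if frequencies is None else frequencies)
    C = _pair_counts(seq_a, seq_b)
    log_pi = np.log(model.pi)

    def nll(t: float) -> float:
        P = model.transition(t)
        return -float(np.sum(C * (log_pi[:, None] + np.log(P))))

    res = minimize_scalar(nll, bounds=(_MIN_T, _MAX_T), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def ml_distance_matrix(aln: ProteinAlignment, **model_kw) -> pd.DataFrame:
    n = len(aln.names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = wag_ml_distance(aln.sequences[i],
                                                aln.sequences[j], **model_kw)
    return pd.DataFrame(d, index=aln.names, columns=aln.names)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: pd.DataFrame) -> dendropy.Tree:
    """Canonical NJ on a symmetric distance matrix -> unrooted tree.

    Join selection uses the Q criterion with ties broken by the
    lexicographically smallest taxon-name pair; negative branch lengths
    are clamped to zero.
    """
    names = list(dm.index)
    if len(names) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dm.to_numpy(), dm.to_numpy().T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    D = {n: {m: float(dm.loc[n, m]) for m in names} for n in names}
    newick_of = {n: n.replace(" ", "_") for n in names}
    active = sorted(names)
    while len(active) > 3:
        r = len(active)
        S = {n: sum(D[n][m] for m in active if m != n) for n in active}
        best, best_q = None, np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * D[a][b] - S[a] - S[b]
                key = tuple(sorted((a, b)))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12
                                          and (best is None or key < best)):
                    best_q, best = q, key
        a, b = best
        va = 0.5 * D[a][b] + (S[a] - S[b]) / (2.0 * (r - 2))
        vb = D[a][b] - va
        va, vb = max(va, 0.0), max(vb, 0.0)
        new = f"__join_{len(newick_of)}"
        newick_of[new] = (f"({newick_of[a]}:{va:.10g},{newick_of[b]}:{vb:.10g})")
        D[new] = {}
        for m in active:
            if m in (a, b):
                continue
            d = 0.5 * (D[a][m] + D[b][m] - D[a][b])
            D[new][m] = D[m][new] = max(d, 0.0)
        active = sorted([m for m in active if m not in (a, b)] + [new])
    a, b, c = active
    va = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    vb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    vc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    parts = [f"{newick_of[n]}:{max(v, 0.0):.10g}"
             for n, v in zip((a, b, c), (va, vb, vc))]
    newick = f"({parts[0]},{parts[1]},{parts[2]});"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Internal bipartitions as frozensets of the side not containing the
    lexicographically first taxon (unrooted normalization)."""
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = taxa[0]
    out: set[frozenset[str]] = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(taxa) - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def bootstrap_support(aln: ProteinAlignment, n_reps: int = 1000, seed=0,
                      **model_kw) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement; supports (percent of
    replicates containing each internal bipartition of the original tree)
    are attached to the corresponding internal-node labels.
    """
    if len(aln.names) < 4:
        raise ValueError("bootstrap supports need at least 4 taxa")
    tree = neighbor_joining(ml_distance_matrix(aln, **model_kw))
    target = _bipartitions(tree)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, aln.length, size=aln.length)
        rep = aln.columns(idx)
        rep_tree = neighbor_joining(ml_distance_matrix(rep, **model_kw))
        found = _bipartitions(rep_tree)
        for bp in target:
            if bp in found:
                hits[bp] += 1
    support = {bp: 100.0 * h / n_reps for bp, h in hits.items()}
    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = taxa[0]
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(taxa) - side
        if side in support:
            node.label = f"{support[side]:.0f}"
    return tree, support
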