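"""Alignment-based diversity statistics for amplicon haplotype sets.

Covers the verification stage of the pipeline: segregating sites,
per-locus Watterson's theta, per-site nucleotide diversity, Tajima's D
with its beta-distribution p-value, and a permutation test for a
difference in nucleotide diversity between two groups of sequences.

Conventions (documented because the two estimators deliberately differ):
theta_W is reported per locus (S / a1), pi per site; gap handling is
complete-deletion for S, theta_W and Tajima's D, pairwise-deletion for pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from scipy import stats

__all__ = [
    "AlignmentSet",
    "DiversityResult",
    "read_alignment_fasta",
    "segregating_sites",
    "watterson_theta",
    "nucleotide_diversity",
    "mean_pairwise_differences",
    "tajimas_d",
    "tajimas_d_from_summary",
    "pi_permutation_test",
    "diversity_result",
]

_GAP = {"-"}
_MISSING = {"-", "N", "n"}


@dataclass
class AlignmentSet:
    """Equal-length nucleotide sequences with per-sequence line labels."""

    sequences: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("sequences must all have the same length")
        if self.labels is None:
            self.labels = ["seq"] * len(self.sequences)
        if len(self.labels) != len(self.sequences):
            raise ValueError("one label per sequence required")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def subset(self, label: str) -> "AlignmentSet":
        seqs = [s for s, l in zip(self.sequences, self.labels) if l == label]
        return AlignmentSet(seqs, [label] * len(seqs))

    def matrix(self) -> np.ndarray:
        return np.array([list(s.upper()) for s in self.sequences])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, (seq, lab) in enumerate(zip(self.sequences, self.labels), 1):
                fh.write(f">{lab}_{i}\n{seq}\n")


def read_alignment_fasta(path, label_of=None) -> AlignmentSet:
    """Load an aligned FASTA; ``label_of`` maps record id -> line label
    (default: the id up to the last underscore)."""
    seqs, labels = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.append(str(rec.seq).upper())
        if label_of is None:
            labels.append(rec.id.rsplit("_", 1)[0])
        else:
            labels.append(label_of(rec.id))
    return AlignmentSet(seqs, labels)


def _complete_columns(aln: AlignmentSet) -> np.ndarray:
    """Columns free of gaps, as a character matrix (n, L')."""
    m = aln.matrix()
    keep = ~np.any(np.isin(m, list(_GAP)), axis=0)
    return m[:, keep]


def segregating_sites(aln: AlignmentSet) -> int:
    """Number of columns with >= 2 distinct non-missing bases
    (gap-containing columns are excluded entirely)."""
    m = _complete_columns(aln)
    count = 0
    for j in range(m.shape[1]):
        col = m[:, j]
        bases = set(col) - _MISSING
        if len(bases) >= 2:
            count += 1
    return count


def harmonic_a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int) -> float:
    """Per-locus Watterson estimate S / a1(n)."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return 0.0
    return S / harmonic_a1(n)


def _pair_stats(m: np.ndarray) -> tuple[float, float]:
    """(mean pairwise differences, mean pairwise proportion of differences)
    over all sequence pairs with pairwise deletion of missing data."""
    n = m.shape[0]
    valid = ~np.isin(m, list(_MISSING))
    diffs, props = [], []
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            ncomp = int(ok.sum())
            if ncomp == 0:
                continue
            d = int(np.sum(m[i, ok] != m[j, ok]))
            diffs.append(d)
            props.append(d / ncomp)
    if not diffs:
        raise ValueError("no comparable sequence pairs")
    return float(np.mean(diffs)), float(np.mean(props))


def nucleotide_diversity(aln: AlignmentSet) -> float:
    """Per-site pi: mean pairwise proportion of differing sites."""
    return _pair_stats(aln.matrix())[1]


def mean_pairwise_differences(aln: AlignmentSet) -> float:
    """Per-locus mean number of pairwise differences over gap-free columns."""
    return _pair_stats(_complete_columns(aln))[0]


def _tajima_constants(n: int, S: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2, "var": var}


def tajimas_d_from_summary(n: int, S: int, k_hat: float,
                           p_method: str = "beta") -> tuple[float, float]:
    """Tajima's D from (chromosomes, segregating sites, mean pairwise
    differences), with a p-value for D != 0.

    ``p_method`` is "beta" (Tajima's bounded-beta approximation of the
    null distribution of D) or "normal".
    """
    if S == 0:
        raise ValueError("Tajima's D is undefined with no segregating sites")
    c = _tajima_constants(n, S)
    D = (k_hat - S / c["a1"]) / np.sqrt(c["var"])
    if p_method == "normal":
        p = 2.0 * stats.norm.sf(abs(D))
    elif p_method == "beta":
        # D is bounded: all-singleton vs maximally intermediate configurations
        d_min = (2.0 / n - 1.0 / c["a1"]) / np.sqrt(c["e2"])
        d_max = ((n + 1) / (2.0 * n) - 1.0 / c["a1"]) / np.sqrt(c["e2"])
        tmp1 = 1.0 + d_min * d_max
        tmp2 = d_max - d_min
        a = -tmp1 * d_max / tmp2
        b = tmp1 * d_min / tmp2
        x = np.clip((D - d_min) / tmp2, 0.0, 1.0)
        cdf = stats.beta.cdf(x, b, a)
        p = float(2 * cdf if cdf < 0.5 else 2 * (1 - cdf))
    else:
        raise ValueError("p_method must be 'beta' or 'normal'")
    return float(D), float(p)


def tajimas_d(aln: AlignmentSet, p_method: str = "beta") -> tuple[float, float]:
    """Tajima's D over gap-free columns of an alignment."""
    return tajimas_d_from_summary(aln.n, segregating_sites(aln),
                                  mean_pairwise_differences(aln), p_method)


def pi_permutation_test(aln_a: AlignmentSet, aln_b: AlignmentSet,
                        n_perm: int = 10_000, seed=None) -> tuple[float, float]:
    """Two-sided permutation test for a difference in pi between groups.

    Observed statistic is pi_A - pi_B; group labels are shuffled across
    the pooled sequences preserving group sizes, and the p-value uses the
    add-one correction (1 + #extreme) / (n_perm + 1), so it is never 0.
    """
    if aln_a.length != aln_b.length:
        raise ValueError("alignments must cover the same locus length")
    if aln_a.n < 2 or aln_b.n < 2:
        raise ValueError("each group needs at least 2 sequences")
    pooled = np.vstack([aln_a.matrix(), aln_b.matrix()])
    n_a, n_tot = aln_a.n, aln_a.n + aln_b.n
    # pi of any subset is the mean of fixed per-pair difference proportions,
    # so precompute the pairwise matrix once
    valid = ~np.isin(pooled, list(_MISSING))
    prop = np.zeros((n_tot, n_tot))
    for i in range(n_tot):
        for j in range(i + 1, n_tot):
            ok = valid[i] & valid[j]
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise ValueError("sequence pair with no comparable sites")
            prop[i, j] = prop[j, i] = np.sum(pooled[i, ok] != pooled[j, ok]) / ncomp

    def delta(idx_a: np.ndarray) -> float:
        mask = np.zeros(n_tot, dtype=bool)
        mask[idx_a] = True
        sub_a = prop[np.ix_(mask, mask)]
        sub_b = prop[np.ix_(~mask, ~mask)]
        na, nb = mask.sum(), (~mask).sum()
        pi_a = sub_a.sum() / (na * (na - 1))
        pi_b = sub_b.sum() / (nb * (nb - 1))
        return pi_a - pi_b

    obs = delta(np.arange(n_a))
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        idx = rng.choice(n_tot, size=n_a, replace=False)
        if abs(delta(idx)) >= abs(obs) - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (n_perm + 1)
    return float(obs), float(p)


@dataclass
class DiversityResult:
    """Per-line summary for one amplicon."""

    line: str
    n: int
    S: int
    theta_w: float
    pi: float
    tajimas_d: float
    d_p_value: float


def diversity_result(aln: AlignmentSet, line: str) -> DiversityResult:
    sub = aln.subset(line) if line in set(aln.labels) else aln
    S = segregating_sites(sub)
    if S > 0:
        D, p = tajimas_d(sub)
    else:
        D, p = float("nan"), float("nan")
    return DiversityResult(
        line=line, n=sub.n, S=S,
        theta_w=watterson_theta(S, sub.n),
        pi=nucleotide_diversity(sub),
        tajimas_d=D, d_p_value=p)
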