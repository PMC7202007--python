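"""Protein-variant tabulation and the exact contingency analysis.

Consensus coding haplotypes (two per individual) are translated, diffed
against a reference protein, collapsed into named variants, counted per
line as chromosomes, and compared between lines with a two-sided exact
r x c Fisher test (point-probability rule).  Haplotype frequencies are
computed either from variant counts via a predicate or from diploid
genotype tallies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

__all__ = [
    "VariantTable",
    "translate",
    "call_protein_variants",
    "fisher_exact_rxc",
    "haplotype_frequency",
    "haplotype_frequency_from_genotypes",
    "read_haplotype_fasta",
]

_CODON = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


class FrameError(ValueError):
    pass


def translate(cds: str) -> str:
    """Standard-genetic-code translation.

    The stop codon is rendered '*' and translation halts after it; codons
    containing an ambiguous base become 'X'.  A trailing partial codon is
    only an error when no stop was reached first.
    """
    s = cds.upper().replace("U", "T")
    out = []
    for i in range(0, len(s) - 2, 3):
        codon = s[i:i + 3]
        if codon in _STOPS:
            out.append("*")
            return "".join(out)
        if codon in _CODON:
            out.append(_CODON[codon])
        else:
            out.append("X")
    if len(s) % 3 != 0:
        raise FrameError("sequence length is not a multiple of 3 and no "
                         "in-frame stop codon was reached")
    return "".join(out)


@dataclass
class VariantTable:
    """Named protein variants with per-line chromosome counts."""

    counts: pd.DataFrame            # index: variant name; columns: lines
    descriptors: dict[str, list[str]]
    proteins: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative variant counts")

    def line_total(self, line: str) -> int:
        return int(self.counts[line].sum())

    def to_contingency(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=int)


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _describe(ref_prot: str, prot: str, aligner: PairwiseAligner) -> list[str]:
    """Human-readable descriptors of protein differences in reference
    coordinates: substitutions (e.g. T1706K), in-frame indels with residue
    strings, and truncation when the protein stops early.

    A deletion block that runs to the end of the alignment of a protein
    ending in a premature stop is a truncation, not an internal deletion.
    """
    stopped_early = prot.endswith("*") and len(prot) < len(ref_prot)
    core = prot[:-1] if prot.endswith("*") else prot
    ref_core = ref_prot[:-1] if ref_prot.endswith("*") else ref_prot
    if core == ref_core:
        return ["reference"]
    aln = aligner.align(ref_core, core)[0]
    ref_a, alt_a = aln[0], aln[1]
    # alignment columns after the protein's last residue
    tail = len(ref_a)
    while tail > 0 and alt_a[tail - 1] == "-":
        tail -= 1
    desc: list[str] = []
    ref_pos = 0
    i = 0
    while i < tail:
        r, q = ref_a[i], alt_a[i]
        if r != "-" and q != "-":
            ref_pos += 1
            if r != q:
                desc.append(f"{r}{ref_pos}{q}")
            i += 1
        elif q == "-":          # internal deletion relative to the reference
            j = i
            lost = []
            while j < tail and alt_a[j] == "-" and ref_a[j] != "-":
                lost.append(ref_a[j])
                j += 1
            desc.append(f"del{ref_pos + 1}-{ref_pos + len(lost)}:{''.join(lost)}")
            ref_pos += len(lost)
            i = j
        else:                   # insertion relative to the reference
            j = i
            gained = []
            while j < tail and ref_a[j] == "-" and alt_a[j] != "-":
                gained.append(alt_a[j])
                j += 1
            desc.append(f"ins{ref_pos}:{''.join(gained)}")
            i = j
    if tail < len(ref_a):
        n_missing = sum(1 for k in range(tail, len(ref_a)) if ref_a[k] != "-")
        if stopped_early:
            desc.append(f"truncation@{ref_pos + 1}")
        elif n_missing:
            desc.append(f"del{ref_pos + 1}-{ref_pos + n_missing}:"
                        f"{''.join(c for c in ref_a[tail:] if c != '-')}")
    return desc


def read_haplotype_fasta(path) -> dict[str, list[str]]:
    """FASTA of haplotype CDSs named ``<individual>_<hap>`` ->
    individual -> list of sequences."""
    out: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ind = rec.id.rsplit("_", 1)[0]
        out.setdefault(ind, []).append(str(rec.seq))
    return out


def call_protein_variants(haplotypes: dict[str, list[str]], reference_cds: str,
                          line_of: dict[str, str]) -> VariantTable:
    """Translate two consensus haplotypes per individual and tabulate the
    distinct protein variants per line.

    Variants are named ``variant_1``, ``variant_2``, ... by descending
    pooled chromosome count (ties broken by sequence); the mapping to any
    external numbering is therefore by frequency rank.
    """
    ref_prot = translate(reference_cds)
    aligner = _protein_aligner()
    lines: list[str] = []
    for ind in haplotypes:
        lab = line_of.get(ind)
        if lab is None:
            raise KeyError(f"individual {ind!r} missing from line map")
        if lab not in lines:
            lines.append(lab)
    prot_counts: dict[str, dict[str, int]] = {}
    for ind, haps in haplotypes.items():
        if len(haps) != 2:
            raise ValueError(f"individual {ind!r} must contribute exactly 2 "
                             f"haplotypes, got {len(haps)}")
        for h in haps:
            prot = translate(h)
            prot_counts.setdefault(prot, {l: 0 for l in lines})
            prot_counts[prot][line_of[ind]] += 1
    ordered = sorted(prot_counts.items(),
                     key=lambda kv: (-sum(kv[1].values()), kv[0]))
    names = [f"variant_{i}" for i in range(1, len(ordered) + 1)]
    counts = pd.DataFrame([kv[1] for kv in ordered], index=names)[lines]
    descriptors = {name: _describe(ref_prot, prot, aligner)
                   for name, (prot, _) in zip(names, ordered)}
    proteins = {name: prot for name, (prot, _) in zip(names, ordered)}
    table = VariantTable(counts=counts, descriptors=descriptors,
                         proteins=proteins)
    # chromosome conservation: two per individual per line
    per_line_inds: dict[str, int] = {}
    for ind, lab in ((i, line_of[i]) for i in haplotypes):
        per_line_inds[lab] = per_line_inds.get(lab, 0) + 1
    for lab, n_ind in per_line_inds.items():
        if table.line_total(lab) != 2 * n_ind:
            raise AssertionError("chromosome counts do not sum to 2 x individuals")
    return table


def _log_factorials(n: int) -> np.ndarray:
    return np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])


def fisher_exact_rxc(table, max_states: int = 10_000_000,
                     n_mc: int = 1_000_000, seed=0,
                     force_enumeration: bool = False) -> float:
    """Two-sided exact Fisher test for an r x c contingency table.

    The p-value sums the probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one
    (relative tolerance 1e-9).  2 x 2 tables use the closed-form
    hypergeometric test; when the margin-constrained state space exceeds
    ``max_states`` the enumeration falls back to Monte-Carlo sampling of
    tables from the margin-conditional null.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("table has an all-zero margin")
    if t.shape == (2, 2) and not force_enumeration:
        return float(stats.fisher_exact(t)[1])
    n = int(t.sum())
    lf = _log_factorials(n)
    log_margin = lf[rows].sum() + lf[cols].sum() - lf[n]

    def log_prob(cells: np.ndarray) -> float:
        return log_margin - lf[cells].sum()

    obs_lp = log_prob(t)
    # size of the margin-constrained search space (upper bound)
    bound = 1
    for r in rows:
        for cval in cols[:-1]:
            bound *= min(r, cval) + 1
            if bound > max_states:
                break
        if bound > max_states:
            break
    if bound > max_states:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(rows, cols)
        extreme = 0
        chunk = 100_000
        done = 0
        while done < n_mc:
            k = min(chunk, n_mc - done)
            draws = dist.rvs(k, random_state=rng).astype(int)
            lps = log_margin - lf[draws].reshape(k, -1).sum(axis=1)
            extreme += int(np.sum(lps <= obs_lp + 1e-9))
            done += k
        return (1 + extreme) / (n_mc + 1)

    r_margins = list(rows)
    c = len(cols)
    total_p = 0.0

    def recurse(row_idx: int, col_rem: np.ndarray, lp_acc: float) -> None:
        nonlocal total_p
        if row_idx == len(r_margins) - 1:
            if (col_rem < 0).any():
                return
            lp = lp_acc - lf[col_rem].sum()
            if lp <= obs_lp + 1e-9 * abs(obs_lp):
                total_p += math.exp(lp)
            return
        r = r_margins[row_idx]
        ranges = [range(min(r, col_rem[j]) + 1) for j in range(c - 1)]
        for combo in itertools.product(*ranges):
            last = r - sum(combo)
            if last < 0 or last > col_rem[c - 1]:
                continue
            cells = np.array(combo + (last,))
            recurse(row_idx + 1, col_rem - cells,
                    lp_acc - lf[cells].sum())

    recurse(0, cols.copy(), log_margin)
    return float(min(total_p, 1.0))


def haplotype_frequency(counts: dict[str, int] | pd.Series, predicate) -> float:
    """Fraction of chromosomes whose variant satisfies ``predicate``
    (a callable on the variant name, or a collection of names)."""
    if isinstance(counts, pd.Series):
        counts = counts.to_dict()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero chromosomes")
    if callable(predicate):
        match = sum(v for k, v in counts.items() if predicate(k))
    else:
        wanted = set(predicate)
        match = sum(v for k, v in counts.items() if k in wanted)
    return match / total


def haplotype_frequency_from_genotypes(hom_ref: int, het: int, hom_alt: int,
                                       which: str = "ref") -> float:
    """Haplotype frequency from diploid genotype tallies
    (2 chromosomes per individual)."""
    total = 2 * (hom_ref + het + hom_alt)
    if total == 0:
        raise ValueError("zero chromosomes")
    if which == "ref":
        return (2 * hom_ref + het) / total
    if which == "alt":
        return (2 * hom_alt + het) / total
    raise ValueError("which must be 'ref' or 'alt'")
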