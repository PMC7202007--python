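"""Windowed selective-sweep scan.

The scan combines three window statistics computed from the filtered
genotype matrix of the two lines:

* pooled heterozygosity of the selected line,
  ``Hp = 2 (sum n_MAJ)(sum n_MIN) / (sum n_MAJ + sum n_MIN)^2``, over
  40-kb windows stepping 20 kb, excluding windows with fewer than 10
  SNPs, and Z-standardized over included windows (ZHp);
* the Weir & Cockerham (1984) two-population theta over the same windows
  (ratio-of-sums across SNPs by default, or the arithmetic mean of
  per-SNP estimates), Z-standardized (ZF_ST);
* a per-window binomial likelihood-ratio test of allele-frequency
  divergence on a finer 5-kb/1-kb grid, Benjamini-Hochberg corrected.

Candidate sweeps are runs of windows with ZHp below a threshold, ZF_ST
above a threshold, and at least one overlapping fine-grid window with
q below the FDR level; flagged windows within one step of each other
merge into a single candidate, which can then be annotated with
overlapping or nearest genes from a GFF3.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .vcfio import GenotypeMatrix

__all__ = [
    "make_windows",
    "pooled_heterozygosity",
    "z_transform",
    "wc_fst_components",
    "wc_fst_window",
    "window_lrt",
    "benjamini_hochberg",
    "window_scan",
    "lrt_scan",
    "call_candidates",
    "annotate_candidates",
    "read_gff3_genes",
]


def make_windows(contig_lengths: dict[str, int], size: int = 40_000,
                 step: int = 20_000) -> pd.DataFrame:
    """Sliding windows (0-based half-open) per contig; the terminal window
    is truncated at the contig end."""
    if size <= 0 or not 0 < step <= size:
        raise ValueError("require size > 0 and 0 < step <= size")
    rows = []
    for contig, length in contig_lengths.items():
        start = 0
        while start < length:
            rows.append((contig, start, min(start + size, length)))
            start += step
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def pooled_heterozygosity(n_maj: np.ndarray, n_min: np.ndarray,
                          min_snps: int = 10) -> float:
    """Hp from per-SNP within-line major/minor allele counts of one window.

    Returns NaN (window excluded, not an error) when fewer than
    ``min_snps`` SNPs contribute.
    """
    n_maj = np.asarray(n_maj, dtype=float)
    n_min = np.asarray(n_min, dtype=float)
    if n_maj.size < min_snps:
        return float("nan")
    smaj, smin = n_maj.sum(), n_min.sum()
    tot = smaj + smin
    if tot == 0:
        return float("nan")
    return float(2.0 * smaj * smin / tot**2)


def z_transform(values) -> np.ndarray:
    """(x - mean)/sd over present (non-NaN) values, sd with ddof=1;
    NaN entries propagate."""
    x = np.asarray(values, dtype=float)
    present = ~np.isnan(x)
    if present.sum() < 2:
        raise ValueError("need at least 2 present values to Z-transform")
    sd = np.std(x[present], ddof=1)
    if sd == 0:
        raise ValueError("zero spread; Z-transform undefined")
    out = np.full_like(x, np.nan)
    out[present] = (x[present] - x[present].mean()) / sd
    return out


def wc_fst_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                      ) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for one SNP.

    ``n``: diploid sample size per population; ``p``: alt-allele
    frequency per population; ``h``: observed heterozygote fraction per
    population.  theta = a / (a + b + c).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = len(n)
    n_bar = n.mean()
    if n_bar <= 1:
        return (np.nan, np.nan, np.nan)
    n_c = (r * n_bar - np.sum(n**2) / (r * n_bar)) / (r - 1)
    p_bar = np.sum(n * p) / (r * n_bar)
    s2 = np.sum(n * (p - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = np.sum(n * h) / (r * n_bar)
    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    return float(a), float(b), float(c)


def _line_site_stats(gm: GenotypeMatrix, line: str):
    """Per-site (n diploids called, alt frequency, observed het fraction)."""
    g = gm.gt[:, gm.line_indices(line)]
    called = g != -1
    n = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=1) / (2.0 * np.maximum(n, 1))
        h = np.where(called, g == 1, False).sum(axis=1) / np.maximum(n, 1)
    return n.astype(float), p, h


def wc_fst_window(gm: GenotypeMatrix, window: tuple[str, int, int],
                  line_a: str, line_b: str, mode: str = "weighted"
                  ) -> float:
    """Window F_ST between two lines over the window's usable SNPs.

    SNPs monomorphic across both lines or with fewer than 2 called
    diploids in either line are skipped.  ``mode`` "weighted" is the
    ratio of summed components, "mean" the arithmetic mean of per-SNP
    estimates.  Returns NaN when no SNP is usable.
    """
    contig, start, end = window
    in_win = (gm.contig == contig) & (gm.pos - 1 >= start) & (gm.pos - 1 < end)
    sub = gm.take_sites(in_win)
    return _wc_fst_sites(sub, line_a, line_b, mode)


def _wc_components_sites(gm: GenotypeMatrix, line_a: str, line_b: str):
    """Vectorized per-site WC84 components; unusable sites get NaN.

    Usable sites have >= 2 called diploids in each line and are
    polymorphic across the pooled sample.
    """
    na, pa, ha = _line_site_stats(gm, line_a)
    nb, pb, hb = _line_site_stats(gm, line_b)
    usable = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_p = (na * pa + nb * pb) / np.maximum(na + nb, 1)
    usable &= (pooled_p > 0) & (pooled_p < 1)
    r = 2.0
    n_bar = (na + nb) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (na**2 + nb**2) / (r * n_bar)) / (r - 1)
        p_bar = (na * pa + nb * pb) / (r * n_bar)
        s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (na * ha + nb * hb) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c, usable


def _wc_fst_sites(gm: GenotypeMatrix, line_a: str, line_b: str,
                  mode: str = "weighted") -> float:
    if mode not in ("weighted", "mean"):
        raise ValueError("mode must be 'weighted' or 'mean'")
    if gm.n_sites == 0:
        return float("nan")
    a, b, c, usable = _wc_components_sites(gm, line_a, line_b)
    if not usable.any():
        return float("nan")
    a, b, c = a[usable], b[usable], c[usable]
    if mode == "weighted":
        denom = np.sum(a + b + c)
        return float(np.sum(a) / denom) if denom != 0 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    theta = theta[np.isfinite(theta)]
    return float(theta.mean()) if theta.size else float("nan")


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(1 - p), 0.0)
    return t1 + t2


def window_lrt(gm: GenotypeMatrix, window: tuple[str, int, int],
               line_a: str, line_b: str) -> tuple[float, int, float]:
    """Summed per-SNP binomial likelihood-ratio of allele counts between
    lines; returns (statistic, df = contributing SNPs, chi-square p).
    NaNs when the window holds no polymorphic SNP."""
    contig, start, end = window
    in_win = (gm.contig == contig) & (gm.pos - 1 >= start) & (gm.pos - 1 < end)
    sub = gm.take_sites(in_win)
    if sub.n_sites == 0:
        return (float("nan"), 0, float("nan"))
    alt_a, m_a = sub.allele_counts(line_a)
    alt_b, m_b = sub.allele_counts(line_b)
    tot_alt, tot_m = alt_a + alt_b, m_a + m_b
    poly = (tot_m > 0) & (tot_alt > 0) & (tot_alt < tot_m)
    if not poly.any():
        return (float("nan"), 0, float("nan"))
    alt_a, m_a = alt_a[poly], m_a[poly]
    alt_b, m_b = alt_b[poly], m_b[poly]
    p_a = alt_a / np.maximum(m_a, 1)
    p_b = alt_b / np.maximum(m_b, 1)
    p_0 = (alt_a + alt_b) / (m_a + m_b)
    ll1 = _binom_ll(alt_a, m_a, p_a) + _binom_ll(alt_b, m_b, p_b)
    ll0 = _binom_ll(alt_a, m_a, p_0) + _binom_ll(alt_b, m_b, p_0)
    stat = float(2.0 * np.sum(ll1 - ll0))
    df = int(poly.sum())
    return stat, df, float(stats.chi2.sf(stat, df))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def infer_contig_lengths(gm: GenotypeMatrix, step: int = 20_000) -> dict[str, int]:
    """Contig spans from observed positions, rounded up to the step grid."""
    out: dict[str, int] = {}
    for contig in pd.unique(gm.contig):
        m = int(gm.pos[gm.contig == contig].max())  # 1-based
        out[str(contig)] = int(np.ceil(m / step) * step)
    return out


def _window_slices(gm: GenotypeMatrix, win: pd.DataFrame):
    """Per-window site index ranges via searchsorted on per-contig
    positions (sites are position-sorted within contig)."""
    pos0 = gm.pos - 1
    by_contig = {}
    for contig in pd.unique(gm.contig):
        idx = np.nonzero(gm.contig == contig)[0]
        by_contig[str(contig)] = (idx, pos0[idx])
    slices = []
    for contig, start, end in win[["contig", "start", "end"]].itertuples(index=False):
        if contig not in by_contig:
            slices.append(np.zeros(0, dtype=int))
            continue
        idx, p = by_contig[contig]
        lo, hi = np.searchsorted(p, [start, end])
        slices.append(idx[lo:hi])
    return slices


def window_scan(gm: GenotypeMatrix, selected_line: str, other_line: str,
                contig_lengths: dict[str, int] | None = None,
                size: int = 40_000, step: int = 20_000, min_snps: int = 10,
                fst_mode: str = "weighted") -> pd.DataFrame:
    """Hp/ZHp (selected line) and window F_ST/ZF_ST for every window.

    Z-standardization runs over all windows passing the SNP-count rule.
    """
    if contig_lengths is None:
        contig_lengths = infer_contig_lengths(gm, step)
    win = make_windows(contig_lengths, size, step)
    alt_sel, m_sel = gm.allele_counts(selected_line)
    n_min_sel = np.minimum(alt_sel, m_sel - alt_sel)
    n_maj_sel = m_sel - n_min_sel
    a, b, c, usable = _wc_components_sites(gm, selected_line, other_line)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_site = np.where(usable & ((a + b + c) != 0), a / (a + b + c), np.nan)
    hp, fst, n_snps, smaj, smin = [], [], [], [], []
    for idx in _window_slices(gm, win):
        idx = idx[m_sel[idx] > 0] if idx.size else idx
        n_snps.append(len(idx))
        smaj.append(int(n_maj_sel[idx].sum()))
        smin.append(int(n_min_sel[idx].sum()))
        hp.append(pooled_heterozygosity(n_maj_sel[idx], n_min_sel[idx], min_snps))
        u = idx[usable[idx]] if idx.size else idx
        if len(idx) >= min_snps and u.size:
            if fst_mode == "weighted":
                denom = np.sum(a[u] + b[u] + c[u])
                fst.append(float(np.sum(a[u]) / denom) if denom != 0 else float("nan"))
            else:
                th = theta_site[u]
                th = th[np.isfinite(th)]
                fst.append(float(th.mean()) if th.size else float("nan"))
        else:
            fst.append(float("nan"))
    win["n_snps"] = n_snps
    win["sum_n_maj"] = smaj
    win["sum_n_min"] = smin
    win["hp"] = hp
    win["fst"] = fst
    win["zhp"] = z_transform(win["hp"])
    win["zfst"] = z_transform(win["fst"])
    return win


def lrt_scan(gm: GenotypeMatrix, line_a: str, line_b: str,
             contig_lengths: dict[str, int] | None = None,
             size: int = 5_000, step: int = 1_000) -> pd.DataFrame:
    """Binomial-LRT divergence test on the fine window grid, with BH q.

    The window statistic is a sum of per-SNP contributions, so the
    contributions are computed once and summed per window."""
    if contig_lengths is None:
        contig_lengths = infer_contig_lengths(gm, step)
    win = make_windows(contig_lengths, size, step)
    alt_a, m_a = gm.allele_counts(line_a)
    alt_b, m_b = gm.allele_counts(line_b)
    tot_alt, tot_m = alt_a + alt_b, m_a + m_b
    poly = (tot_m > 0) & (tot_alt > 0) & (tot_alt < tot_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = alt_a / np.maximum(m_a, 1)
        p_b = alt_b / np.maximum(m_b, 1)
        p_0 = tot_alt / np.maximum(tot_m, 1)
    ll1 = _binom_ll(alt_a, m_a, p_a) + _binom_ll(alt_b, m_b, p_b)
    ll0 = _binom_ll(alt_a, m_a, p_0) + _binom_ll(alt_b, m_b, p_0)
    per_site = np.where(poly, 2.0 * (ll1 - ll0), 0.0)
    stats_, dfs, ps = [], [], []
    for idx in _window_slices(gm, win):
        df = int(poly[idx].sum())
        if df == 0:
            stats_.append(float("nan"))
            dfs.append(0)
            ps.append(float("nan"))
            continue
        s = float(per_site[idx].sum())
        stats_.append(s)
        dfs.append(df)
        ps.append(float(stats.chi2.sf(s, df)))
    win["lrt_stat"] = stats_
    win["lrt_df"] = dfs
    win["p_value"] = ps
    q = np.full(len(win), np.nan)
    present = ~win["p_value"].isna()
    if present.any():
        q[present] = benjamini_hochberg(win.loc[present, "p_value"].to_numpy())
    win["q_value"] = q
    return win


def call_candidates(windows: pd.DataFrame, lrt_windows: pd.DataFrame | None = None,
                    zhp_max: float = -6.0, zfst_min: float = 1.1,
                    q_max: float = 0.05, step: int = 20_000) -> pd.DataFrame:
    """Flag windows passing all thresholds and merge runs into candidates.

    A window's divergence is "significant" when at least one overlapping
    fine-grid window has q < ``q_max`` (if no fine grid is supplied the
    criterion is skipped).  Flagged windows on one contig merge when
    within one step of each other.
    """
    flagged = ((windows["zhp"] < zhp_max) & (windows["zfst"] > zfst_min)).to_numpy()
    if lrt_windows is not None:
        for i in np.nonzero(flagged)[0]:
            row = windows.iloc[i]
            lw = lrt_windows[(lrt_windows["contig"] == row["contig"])
                             & (lrt_windows["start"] < row["end"])
                             & (lrt_windows["end"] > row["start"])]
            flagged[i] = bool((lw["q_value"] < q_max).any())
    f = windows[flagged].sort_values(["contig", "start"])
    rows = []
    cur = None
    for w in f.itertuples(index=False):
        if cur is not None and w.contig == cur["contig"] \
                and w.start <= cur["end"] + step:
            cur["end"] = max(cur["end"], w.end)
            cur["n_windows"] += 1
            cur["min_zhp"] = min(cur["min_zhp"], w.zhp)
            cur["max_zfst"] = max(cur["max_zfst"], w.zfst)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"contig": w.contig, "start": w.start, "end": w.end,
                   "n_windows": 1, "min_zhp": w.zhp, "max_zfst": w.zfst}
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_windows",
                                       "min_zhp", "max_zfst"])


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 as (contig, start0, end, gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"seqid": str})
    df = df[df["type"] == "gene"].copy()

    def gene_id(attrs: str) -> str:
        for fieldv in str(attrs).split(";"):
            k, _, v = fieldv.partition("=")
            if k.strip() in ("ID", "Name", "gene_id"):
                return v.strip()
        return str(attrs)

    return pd.DataFrame({
        "contig": df["seqid"].astype(str),
        "start": df["start"].astype(int) - 1,   # GFF is 1-based inclusive
        "end": df["end"].astype(int),
        "gene_id": df["attributes"].map(gene_id),
    }).reset_index(drop=True)


def annotate_candidates(candidates: pd.DataFrame, gff3_path) -> pd.DataFrame:
    """Attach overlapping genes (distance 0) or the nearest up/downstream
    gene with signed distances; candidates on contigs absent from the
    annotation get "no annotation"."""
    genes = read_gff3_genes(gff3_path)
    out = candidates.copy()
    ann = []
    for cand in candidates.itertuples(index=False):
        g = genes[genes["contig"] == cand.contig]
        if g.empty:
            warnings.warn(f"contig {cand.contig} absent from annotation")
            ann.append("no annotation")
            continue
        overlap = g[(g["start"] < cand.end) & (g["end"] > cand.start)]
        if not overlap.empty:
            ann.append(";".join(f"{r.gene_id}:0"
                                for r in overlap.itertuples(index=False)))
            continue
        entries = []
        up = g[g["end"] <= cand.start]
        if not up.empty:
            r = up.loc[up["end"].idxmax()]
            entries.append(f"{r.gene_id}:{int(r.end - cand.start)}")
        down = g[g["start"] >= cand.end]
        if not down.empty:
            r = down.loc[down["start"].idxmin()]
            entries.append(f"{r.gene_id}:+{int(r.start - cand.end)}")
        ann.append(";".join(entries) if entries else "no annotation")
    out["genes"] = ann
    return out
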