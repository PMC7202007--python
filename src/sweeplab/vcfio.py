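"""VCF input and the variant filters applied before population analysis.

A site survives filtering iff, in order: per-genotype depths pass
``min_depth <= DP <= max_depth_factor * mean genome-wide depth`` (failing
genotypes are set missing first), the fraction of non-missing genotypes is
at least ``min_call_fraction``, the record is biallelic, and the pooled
minor-allele frequency over remaining calls is strictly greater than
``min_maf``.  Thinning keeps one SNP per ``thin_gap_bp`` greedily from the
left.  VCF positions are 1-based; windowed analyses elsewhere use 0-based
half-open coordinates, and the conversion happens only at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from cyvcf2 import VCF

__all__ = [
    "GenotypeMatrix",
    "FilterConfig",
    "read_vcf",
    "read_line_map",
    "apply_filters",
    "thin",
]

MISSING = -1


class VcfParseError(ValueError):
    pass


class LineMapError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls (alt-allele counts) with depths and line labels."""

    contig: np.ndarray            # (n_sites,) str
    pos: np.ndarray               # (n_sites,) int, 1-based
    ref: list[str]
    alt: list[list[str]]          # per-site alt allele list (>=1 pre-filter)
    gt: np.ndarray                # (n_sites, n_ind) int8, -1 missing
    dp: np.ndarray | None         # (n_sites, n_ind) int32, -1 missing
    samples: list[str]
    line_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if self.dp is not None and self.dp.shape != self.gt.shape:
            raise ValueError("depth matrix shape mismatch")
        missing = [s for s in self.samples if s not in self.line_of]
        if missing:
            raise LineMapError(f"samples missing from line map: {missing}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def lines(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            lab = self.line_of[s]
            if lab not in seen:
                seen.append(lab)
        return seen

    def line_indices(self, line: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.line_of[s] == line]
        if not idx:
            raise KeyError(f"no samples belong to line {line!r}")
        return np.asarray(idx)

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return GenotypeMatrix(
            contig=self.contig[idx], pos=self.pos[idx],
            ref=[self.ref[i] for i in idx], alt=[self.alt[i] for i in idx],
            gt=self.gt[idx], dp=None if self.dp is None else self.dp[idx],
            samples=self.samples, line_of=dict(self.line_of))

    def allele_counts(self, line: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called chromosome count) per site, pooled or
        restricted to one line."""
        g = self.gt if line is None else self.gt[:, self.line_indices(line)]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=1)
        return alt.astype(np.int64), 2 * called.sum(axis=1).astype(np.int64)


def read_line_map(path) -> dict[str, str]:
    """Two-column TSV (sample, line) -> dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) != 2:
                raise LineMapError(f"expected two tab-separated columns: {raw!r}")
            out[parts[0]] = parts[1]
    return out


def read_vcf(path, line_map: dict[str, str] | str) -> GenotypeMatrix:
    """Read a VCF 4.x with GT (DP optional) into a GenotypeMatrix.

    Multiallelic records are retained with their full alt-allele list so
    that the biallelic filter can act on them; the genotype code is the
    count of non-reference alleles.  Half-missing calls are treated as
    missing.
    """
    if isinstance(line_map, (str, bytes)) or hasattr(line_map, "__fspath__"):
        line_map = read_line_map(line_map)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"could not open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in line_map]
    if absent:
        raise LineMapError(f"VCF samples absent from line map: {absent}")
    contigs, pos, ref, alt, gts, dps = [], [], [], [], [], []
    has_dp = False
    for i, var in enumerate(vcf, 1):
        try:
            contigs.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(list(var.ALT))
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for j, call in enumerate(var.genotypes):
                a = call[:-1]
                if len(a) >= 2 and a[0] >= 0 and a[1] >= 0:
                    row[j] = int(a[0] > 0) + int(a[1] > 0)
            gts.append(row)
            d = var.format("DP")
            if d is not None:
                has_dp = True
                drow = d.reshape(-1).astype(np.int32)
                drow[drow < 0] = MISSING
                dps.append(drow)
            else:
                dps.append(np.full(len(samples), MISSING, dtype=np.int32))
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    n = len(pos)
    return GenotypeMatrix(
        contig=np.asarray(contigs, dtype=object), pos=np.asarray(pos, dtype=np.int64),
        ref=ref, alt=alt,
        gt=(np.vstack(gts) if n else np.zeros((0, len(samples)), dtype=np.int8)),
        dp=(np.vstack(dps) if (n and has_dp) else None),
        samples=samples, line_of=dict(line_map))


@dataclass
class FilterConfig:
    min_call_fraction: float = 0.5
    min_depth: int = 5
    max_depth_factor: float = 2.5
    min_maf: float = 0.1
    biallelic_only: bool = True
    thin_gap_bp: int = 5000

    def __post_init__(self) -> None:
        if not 0 < self.min_call_fraction <= 1:
            raise ValueError("min_call_fraction must be in (0, 1]")
        if self.min_depth < 0 or self.max_depth_factor < 0:
            raise ValueError("depth thresholds must be non-negative")
        if self.thin_gap_bp < 0:
            raise ValueError("thin_gap_bp must be non-negative")


def apply_filters(gm: GenotypeMatrix, cfg: FilterConfig | None = None,
                  mean_depth: float | None = None
                  ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the variant filters; returns the filtered matrix and removal
    counts keyed "depth_masked_genotypes", "call_fraction", "biallelic",
    "maf" (applied in that order).

    ``mean_depth`` pins the mean genome-wide coverage used for the upper
    depth bound; by default it is the mean of all non-missing DP values in
    the input.  Passing the same value on a second application makes the
    filter idempotent.
    """
    cfg = cfg or FilterConfig()
    if gm.n_sites == 0:
        raise ValueError("cannot filter an empty genotype matrix")
    counts = {"depth_masked_genotypes": 0, "call_fraction": 0,
              "biallelic": 0, "maf": 0}
    gt = gm.gt.copy()
    if gm.dp is not None:
        if mean_depth is None:
            observed = gm.dp[gm.dp != MISSING]
            mean_depth = float(observed.mean()) if observed.size else 0.0
        hi = cfg.max_depth_factor * mean_depth
        bad = (gm.dp != MISSING) & ((gm.dp < cfg.min_depth) | (gm.dp > hi))
        bad &= gt != MISSING
        counts["depth_masked_genotypes"] = int(bad.sum())
        gt = np.where(bad, MISSING, gt)

    called_frac = (gt != MISSING).mean(axis=1)
    keep = called_frac >= cfg.min_call_fraction
    counts["call_fraction"] = int((~keep).sum())

    if cfg.biallelic_only:
        biall = np.array([len(a) == 1 for a in gm.alt])
        counts["biallelic"] = int((keep & ~biall).sum())
        keep &= biall

    called = gt != MISSING
    alt = np.where(called, gt, 0).sum(axis=1)
    chroms = 2 * called.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(chroms > 0, alt / np.maximum(chroms, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    pass_maf = maf > cfg.min_maf
    counts["maf"] = int((keep & ~pass_maf).sum())
    keep &= pass_maf

    out = replace(gm, gt=gt, dp=gm.dp)
    out = out.take_sites(keep)
    return out, counts


def thin(gm: GenotypeMatrix, gap_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right thinning to one site per ``gap_bp`` per contig."""
    if gap_bp <= 0:
        return gm.take_sites(np.arange(gm.n_sites))
    keep = np.zeros(gm.n_sites, dtype=bool)
    last: dict[str, int] = {}
    for i in range(gm.n_sites):
        c, p = gm.contig[i], int(gm.pos[i])
        if c not in last or p - last[c] >= gap_bp:
            keep[i] = True
            last[c] = p
    return gm.take_sites(keep)
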