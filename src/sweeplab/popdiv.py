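"""Genome-wide within-line diversity summaries with BCa bootstrap CIs.

Implements the per-line statistics of the diversity table: proportion of
polymorphic sites (P_N), mean minor-allele frequency, observed and
expected heterozygosity (the latter with Nei's small-sample correction
2n/(2n-1)), the inbreeding coefficient F_IS = 1 - mean(H_O)/mean(H_E)
(means over sites taken before the ratio), and the mean Nei (1972)
standard genetic distance between individuals of a line, each individual
treated as a two-allele population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .vcfio import MISSING, GenotypeMatrix

__all__ = [
    "DiversitySummary",
    "diversity_summary",
    "nei_within",
    "bca_ci",
    "STATISTICS",
]

#: cap for pairwise Nei distances whose between-individual identity is zero
NEI_DISTANCE_CAP = 10.0


@dataclass
class DiversitySummary:
    line: str
    n_individuals: int
    n_sites: int
    p_n: float
    maf_mean: float
    h_o: float
    h_e: float
    f_is: float


def _line_gt(gm: GenotypeMatrix, line: str) -> np.ndarray:
    idx = gm.line_indices(line)
    if len(idx) < 2:
        raise ValueError(f"line {line!r} needs at least 2 individuals")
    return gm.gt[:, idx]


def _site_components(g: np.ndarray):
    """Per-site pieces used by the summary statistics.

    Returns (mask of sites with >=1 call, alt frequency p, observed-het
    fraction, corrected expected het) over sites with calls."""
    called = g != MISSING
    n_called = called.sum(axis=1)
    ok = n_called > 0
    g, called, n_called = g[ok], called[ok], n_called[ok]
    alt = np.where(called, g, 0).sum(axis=1)
    p = alt / (2.0 * n_called)
    h_o = np.where(called, g == 1, False).sum(axis=1) / n_called
    two_n = 2.0 * n_called
    with np.errstate(invalid="ignore"):
        h_e = 2.0 * p * (1 - p) * np.where(two_n > 1, two_n / (two_n - 1), np.nan)
    return ok, p, h_o, h_e


def diversity_summary(gm: GenotypeMatrix, line: str) -> DiversitySummary:
    """Summary over sites with at least one called genotype in the line.

    A monomorphic line yields H_E = 0 and an undefined (NaN) F_IS.
    """
    g = _line_gt(gm, line)
    ok, p, h_o, h_e = _site_components(g)
    if not ok.any():
        raise ValueError(f"no called sites for line {line!r}")
    p_n = float(np.mean((p > 0) & (p < 1)))
    maf = np.minimum(p, 1 - p)
    mean_ho = float(h_o.mean())
    mean_he = float(h_e.mean())
    f_is = 1.0 - mean_ho / mean_he if mean_he > 0 else float("nan")
    return DiversitySummary(
        line=line, n_individuals=g.shape[1], n_sites=int(ok.sum()),
        p_n=p_n, maf_mean=float(maf.mean()),
        h_o=mean_ho, h_e=mean_he, f_is=f_is)


def _nei_pair(gi: np.ndarray, gj: np.ndarray) -> float | None:
    """Nei 1972 D between two individuals over shared called sites."""
    ok = (gi != MISSING) & (gj != MISSING)
    if not ok.any():
        return None
    x = gi[ok] / 2.0   # alt-allele dose as within-"population" frequency
    y = gj[ok] / 2.0
    jx = float(np.mean(x**2 + (1 - x) ** 2))
    jy = float(np.mean(y**2 + (1 - y) ** 2))
    jxy = float(np.mean(x * y + (1 - x) * (1 - y)))
    if jxy <= 0:
        return NEI_DISTANCE_CAP
    return float(min(-np.log(jxy / np.sqrt(jx * jy)), NEI_DISTANCE_CAP))


def nei_within(gm: GenotypeMatrix, line: str) -> float:
    """Mean pairwise Nei (1972) distance among individuals of a line."""
    g = _line_gt(gm, line)
    n = g.shape[1]
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _nei_pair(g[:, i], g[:, j])
            if d is None:
                warnings.warn(f"individual pair ({i},{j}) shares no called "
                              "sites; skipped")
                continue
            dists.append(d)
    if not dists:
        raise ValueError("no individual pair shares called sites")
    return float(np.mean(dists))


def _stat_over_sites(gm: GenotypeMatrix, line: str, name: str):
    """Return f(site_indices) recomputing the named statistic on a site
    resample, the resampling unit being the locus."""
    def f(indices: np.ndarray) -> float:
        sub = gm.take_sites(np.asarray(indices, dtype=int))
        if name == "d_within":
            return nei_within(sub, line)
        s = diversity_summary(sub, line)
        return getattr(s, name)
    return f


STATISTICS = ("p_n", "maf_mean", "h_o", "h_e", "f_is", "d_within")


def bca_ci(gm: GenotypeMatrix, line: str, statistic: str,
           n_boot: int = 1000, seed=None,
           confidence_level: float = 0.95) -> tuple[float, float]:
    """BCa bootstrap CI for a per-line statistic, resampling loci.

    Bias correction comes from the bootstrap fraction below the point
    estimate and acceleration from a jackknife over sites (both via
    scipy's BCa implementation).  A degenerate bootstrap distribution
    collapses the interval to the point estimate with a warning.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    f = _stat_over_sites(gm, line, statistic)
    indices = np.arange(gm.n_sites)
    point = f(indices)
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.bootstrap(
                (indices,), f, n_resamples=n_boot, method="BCa",
                confidence_level=confidence_level, vectorized=False, rng=rng)
        except Exception:
            warnings.simplefilter("default")
            warnings.warn("degenerate bootstrap distribution; interval "
                          "collapsed to the point estimate")
            return (point, point)
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not np.isfinite(lo) or not np.isfinite(hi):
        warnings.warn("degenerate bootstrap distribution; interval collapsed "
                      "to the point estimate")
        return (point, point)
    return lo, hi
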