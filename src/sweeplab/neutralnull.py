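"""Monte-Carlo neutral null for the 40-kb window F_ST.

Each replicate simulates the full two-line breeding demography without
selection over a single 40-kb window, samples 5 diploids per line, applies
the same pooled MAF > 0.1 site filter as the genome scan, and computes the
weighted Weir-Cockerham window F_ST.  The tail probability is the fraction
of replicates at or above the observed threshold, reported with an exact
binomial 95% CI; the sensitivity suite repeats this for reduced founder
collections and reduced per-generation census sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import simkit
from .simkit import LineScenario, ScenarioError, SimulatedSample

__all__ = ["NullResult", "window_fst_of_sample", "fst_null", "sensitivity_suite"]


@dataclass
class NullResult:
    scenario_tag: str
    threshold: float
    n_reps: int
    n_exceed: int
    tail_probability: float
    ci_lower: float
    ci_upper: float
    fst_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_exceed <= self.n_reps:
            raise ValueError("n_exceed out of range")


def window_fst_of_sample(sample: SimulatedSample, min_maf: float = 0.1,
                         mode: str = "weighted") -> float:
    """Weighted WC84 window F_ST between the two sampled lines, over sites
    with pooled MAF strictly above ``min_maf`` (the scan's site filter)."""
    hap = sample.haplotypes
    if hap.shape[1] == 0:
        return float("nan")
    labels = np.asarray(sample.line_labels)
    lines = sample.lines
    if len(lines) != 2:
        raise ValueError("expected exactly two lines in the sample")
    freq = hap.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf > min_maf
    if not keep.any():
        return float("nan")
    comps = []
    for line in lines:
        rows = hap[labels == line][:, keep]
        n_dip = rows.shape[0] // 2
        p = rows.mean(axis=0)
        het = (rows[0::2] != rows[1::2]).mean(axis=0)
        comps.append((n_dip, p, het))
    (na, pa, ha), (nb, pb, hb) = comps
    # vectorized WC84 components with r = 2 populations and scalar sizes
    r = 2.0
    n_bar = (na + nb) / r
    n_c = (r * n_bar - (na**2 + nb**2) / (r * n_bar)) / (r - 1)
    p_bar = (na * pa + nb * pb) / (r * n_bar)
    s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (na * ha + nb * hb) / (r * n_bar)
    inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
    a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2.0
    if mode == "weighted":
        denom = np.sum(a + b + c)
        return float(np.sum(a) / denom) if denom != 0 else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    theta = theta[np.isfinite(theta)]
    return float(theta.mean()) if theta.size else float("nan")


def fst_null(scenario: LineScenario, n_reps: int = 10_000,
             threshold: float = 0.44, seed=0, min_maf: float = 0.1,
             scenario_tag: str | None = None) -> NullResult:
    """Distribution of the neutral window F_ST under the demography.

    Replicates with no site surviving the MAF filter contribute F_ST = NaN
    and never count as exceedances.
    """
    if scenario.selection_episodes:
        raise ScenarioError("the neutral null requires a scenario without "
                            "selection episodes")
    ss = np.random.SeedSequence(int(seed)) if not isinstance(
        seed, np.random.SeedSequence) else seed
    children = ss.spawn(n_reps)
    fst = np.empty(n_reps)
    for i, child in enumerate(children):
        sample = simkit.simulate_two_lines(scenario, child)
        fst[i] = window_fst_of_sample(sample, min_maf=min_maf)
    n_exceed = int(np.nansum(fst >= threshold))
    tail = n_exceed / n_reps
    ci = stats.binomtest(n_exceed, n_reps).proportion_ci(
        confidence_level=0.95, method="exact")
    tag = scenario_tag or (f"founders={scenario.n_founders},"
                           f"census={scenario.census_size}")
    return NullResult(scenario_tag=tag, threshold=threshold, n_reps=n_reps,
                      n_exceed=n_exceed, tail_probability=tail,
                      ci_lower=float(ci.low), ci_upper=float(ci.high),
                      fst_values=fst)


def sensitivity_suite(base: LineScenario, n_reps: int = 10_000, seed=0,
                      threshold: float = 0.44,
                      founder_sizes: tuple[int, ...] = (180, 90, 45),
                      census_scales: tuple[float, ...] = (0.5, 0.25)
                      ) -> list[NullResult]:
    """The demographic sensitivity grid: reduced founder collections at
    full census, then reduced census at the full founder collection."""
    if base.selection_episodes:
        raise ScenarioError("the sensitivity suite requires a neutral base "
                            "scenario")
    ss = np.random.SeedSequence(int(seed))
    variants: list[tuple[str, LineScenario]] = []
    for nf in founder_sizes:
        variants.append((f"founders={nf},census={base.census_size}",
                         base.replace(n_founders=nf)))
    for scale in census_scales:
        census = max(int(round(base.census_size * scale)), 2)
        variants.append((f"founders={base.n_founders},census={census}",
                         base.replace(census_size=census)))
    out = []
    for child, (tag, scen) in zip(ss.spawn(len(variants)), variants):
        out.append(fst_null(scen, n_reps=n_reps, threshold=threshold,
                            seed=child, scenario_tag=tag))
    return out
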