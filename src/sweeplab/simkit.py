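"""Forward Wright-Fisher simulator of a two-line laboratory breeding program.

The model mirrors a selection experiment in which a field collection of
``n_founders`` diploid individuals founds an unselected line (reared at a
fixed census size), a selected line is split off after a couple of
generations, episodic viability selection is applied to the selected line
at a single target locus, and the selected line is re-founded mid-course by
a backcross to the unselected line.  Standing variation in the founders is
generated under a neutral coalescent (msprime) over a single window;
no new mutation arises during breeding.

Internally each chromosome carries a founder-haplotype *label* rather than
a sequence.  Recombinant gametes receive fresh labels that reference their
two parental labels plus crossover breakpoints, and labels are resolved to
0/1 haplotype arrays only for the sampled individuals.  This is an exact
implementation of the Wright-Fisher model with per-bp recombination, not an
approximation: per generation only integer label arrays are copied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np

from .seqdiv import AlignmentSet

__all__ = [
    "LineScenario",
    "SimulatedSample",
    "generate_founder_haplotypes",
    "simulate_two_lines",
    "selection_schedule",
    "emit_vcf",
    "emit_genome_vcf",
    "sample_names",
    "emit_amplicon_alignment",
]

#: line labels used throughout the package
UNSELECTED = "GA"
SELECTED = "GA-R"


class ScenarioError(ValueError):
    """Raised for inconsistent scenario parameters."""


@dataclass
class LineScenario:
    """Demography of the two-line breeding program.

    Generations live on a single shared clock starting at the founding
    collection (generation 0).  The unselected line runs for
    ``n_generations_unsel`` generations; the selected line is founded from
    it at ``split_generation`` and runs for ``n_generations_sel``
    generations of its own, i.e. it is sampled at shared-clock generation
    ``split_generation + n_generations_sel``.  ``backcross_generation`` and
    the generations in ``selection_episodes`` are shared-clock indices.
    """

    n_founders: int = 180
    census_size: int = 600
    n_generations_sel: int = 52
    n_generations_unsel: int = 72
    split_generation: int = 2
    backcross_generation: int | None = 27
    #: (shared-clock generation, selection coefficient s, dominance h)
    selection_episodes: list[tuple[int, float, float]] = field(default_factory=list)
    target_locus_pos: int = 20_000
    window_length: int = 40_000
    theta_per_window: float = 120.0
    #: population-scaled recombination rate (4 N_wild r L) of the founder
    #: standing variation across the window; wild insect populations are
    #: large, so founder haplotypes are fine-scale mosaics
    founder_rho: float = 400.0
    recomb_rate: float = 3e-8
    sample_size: int = 5
    #: founder frequency band from which the selected (alt) allele is drawn;
    #: the default targets rare standing variation (2-3 copies among 360
    #: founder chromosomes), the regime that produces a hard sweep
    target_freq_range: tuple[float, float] = (0.002, 0.008)

    @property
    def terminal_generation_sel(self) -> int:
        return self.split_generation + self.n_generations_sel

    def __post_init__(self) -> None:
        for name in ("n_founders", "census_size", "n_generations_sel",
                     "n_generations_unsel", "sample_size", "window_length"):
            if getattr(self, name) < 1:
                raise ScenarioError(f"{name} must be >= 1")
        if self.theta_per_window < 0:
            raise ScenarioError("theta_per_window must be non-negative")
        if self.recomb_rate < 0:
            raise ScenarioError("recomb_rate must be non-negative")
        if not 0 <= self.target_locus_pos < self.window_length:
            raise ScenarioError("target_locus_pos must lie in [0, window_length)")
        terminal = min(self.terminal_generation_sel, self.n_generations_unsel)
        if self.split_generation < 1:
            raise ScenarioError("split_generation must be >= 1")
        if self.backcross_generation is not None and not (
                self.split_generation < self.backcross_generation < terminal):
            raise ScenarioError(
                "require split_generation < backcross_generation < terminal generation")
        for gen, s, h in self.selection_episodes:
            if s < 0:
                raise ScenarioError("selection coefficient s must be >= 0")
            if not 0 <= h <= 1:
                raise ScenarioError("dominance h must be in [0, 1]")
            if not self.split_generation < gen <= self.terminal_generation_sel:
                raise ScenarioError(
                    f"selection episode at generation {gen} is outside the "
                    f"selected line's lifetime ({self.split_generation}, "
                    f"{self.terminal_generation_sel}]")
        if self.sample_size > self.census_size:
            raise ScenarioError("sample_size cannot exceed census_size")

    def replace(self, **kw) -> "LineScenario":
        return dataclasses.replace(self, **kw)


def selection_schedule(scenario: LineScenario, s: float, h: float = 0.5,
                       n_pre: int = 19, n_post: int = 32) -> list[tuple[int, float, float]]:
    """Episode schedule emulating the experiment's selection history.

    ``n_pre`` episodes are spread evenly between the line split and the
    backcross, ``n_post`` between the backcross and sampling (defaults: the
    9 + 10 pre-backcross and 7 + 25 post-backcross episodes of the
    experiment).  When the requested count exceeds the generations
    available the episodes collapse onto every available generation.
    """
    if scenario.backcross_generation is None:
        lo, hi = scenario.split_generation + 1, scenario.terminal_generation_sel
        gens = np.unique(np.linspace(lo, hi, min(n_pre + n_post, hi - lo + 1)).round().astype(int))
        return [(int(g), s, h) for g in gens]
    bc = scenario.backcross_generation
    pre_lo, pre_hi = scenario.split_generation + 1, bc - 1
    post_lo, post_hi = bc + 1, scenario.terminal_generation_sel
    pre = np.unique(np.linspace(pre_lo, pre_hi, min(n_pre, pre_hi - pre_lo + 1)).round().astype(int))
    post = np.unique(np.linspace(post_lo, post_hi, min(n_post, post_hi - post_lo + 1)).round().astype(int))
    return [(int(g), s, h) for g in np.concatenate([pre, post])]


@dataclass
class SimulatedSample:
    """Sampled diploids from both lines at their terminal generations."""

    haplotypes: np.ndarray          # (2 * sample_size * 2 lines, S) of 0/1
    positions: np.ndarray           # bp, 0-based within the window, increasing
    line_labels: list[str]          # one entry per chromosome row
    target_allele_freq_by_line: dict[str, float]
    target_site_pos: int | None = None

    def __post_init__(self) -> None:
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype columns must match positions")
        if len(self.line_labels) != self.haplotypes.shape[0]:
            raise ValueError("one line label per chromosome row required")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def lines(self) -> list[str]:
        seen: list[str] = []
        for lab in self.line_labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def diploid_genotypes(self) -> tuple[np.ndarray, list[str]]:
        """Collapse consecutive haplotype pairs into alt-allele counts.

        Returns (genotypes with shape (S, n_individuals), per-individual
        line labels)."""
        h = self.haplotypes
        gt = (h[0::2] + h[1::2]).T.astype(np.int8)
        return gt, self.line_labels[0::2]


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def _msprime_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 2) + 1)


def generate_founder_haplotypes(scenario: LineScenario, seed) -> tuple[np.ndarray, np.ndarray]:
    """Neutral-coalescent standing variation for the founder collection.

    Returns ``(haplotypes, positions)`` with one row per founder chromosome
    (2 x n_founders) and one column per segregating site under an
    infinite-sites model with intra-window recombination at the
    population-scaled rate ``founder_rho`` (standing variation from a large
    wild source population is a fine-scale mosaic; ``founder_rho = 0``
    recovers a single window-wide genealogy).  The expected number of
    sites is ``theta_per_window * a1(2 n_founders)`` with
    ``a1(n) = sum_{i<n} 1/i``.  ``theta_per_window = 0`` is the documented
    no-variation limit (zero sites); negative values are an error.
    """
    if scenario.theta_per_window < 0:
        raise ScenarioError("theta_per_window must be non-negative")
    ss = _seed_sequence(seed)
    n_chrom = 2 * scenario.n_founders
    L = float(scenario.window_length)
    if scenario.theta_per_window == 0:
        return (np.zeros((n_chrom, 0), dtype=np.uint8),
                np.zeros(0, dtype=np.int64))
    anc_seed, mut_seed = (_msprime_seed(c) for c in ss.spawn(2))
    # haploid samples with population_size 1 put the pairwise coalescence
    # rate at 1/generation, so E[S] = (rate * L) * 2 a1 = theta * a1
    ts = msprime.sim_ancestry(
        samples=n_chrom, ploidy=1, population_size=1.0,
        sequence_length=L, discrete_genome=False,
        recombination_rate=scenario.founder_rho / (2.0 * L),
        random_seed=anc_seed)
    ts = msprime.sim_mutations(
        ts, rate=scenario.theta_per_window / (2.0 * L),
        model=msprime.BinaryMutationModel(), discrete_genome=False,
        random_seed=mut_seed)
    hap = ts.genotype_matrix().T.astype(np.uint8)  # (n_chrom, S)
    raw_pos = np.array([s.position for s in ts.sites()])
    # map continuous positions onto unique integer bp, preserving order
    pos = np.floor(raw_pos).astype(np.int64)
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    keep = pos < scenario.window_length
    return np.ascontiguousarray(hap[:, keep]), pos[keep]


class _LabelSpace:
    """Founder and recombinant haplotype labels for one simulated window."""

    def __init__(self, founders: np.ndarray, positions: np.ndarray,
                 target_site: int | None, span: float = 1.0):
        self.founders = founders
        self.positions = positions
        self.span = float(span)
        self.n_founder_labels = founders.shape[0]
        self.target_site = target_site
        # recombinant label k (k >= n_founder_labels) -> (labA, labB, breakpoints)
        self.recombinants: list[tuple[int, int, np.ndarray]] = []
        if target_site is not None:
            self.target_allele = list(founders[:, target_site].astype(int))
        else:
            self.target_allele = None
        self._cache: dict[int, np.ndarray] = {}

    def new_recombinant(self, lab_a: int, lab_b: int, breakpoints: np.ndarray) -> int:
        label = self.n_founder_labels + len(self.recombinants)
        self.recombinants.append((lab_a, lab_b, breakpoints))
        if self.target_allele is not None:
            pos = self.positions[self.target_site]
            parity = np.searchsorted(breakpoints, pos, side="right") % 2
            src = lab_a if parity == 0 else lab_b
            self.target_allele.append(self.target_allele[src])
        return label

    def target_alleles_of(self, labels: np.ndarray) -> np.ndarray:
        arr = np.asarray(self.target_allele)
        return arr[labels]

    def resolve(self, label: int) -> np.ndarray:
        if label < self.n_founder_labels:
            return self.founders[label]
        if label in self._cache:
            return self._cache[label]
        lab_a, lab_b, bps = self.recombinants[label - self.n_founder_labels]
        ha, hb = self.resolve(lab_a), self.resolve(lab_b)
        parity = np.searchsorted(bps, self.positions, side="right") % 2
        out = np.where(parity == 0, ha, hb).astype(np.uint8)
        self._cache[label] = out
        return out


def _gametes(space: _LabelSpace, pop: np.ndarray, parents: np.ndarray,
             rng: np.random.Generator, xover_mean: float) -> np.ndarray:
    """One gamete label per entry of ``parents`` (1-D parent indices)."""
    n = parents.shape[0]
    hap_choice = rng.integers(0, 2, size=n)
    out = pop[parents, hap_choice].copy()
    if xover_mean > 0:
        n_x = rng.poisson(xover_mean, size=n)
        for i in np.nonzero(n_x)[0]:
            p = parents[i]
            lab_a, lab_b = pop[p, hap_choice[i]], pop[p, 1 - hap_choice[i]]
            if lab_a == lab_b:
                continue
            bps = np.sort(rng.uniform(0.0, space.span, n_x[i]))
            out[i] = space.new_recombinant(int(lab_a), int(lab_b), bps)
    return out


def _reproduce(space: _LabelSpace, pop: np.ndarray, n_offspring: int,
               rng: np.random.Generator, xover_mean: float,
               fitness: np.ndarray | None = None) -> np.ndarray:
    n_parents = pop.shape[0]
    if fitness is None:
        parents = rng.integers(0, n_parents, size=2 * n_offspring)
    else:
        parents = rng.choice(n_parents, size=2 * n_offspring,
                             p=fitness / fitness.sum())
    gam = _gametes(space, pop, parents, rng, xover_mean)
    return gam.reshape(n_offspring, 2)


def _fitness(space: _LabelSpace, pop: np.ndarray, s: float, h: float) -> np.ndarray:
    g = space.target_alleles_of(pop[:, 0]) + space.target_alleles_of(pop[:, 1])
    return 1.0 + s * (h * (g == 1) + (g == 2))


def _pick_target_site(founders: np.ndarray, positions: np.ndarray,
                      scenario: LineScenario) -> int | None:
    if founders.shape[1] == 0:
        return None
    freq = founders.mean(axis=0)
    lo, hi = scenario.target_freq_range
    eligible = np.nonzero((freq >= lo) & (freq <= hi))[0]
    if eligible.size == 0:
        eligible = np.arange(founders.shape[1])
    dist = np.abs(positions[eligible] - scenario.target_locus_pos)
    return int(eligible[np.argmin(dist)])


def simulate_two_lines(scenario: LineScenario, seed,
                       founders: tuple[np.ndarray, np.ndarray] | None = None,
                       keep_monomorphic: bool = False) -> SimulatedSample:
    """Run the two-line breeding program and sample diploids from each line.

    Reproduction is Wright-Fisher with random mating (selfing allowed)
    within each line; selection episodes weight the selected line's parents
    by viability 1, 1+hs, 1+s for 0/1/2 copies of the selected allele; at
    the backcross generation every selected-line offspring receives one
    gamete from a selected-line parent and one from a contemporaneous
    unselected-line parent.  ``founders`` may inject an explicit founder
    haplotype pool ``(haplotypes, positions)`` in place of the coalescent.
    """
    ss = _seed_sequence(seed)
    founder_ss, wf_ss = ss.spawn(2)
    if founders is None:
        founder_h, positions = generate_founder_haplotypes(scenario, founder_ss)
    else:
        founder_h = np.asarray(founders[0], dtype=np.uint8)
        positions = np.asarray(founders[1], dtype=np.int64)
    if founder_h.shape[0] != 2 * scenario.n_founders:
        raise ScenarioError("founder pool must contain 2 * n_founders haplotypes")
    rng = np.random.default_rng(wf_ss)

    target_site = _pick_target_site(founder_h, positions, scenario)
    space = _LabelSpace(founder_h, positions, target_site,
                        span=scenario.window_length)
    xover = scenario.recomb_rate * scenario.window_length

    episodes = {g: (s, h) for g, s, h in scenario.selection_episodes}
    N = scenario.census_size
    split = scenario.split_generation
    terminal_sel = scenario.terminal_generation_sel

    unsel = np.arange(2 * scenario.n_founders).reshape(scenario.n_founders, 2)
    sel: np.ndarray | None = None
    sel_final: np.ndarray | None = None
    for g in range(1, scenario.n_generations_unsel + 1):
        unsel_prev = unsel
        unsel = _reproduce(space, unsel_prev, N, rng, xover)
        if g == split:
            sel = _reproduce(space, unsel_prev, N, rng, xover)
        elif sel is not None and g <= terminal_sel:
            if g == scenario.backcross_generation:
                # 50:50 re-founding cross: one gamete from each line
                p_sel = rng.integers(0, sel.shape[0], size=N)
                p_uns = rng.integers(0, unsel_prev.shape[0], size=N)
                gam_s = _gametes(space, sel, p_sel, rng, xover)
                gam_u = _gametes(space, unsel_prev, p_uns, rng, xover)
                sel = np.stack([gam_s, gam_u], axis=1)
            else:
                fit = None
                if g in episodes and target_site is not None:
                    s, h = episodes[g]
                    fit = _fitness(space, sel, s, h)
                sel = _reproduce(space, sel, N, rng, xover, fitness=fit)
        if g == terminal_sel:
            sel_final = sel
    if sel_final is None:
        raise ScenarioError("selected line never reached its terminal generation")

    freqs: dict[str, float] = {}
    if target_site is not None:
        for name, pop in ((UNSELECTED, unsel), (SELECTED, sel_final)):
            alle = space.target_alleles_of(pop.ravel())
            freqs[name] = float(alle.mean())
    else:
        freqs = {UNSELECTED: float("nan"), SELECTED: float("nan")}

    rows: list[np.ndarray] = []
    labels: list[str] = []
    for name, pop in ((UNSELECTED, unsel), (SELECTED, sel_final)):
        idx = rng.choice(pop.shape[0], size=scenario.sample_size, replace=False)
        for i in idx:
            for hap in (0, 1):
                rows.append(space.resolve(int(pop[i, hap])))
                labels.append(name)
    hap = (np.vstack(rows) if rows and founder_h.shape[1] else
           np.zeros((len(rows), founder_h.shape[1]), dtype=np.uint8))
    pos = positions
    tpos = None if target_site is None else int(positions[target_site])
    if not keep_monomorphic and hap.shape[1]:
        seg = (hap.sum(axis=0) > 0) & (hap.sum(axis=0) < hap.shape[0])
        hap, pos = hap[:, seg], pos[seg]
    return SimulatedSample(haplotypes=hap, positions=pos, line_labels=labels,
                           target_allele_freq_by_line=freqs,
                           target_site_pos=tpos)


# ---------------------------------------------------------------------------
# emitters


def sample_names(sample: SimulatedSample) -> list[str]:
    """Per-individual sample names encoding line membership (GA_1, ...)."""
    counts: dict[str, int] = {}
    names = []
    for line in sample.line_labels[0::2]:
        counts[line] = counts.get(line, 0) + 1
        names.append(f"{line}_{counts[line]}")
    return names


def emit_genome_vcf(samples: dict[str, SimulatedSample], mean_depth: float,
                    seed, path,
                    contig_lengths: dict[str, int] | None = None) -> None:
    """Write one VCF 4.2 (GT and Poisson DP) covering several contigs.

    All samples must share the same individual layout; sample columns are
    named from the first contig's line labels.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not samples:
        raise ValueError("no contigs to write")
    rng = np.random.default_rng(_seed_sequence(seed))
    first = next(iter(samples.values()))
    names = sample_names(first)
    bases = np.array(list("ACGT"))
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for contig, s in samples.items():
                length = (contig_lengths or {}).get(
                    contig, int(s.positions[-1]) + 2 if len(s.positions) else 2)
                fh.write(f"##contig=<ID={contig},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(names) + "\n")
            for contig, s in samples.items():
                hap = s.haplotypes
                n_sites, n_ind = hap.shape[1], hap.shape[0] // 2
                dp = rng.poisson(mean_depth, size=(n_sites, n_ind))
                ref_i = rng.integers(0, 4, size=n_sites)
                alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
                for j in range(n_sites):
                    cells = [
                        f"{hap[2 * i, j]}/{hap[2 * i + 1, j]}:{dp[j, i]}"
                        for i in range(n_ind)
                    ]
                    fh.write(f"{contig}\t{int(s.positions[j]) + 1}\t.\t"
                             f"{bases[ref_i[j]]}\t{bases[alt_i[j]]}\t.\tPASS\t.\t"
                             "GT:DP\t" + "\t".join(cells) + "\n")
    except OSError as exc:
        raise IOError(f"could not write VCF to {path}: {exc}") from exc


def emit_vcf(sample: SimulatedSample, mean_depth: float, seed, path,
             contig: str = "sim_1", contig_length: int | None = None) -> None:
    """Write one sample as a single-contig diploid VCF 4.2."""
    lengths = None if contig_length is None else {contig: contig_length}
    emit_genome_vcf({contig: sample}, mean_depth, seed, path, lengths)


def emit_amplicon_alignment(n_per_line: int, length: int, snp_positions,
                            line_freqs: dict[str, np.ndarray], seed) -> AlignmentSet:
    """Synthesize an aligned haplotype FASTA-style set with line structure.

    ``line_freqs`` maps a line label to per-SNP alternate-allele
    frequencies; each sequence draws its allele independently per site, so
    the realized site-frequency spectrum is binomial around the requested
    frequencies.
    """
    snp_positions = np.asarray(snp_positions, dtype=int)
    if np.any((snp_positions < 0) | (snp_positions >= length)):
        raise ValueError("snp positions must lie in [0, length)")
    rng = np.random.default_rng(_seed_sequence(seed))
    bases = np.array(list("ACGT"))
    backbone = rng.integers(0, 4, size=length)
    alt = (backbone[snp_positions] + rng.integers(1, 4, size=len(snp_positions))) % 4
    seqs: list[str] = []
    labels: list[str] = []
    for line, freqs in line_freqs.items():
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != snp_positions.shape:
            raise ValueError("one frequency per SNP position required")
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        draws = rng.random((n_per_line, len(snp_positions))) < freqs
        for i in range(n_per_line):
            row = backbone.copy()
            row[snp_positions[draws[i]]] = alt[draws[i]]
            seqs.append("".join(bases[row]))
            labels.append(line)
    return AlignmentSet(sequences=seqs, labels=labels)
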