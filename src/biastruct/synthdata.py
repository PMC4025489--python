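"""Synthetic founders and forward-simulated admixed cohorts.

Two ancestral populations are generated under the Balding-Nichols model:
each locus has an ancestral frequency drawn uniformly on [0.05, 0.95], and
each population's frequency is a Beta draw with that mean and dispersion
parameter F (the drift accumulated since the split), so the expected Hudson
F_ST between the two samples equals the mean of the two drift values.

Admixed cohorts come from an explicit forward simulator: a single admixture
generation in which every offspring has one parent from each founder
population (ancestry exactly 50-50), followed by generations of random mating
with Poisson-distributed crossovers.  Each haplotype carries its local
ancestry as a list of (start, end, population) intervals in 0-based half-open
base-pair coordinates, so the true ancestry proportion theta (fraction of the
genome from population 2) is known exactly for every simulated individual.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import GenotypeTable, LabelTable

__all__ = [
    "FounderFrequencies",
    "Cohort",
    "gen_founder_frequencies",
    "sample_founder_genotypes",
    "simulate_admixture",
    "expand_pool",
    "assemble_study_population",
]


@dataclasses.dataclass
class FounderFrequencies:
    """Per-locus ancestral and population allele frequencies with drift."""

    ancestral_freq: np.ndarray  # (M,)
    pop_freq: np.ndarray  # (2, M)
    drift_f: tuple[float, float]

    def __post_init__(self) -> None:
        self.ancestral_freq = np.asarray(self.ancestral_freq, dtype=float)
        self.pop_freq = np.asarray(self.pop_freq, dtype=float)
        if self.pop_freq.shape != (2, self.ancestral_freq.size):
            raise ValueError("pop_freq must be 2 x n_loci")
        if ((self.pop_freq < 0) | (self.pop_freq > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if min(self.drift_f) <= 0:
            raise ValueError("drift must be positive")

    @property
    def n_loci(self) -> int:
        return self.ancestral_freq.size


@dataclasses.dataclass
class Cohort:
    """Genotypes + labels (+ haplotypes and ancestry segments when simulated).

    `haplotypes` is an (N, 2, M) 0/1 array of phased alleles; `segments`
    holds, per individual, a pair of lists of (start, end, population)
    intervals covering [0, region_length).
    """

    genotypes: GenotypeTable
    labels: LabelTable
    haplotypes: np.ndarray | None = None
    segments: list | None = None
    region_length: float | None = None
    positions: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    def theta_from_segments(self) -> np.ndarray:
        """Recompute theta as the pop-2 length fraction of each genome."""
        if self.segments is None or self.region_length is None:
            raise ValueError("cohort carries no ancestry segments")
        total = 2.0 * self.region_length
        out = np.empty(self.n_individuals)
        for i, (segs_a, segs_b) in enumerate(self.segments):
            pop2 = sum(e - s for s, e, p in segs_a if p == 2)
            pop2 += sum(e - s for s, e, p in segs_b if p == 2)
            out[i] = pop2 / total
        return out

    def take(self, indices, ids: list[str] | None = None) -> "Cohort":
        indices = np.asarray(indices)
        haps = None if self.haplotypes is None else self.haplotypes[indices]
        segs = None if self.segments is None else [self.segments[i] for i in indices]
        return Cohort(
            self.genotypes.take(indices, ids),
            self.labels.take(indices, ids),
            haplotypes=haps,
            segments=segs,
            region_length=self.region_length,
            positions=self.positions,
        )

    def by_group(self, group: int) -> "Cohort":
        return self.take(np.flatnonzero(self.labels.group == group))

    @staticmethod
    def concat(cohorts: list["Cohort"]) -> "Cohort":
        cohorts = [c for c in cohorts if c.n_individuals > 0]
        ids = [i for c in cohorts for i in c.genotypes.individual_ids]
        locus_ids = cohorts[0].genotypes.locus_ids
        matrix = np.vstack([c.genotypes.matrix for c in cohorts])
        group = np.concatenate([c.labels.group for c in cohorts])
        thetas = [c.labels.true_theta for c in cohorts]
        theta = None if any(t is None for t in thetas) else np.concatenate(thetas)
        haps = None
        if all(c.haplotypes is not None for c in cohorts):
            haps = np.vstack([c.haplotypes for c in cohorts])
        segs = None
        if all(c.segments is not None for c in cohorts):
            segs = [s for c in cohorts for s in c.segments]
        region = cohorts[0].region_length
        positions = cohorts[0].positions
        return Cohort(
            GenotypeTable(ids, list(locus_ids), matrix),
            LabelTable(ids, group, theta),
            haplotypes=haps,
            segments=segs,
            region_length=region,
            positions=positions,
        )


# ---------------------------------------------------------------------------
# founders


def gen_founder_frequencies(
    n_loci: int,
    fst_target: float | None = 0.1,
    seed=None,
    drift_f: tuple[float, float] | None = None,
) -> FounderFrequencies:
    """Draw Balding-Nichols founder frequencies for two populations.

    `fst_target` sets a common drift F for both branches; `drift_f` overrides
    it with per-branch values (used for bottleneck scenarios, where one branch
    drifts more).  Loci where either population's frequency collapses to 0 or
    1 are rejected and redrawn, so every locus stays polymorphic.
    """
    if drift_f is None:
        if fst_target is None or not 0 < fst_target < 0.5:
            raise ValueError("fst_target must lie in (0, 0.5)")
        drift_f = (fst_target, fst_target)
    if not all(0 < f < 1 for f in drift_f):
        raise ValueError("drift values must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    anc = np.empty(n_loci)
    pops = np.empty((2, n_loci))
    todo = np.arange(n_loci)
    while todo.size:
        p = rng.uniform(0.05, 0.95, todo.size)
        draws = np.empty((2, todo.size))
        for k, f in enumerate(drift_f):
            a = p * (1.0 - f) / f
            b = (1.0 - p) * (1.0 - f) / f
            draws[k] = rng.beta(a, b)
        ok = ((draws > 1e-9) & (draws < 1.0 - 1e-9)).all(axis=0)
        anc[todo[ok]] = p[ok]
        pops[:, todo[ok]] = draws[:, ok]
        todo = todo[~ok]
    return FounderFrequencies(anc, pops, tuple(drift_f))


def sample_founder_genotypes(freqs: FounderFrequencies, n_per_pop: int, seed=None) -> Cohort:
    """Draw `n_per_pop` diploids from each founder population.

    Haplotypes are independent Bernoulli draws from the population frequency,
    so genotypes are Binomial(2, p) per locus.  Group labels are 1 and 2 with
    theta 0 and 1 respectively.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    m = freqs.n_loci
    haps = np.empty((2 * n_per_pop, 2, m), dtype=np.int8)
    for k in range(2):
        sl = slice(k * n_per_pop, (k + 1) * n_per_pop)
        haps[sl] = (rng.random((n_per_pop, 2, m)) < freqs.pop_freq[k]).astype(np.int8)
    geno = haps.sum(axis=1, dtype=np.int8)
    ids = [f"pop{k + 1}_{i}" for k in range(2) for i in range(n_per_pop)]
    group = np.repeat([1, 2], n_per_pop)
    theta = np.repeat([0.0, 1.0], n_per_pop)
    locus_ids = [f"L{j}" for j in range(m)]
    return Cohort(
        GenotypeTable(ids, locus_ids, geno),
        LabelTable(ids, group, theta),
        haplotypes=haps,
    )


# ---------------------------------------------------------------------------
# forward simulation


def _clip_segments(segs, lo, hi):
    out = []
    for s, e, p in segs:
        if e <= lo or s >= hi:
            continue
        out.append((max(s, lo), min(e, hi), p))
    return out


def _merge_segments(segs):
    if not segs:
        return segs
    merged = [segs[0]]
    for s, e, p in segs[1:]:
        ls, le, lp = merged[-1]
        if p == lp and s <= le:
            merged[-1] = (ls, e, p)
        else:
            merged.append((s, e, p))
    return merged


def _meiosis(hap_pair, seg_pair, positions, length, recomb_rate, rng):
    """One gamete from a parent: Poisson crossovers placed uniformly."""
    n_cross = rng.poisson(length * recomb_rate)
    start = int(rng.integers(2))
    if n_cross == 0:
        return hap_pair[start].copy(), list(seg_pair[start])
    breaks = np.sort(rng.uniform(0.0, length, n_cross))
    interval = np.searchsorted(breaks, positions, side="right")
    from_b = (start + interval) % 2 == 1
    alleles = np.where(from_b, hap_pair[1], hap_pair[0])
    bounds = np.concatenate(([0.0], breaks, [length]))
    segs = []
    for i in range(bounds.size - 1):
        src = seg_pair[(start + i) % 2]
        segs.extend(_clip_segments(src, bounds[i], bounds[i + 1]))
    return alleles, _merge_segments(segs)


def simulate_admixture(
    founders1: Cohort,
    founders2: Cohort,
    n_offspring: int = 800,
    n_generations: int = 7,
    region_length_bp: float = 102_000_000.0,
    recomb_rate: float = 1e-8,
    mutation_rate: float = 0.0,
    seed=None,
) -> Cohort:
    """Forward-simulate an admixed cohort with tracked local ancestry.

    Generation 1 is the admixture event: each offspring draws one parent from
    each founder pool, so its ancestry is exactly 50-50.  Every later
    generation draws two distinct parents uniformly at random (with
    replacement across offspring) from the previous generation.  Crossovers
    per meiosis are Poisson(region_length_bp * recomb_rate), placed uniformly;
    ancestry segments are propagated through each crossover mosaic and theta
    is recomputed as the pop-2 fraction of the diploid genome.  Mutation
    (allele flip with `mutation_rate` per locus per meiosis) is off by
    default: at array-like densities over a handful of generations it is
    negligible.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if founders1.n_individuals == 0 or founders2.n_individuals == 0:
        raise ValueError("founder pools must be non-empty")
    if founders1.haplotypes is None or founders2.haplotypes is None:
        raise ValueError("founders must carry phased haplotypes")
    rng = np.random.default_rng(seed)
    m = founders1.genotypes.n_loci
    length = float(region_length_bp)
    # loci evenly spaced over the region; segment arithmetic is in bp
    positions = (np.arange(m) + 0.5) * (length / m)

    founder_pools = []
    for pop_id, fd in ((1, founders1), (2, founders2)):
        pool = []
        for i in range(fd.n_individuals):
            segs = [(0.0, length, pop_id)]
            pool.append(
                (
                    (fd.haplotypes[i, 0], fd.haplotypes[i, 1]),
                    (list(segs), list(segs)),
                )
            )
        founder_pools.append(pool)

    def _mutate(alleles):
        if mutation_rate > 0:
            flips = rng.random(m) < mutation_rate
            if flips.any():
                alleles = alleles ^ flips
        return alleles

    current = []
    for _ in range(n_offspring):
        pa = founder_pools[0][rng.integers(len(founder_pools[0]))]
        pb = founder_pools[1][rng.integers(len(founder_pools[1]))]
        ha, sa = _meiosis(*pa, positions, length, recomb_rate, rng)
        hb, sb = _meiosis(*pb, positions, length, recomb_rate, rng)
        current.append(((_mutate(ha), _mutate(hb)), (sa, sb)))

    for _ in range(n_generations - 1):
        nxt = []
        n = len(current)
        for _ in range(n_offspring):
            i, j = rng.choice(n, size=2, replace=False)  # no selfing
            ha, sa = _meiosis(*current[i], positions, length, recomb_rate, rng)
            hb, sb = _meiosis(*current[j], positions, length, recomb_rate, rng)
            nxt.append(((_mutate(ha), _mutate(hb)), (sa, sb)))
        current = nxt

    haps = np.empty((n_offspring, 2, m), dtype=np.int8)
    segments = []
    for i, ((ha, hb), (sa, sb)) in enumerate(current):
        haps[i, 0] = ha
        haps[i, 1] = hb
        segments.append((sa, sb))
    geno = haps.sum(axis=1, dtype=np.int8)
    ids = [f"adm_{i}" for i in range(n_offspring)]
    locus_ids = list(founders1.genotypes.locus_ids)
    cohort = Cohort(
        GenotypeTable(ids, locus_ids, geno),
        LabelTable(ids, np.full(n_offspring, 3), np.zeros(n_offspring)),
        haplotypes=haps,
        segments=segments,
        region_length=length,
        positions=positions,
    )
    cohort.labels.true_theta = cohort.theta_from_segments()
    return cohort


def expand_pool(cohort: Cohort, target_count: int, seed=None) -> Cohort:
    """Duplicate individuals cyclically until the pool reaches `target_count`.

    Output individual i is input individual i mod n, so a pool of 38 expanded
    to 100 triplicates the first 24 and duplicates the remaining 14.
    """
    n = cohort.n_individuals
    if n == 0:
        raise ValueError("cannot expand an empty cohort")
    if target_count < n:
        raise ValueError("target_count must be >= current size")
    indices = np.arange(target_count) % n
    ids = []
    for k, i in enumerate(indices):
        base = cohort.genotypes.individual_ids[i]
        copy = k // n
        ids.append(base if copy == 0 else f"{base}.dup{copy}")
    return cohort.take(indices, ids)


def assemble_study_population(freqs: FounderFrequencies, config, seed=None) -> Cohort:
    """Build the three-group study population from founder frequencies.

    Group 1: unmixed pop-1 diploids expanded to `config.unmixed_pool`;
    group 2: likewise for pop 2; group 3: `config.n_admixed` forward-simulated
    admixed individuals (`config.n_generations` generations, the first being
    the 50-50 admixture event).  Default sizes are 100/100/800.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_founders, s_unmixed, s_sim = ss.spawn(3)
    parts = []
    unmixed = sample_founder_genotypes(freqs, config.n_founders, s_unmixed)
    parts.append(expand_pool(unmixed.by_group(1), config.unmixed_pool))
    parts.append(expand_pool(unmixed.by_group(2), config.unmixed_pool))
    if config.n_admixed > 0:
        founders = sample_founder_genotypes(freqs, config.n_founders, s_founders)
        parts.append(
            simulate_admixture(
                founders.by_group(1),
                founders.by_group(2),
                n_offspring=config.n_admixed,
                n_generations=config.n_generations,
                seed=s_sim,
            )
        )
    return Cohort.concat(parts)
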