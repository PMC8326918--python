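"""Simulation of an F2 bulk-segregant sequencing experiment.

Simulates an F2 population from a biparental cross (short-mesocotyl
recurrent parent x long-mesocotyl donor), selects extreme-phenotype
bulks, and samples pooled short-read allele depths at a marker grid,
emitting parent + bulk genotype data as VCF.

Recombination uses the Haldane map function (crossover count per
chromosome ~ Poisson(genetic length in Morgans), positions uniform,
no interference). Per-site depth is Poisson(mean_depth) by default,
negative binomial when a dispersion is configured.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "GenomeMap",
    "QTLSpec",
    "F2SimConfig",
    "F2Individual",
    "F2Population",
    "SimSite",
    "simulate_f2_population",
    "select_bulks",
    "simulate_bulk_reads",
    "write_simulation_vcf",
    "rice_like_genome",
    "QTLPositionError",
]

#: Phred points of genotype-quality support contributed by one concordant
#: read at a homozygous site (the usual variant-caller heuristic), capped
#: at the conventional GQ ceiling of 99.
PHRED_PER_READ = 3.0
GQ_CAP = 99

SAMPLE_NAMES = ("parent_short", "parent_long", "bulk_high", "bulk_low")


class QTLPositionError(ValueError):
    """A QTL position does not coincide with a marker-grid position."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    length_morgans: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: physical length must be > 0")
        if self.length_morgans <= 0:
            raise ValueError(f"{self.name}: genetic length must be > 0")


@dataclass(frozen=True)
class GenomeMap:
    """Marker grid on a set of chromosomes with a fixed bp<->cM scaling.

    Markers are placed every ``marker_spacing`` bp (1-based positions,
    starting at ``marker_spacing``); genetic positions scale linearly
    with physical position on each chromosome.
    """

    chromosomes: tuple[Chromosome, ...]
    marker_spacing: int = 10_000

    def __post_init__(self) -> None:
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be > 0")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def marker_positions(self, chrom: str) -> np.ndarray:
        """1-based marker positions (bp) on ``chrom``, strictly increasing."""
        c = self.chromosome(chrom)
        return np.arange(self.marker_spacing, c.length_bp + 1, self.marker_spacing,
                         dtype=np.int64)

    def marker_morgans(self, chrom: str) -> np.ndarray:
        """Genetic positions (Morgans) of the marker grid on ``chrom``."""
        c = self.chromosome(chrom)
        return self.marker_positions(chrom) / c.length_bp * c.length_morgans

    @property
    def n_markers(self) -> int:
        return sum(len(self.marker_positions(c.name)) for c in self.chromosomes)


def rice_like_genome(n_chromosomes: int = 2, length_bp: int = 40_000_000,
                     cm_per_mb: float = 4.0, marker_spacing: int = 10_000) -> GenomeMap:
    """A desk-scale stand-in for a rice-like genome.

    Defaults give 2 chromosomes of 40 Mb at 4 cM/Mb (the rice genome-wide
    average, ~1530 cM over ~373 Mb) with one marker per 10 kb.
    """
    morgans = length_bp / 1e6 * cm_per_mb / 100.0
    chroms = tuple(Chromosome(f"chr{i + 1}", length_bp, morgans)
                   for i in range(n_chromosomes))
    return GenomeMap(chroms, marker_spacing=marker_spacing)


@dataclass(frozen=True)
class QTLSpec:
    """One planted QTL: additive effect ``a`` and dominance ``d`` in
    phenotype units, following the F2 parameterisation
    y += a*(g-1) + d*1[g==1] where g counts long-parent alleles."""

    chromosome: str
    position: int
    additive_effect: float
    dominance_effect: float = 0.0


@dataclass(frozen=True)
class F2SimConfig:
    genome: GenomeMap
    qtls: tuple[QTLSpec, ...] = ()
    population_size: int = 720
    bulk_size: int = 50
    residual_sd: float = 1.0
    phenotype_mean: float = 0.0
    mean_depth: float = 50.0
    depth_dispersion: float | None = None  # NB size parameter; None -> Poisson
    base_error_rate: float = 0.001
    gq_model: str = "depth"  # "depth" or "fixed:<value>"
    ref_is_short_parent_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.bulk_size > self.population_size:
            raise ValueError("2*bulk_size must be <= population_size")
        if self.bulk_size <= 0:
            raise ValueError("bulk_size must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        for q in self.qtls:
            positions = self.genome.marker_positions(q.chromosome)
            if q.position not in positions:
                idx = int(np.argmin(np.abs(positions - q.position)))
                raise QTLPositionError(
                    f"QTL at {q.chromosome}:{q.position} is not on the marker "
                    f"grid (spacing {self.genome.marker_spacing} bp); nearest "
                    f"grid position is {int(positions[idx])}"
                )


@dataclass(frozen=True)
class F2Individual:
    """View of one simulated F2 individual: per-marker count of
    long-parent alleles (0/1/2) and its phenotype."""

    genotypes: np.ndarray
    phenotype: float


@dataclass
class F2Population:
    """A simulated F2 population.

    ``genotypes`` is an (n_individuals, n_markers) int8 matrix counting
    long-parent alleles; markers are ordered by (chromosome, position)
    following the genome map. Indexable: ``pop[i]`` -> :class:`F2Individual`.
    """

    genome: GenomeMap
    chrom_index: np.ndarray  # per-marker chromosome index into genome.chromosomes
    positions: np.ndarray    # per-marker bp position
    genotypes: np.ndarray    # (n, m) int8
    phenotypes: np.ndarray   # (n,) float

    def __len__(self) -> int:
        return self.genotypes.shape[0]

    def __getitem__(self, i: int) -> F2Individual:
        return F2Individual(self.genotypes[i], float(self.phenotypes[i]))

    def __iter__(self) -> Iterator[F2Individual]:
        for i in range(len(self)):
            yield self[i]

    def marker_index(self, chrom: str, position: int) -> int:
        ci = [c.name for c in self.genome.chromosomes].index(chrom)
        hits = np.flatnonzero((self.chrom_index == ci) & (self.positions == position))
        if hits.size == 0:
            raise KeyError(f"{chrom}:{position} not on marker grid")
        return int(hits[0])


def _simulate_gametes(genome: GenomeMap, n_gametes: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Parental origin (0 = short parent, 1 = long parent) of each gamete at
    every grid marker, under the Haldane model."""
    blocks = []
    for c in genome.chromosomes:
        gpos = genome.marker_morgans(c.name)
        out = np.empty((n_gametes, gpos.size), dtype=np.int8)
        n_xo = rng.poisson(c.length_morgans, size=n_gametes)
        starts = rng.integers(0, 2, size=n_gametes)
        for g in range(n_gametes):
            if n_xo[g] == 0:
                out[g] = starts[g]
            else:
                xo = np.sort(rng.uniform(0.0, c.length_morgans, size=n_xo[g]))
                out[g] = (starts[g] + np.searchsorted(xo, gpos)) % 2
        blocks.append(out)
    return np.concatenate(blocks, axis=1)


def simulate_f2_population(config: F2SimConfig) -> F2Population:
    """Simulate ``config.population_size`` F2 individuals.

    Each individual is the union of two independently recombined gametes;
    the phenotype is mu + sum_q [a_q*(g_q-1) + d_q*1(g_q=1)] + N(0, sigma^2).
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    n = config.population_size

    chrom_index = np.concatenate([
        np.full(genome.marker_positions(c.name).size, i, dtype=np.int32)
        for i, c in enumerate(genome.chromosomes)
    ])
    positions = np.concatenate([genome.marker_positions(c.name)
                                for c in genome.chromosomes])

    gametes = _simulate_gametes(genome, 2 * n, rng)
    genotypes = (gametes[:n] + gametes[n:]).astype(np.int8)

    phenotypes = np.full(n, config.phenotype_mean, dtype=float)
    names = [c.name for c in genome.chromosomes]
    for q in config.qtls:
        ci = names.index(q.chromosome)
        m = np.flatnonzero((chrom_index == ci) & (positions == q.position))[0]
        g = genotypes[:, m].astype(float)
        phenotypes += q.additive_effect * (g - 1.0)
        phenotypes += q.dominance_effect * (g == 1.0)
    if config.residual_sd > 0:
        phenotypes += rng.normal(0.0, config.residual_sd, size=n)

    return F2Population(genome, chrom_index, positions, genotypes, phenotypes)


def select_bulks(population: F2Population | Sequence[F2Individual], k: int,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the high (k largest phenotypes) and low (k smallest) bulks.

    Ties at the bulk boundary are broken by a seeded uniform draw, so the
    bulks are always disjoint and reproducible.
    """
    if k <= 0:
        raise ValueError("bulk size k must be > 0")
    if isinstance(population, F2Population):
        phenotypes = population.phenotypes
    else:
        phenotypes = np.asarray([ind.phenotype for ind in population], dtype=float)
    n = phenotypes.size
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds population size {n}")
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.random(n), phenotypes))
    low = np.sort(order[:k])
    high = np.sort(order[-k:])
    return high, low


@dataclass(frozen=True)
class SimSite:
    """One simulated VCF site: parent and bulk calls at a grid marker.

    Depth pairs are (ref reads, alt reads). ``long_allele_is_alt`` records
    which VCF allele is the long-parent allele at this site.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    long_allele_is_alt: bool
    parent_short_ad: tuple[int, int]
    parent_long_ad: tuple[int, int]
    high_ad: tuple[int, int]
    low_ad: tuple[int, int]
    parent_short_gq: int
    parent_long_gq: int
    high_gq: int
    low_gq: int


def _draw_depths(rng: np.random.Generator, m: int, cfg: F2SimConfig) -> np.ndarray:
    if cfg.depth_dispersion is None:
        return rng.poisson(cfg.mean_depth, size=m)
    size = cfg.depth_dispersion
    p = size / (size + cfg.mean_depth)
    return rng.negative_binomial(size, p, size=m)


def _gq(depths: np.ndarray, cfg: F2SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.gq_model.startswith("fixed:"):
        return np.full(depths.size, int(cfg.gq_model.split(":", 1)[1]), dtype=np.int64)
    if cfg.gq_model != "depth":
        raise ValueError(f"unknown gq_model {cfg.gq_model!r}")
    return np.minimum(GQ_CAP, np.round(PHRED_PER_READ * depths)).astype(np.int64)


def simulate_bulk_reads(population: F2Population, high: np.ndarray, low: np.ndarray,
                        config: F2SimConfig) -> list[SimSite]:
    """Sample pooled sequencing reads for both bulks and both parents.

    At each marker the bulk long-allele frequency is f = sum(g)/2k over the
    bulk's members (equimolar pooling); the long-allele read count is
    Binomial(depth, f*(1-eps) + (1-f)*eps). Parents are homozygous opposite
    alleles at every marker; which parent carries REF is drawn per site with
    probability ``ref_is_short_parent_prob``.
    """
    # independent stream from the population seed so population and reads
    # can be re-drawn separately but reproducibly
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    k = len(high)
    m = population.positions.size
    eps = config.base_error_rate

    f_high = population.genotypes[high].sum(axis=0) / (2.0 * k)
    f_low = population.genotypes[low].sum(axis=0) / (2.0 * k)

    ref_is_short = rng.random(m) < config.ref_is_short_parent_prob
    bases = np.array(["A", "C", "G", "T"])
    ref_base = rng.integers(0, 4, size=m)
    alt_base = (ref_base + rng.integers(1, 4, size=m)) % 4

    out: dict[str, np.ndarray] = {}
    for label, f in (("high", f_high), ("low", f_low),
                     ("p_short", np.zeros(m)), ("p_long", np.ones(m))):
        depth = _draw_depths(rng, m, config)
        p_long_read = f * (1 - eps) + (1 - f) * eps
        long_reads = rng.binomial(depth, p_long_read)
        out[label + "_depth"] = depth
        out[label + "_long"] = long_reads
        out[label + "_gq"] = _gq(depth, config, rng)

    sites: list[SimSite] = []
    names = [c.name for c in population.genome.chromosomes]
    for j in range(m):
        chrom = names[population.chrom_index[j]]

        def ad(label: str) -> tuple[int, int]:
            d = int(out[label + "_depth"][j])
            lg = int(out[label + "_long"][j])
            short_reads, long_reads = d - lg, lg
            if ref_is_short[j]:           # REF = short-parent allele
                return short_reads, long_reads
            return long_reads, short_reads

        sites.append(SimSite(
            chrom=chrom,
            pos=int(population.positions[j]),
            ref=str(bases[ref_base[j]]),
            alt=str(bases[alt_base[j]]),
            long_allele_is_alt=bool(ref_is_short[j]),
            parent_short_ad=ad("p_short"),
            parent_long_ad=ad("p_long"),
            high_ad=ad("high"),
            low_ad=ad("low"),
            parent_short_gq=int(out["p_short_gq"][j]),
            parent_long_gq=int(out["p_long_gq"][j]),
            high_gq=int(out["high_gq"][j]),
            low_gq=int(out["low_gq"][j]),
        ))
    return sites


def _vcf_sample_field(ad: tuple[int, int], gq: int, hom_alt: bool) -> str:
    gt = "1/1" if hom_alt else "0/0"
    return f"{gt}:{ad[0]},{ad[1]}:{ad[0] + ad[1]}:{gq}"


def _bulk_gt(ad: tuple[int, int]) -> str:
    ref_reads, alt_reads = ad
    if ref_reads == 0 and alt_reads == 0:
        return "./."
    if alt_reads == 0:
        return "0/0"
    if ref_reads == 0:
        return "1/1"
    return "0/1"


def write_simulation_vcf(sites: Sequence[SimSite], path, genome: GenomeMap | None = None) -> None:
    """Write simulated sites as a VCF v4.2 with samples
    parent_short, parent_long, bulk_high, bulk_low (FORMAT GT:AD:DP:GQ).

    Output is byte-deterministic for a given site list.
    """
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=qtlseq-f2sim\n")
    if genome is not None:
        for c in genome.chromosomes:
            buf.write(f"##contig=<ID={c.name},length={c.length_bp}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(SAMPLE_NAMES) + "\n")
    for s in sites:
        short_hom_alt = not s.long_allele_is_alt  # short parent carries ALT
        fields = [
            s.chrom, str(s.pos), ".", s.ref, s.alt, ".", "PASS", ".", "GT:AD:DP:GQ",
            _vcf_sample_field(s.parent_short_ad, s.parent_short_gq, short_hom_alt),
            _vcf_sample_field(s.parent_long_ad, s.parent_long_gq, not short_hom_alt),
            f"{_bulk_gt(s.high_ad)}:{s.high_ad[0]},{s.high_ad[1]}:"
            f"{s.high_ad[0] + s.high_ad[1]}:{s.high_gq}",
            f"{_bulk_gt(s.low_ad)}:{s.low_ad[0]},{s.low_ad[1]}:"
            f"{s.low_ad[0] + s.low_ad[1]}:{s.low_gq}",
        ]
        buf.write("\t".join(fields) + "\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def simulate_experiment(config: F2SimConfig) -> tuple[F2Population, np.ndarray, np.ndarray, list[SimSite]]:
    """Convenience pipeline: population -> bulks -> pooled reads."""
    pop = simulate_f2_population(config)
    high, low = select_bulks(pop, config.bulk_size, seed=config.seed)
    sites = simulate_bulk_reads(pop, high, low, config)
    return pop, high, low, sites
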