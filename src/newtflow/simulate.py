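"""Coalescent data generator and Monte Carlo oracle.

This module wraps msprime to produce (i) genotype datasets with the
transcriptome-like structure the downstream filters expect -- independent
transcript loci, 6+6 diploid in-group individuals with locality labels plus
one outgroup individual, read-depth/quality metadata and missing data -- and
(ii) Monte Carlo estimates of the expected joint SFS used to cross-validate
the deterministic engine.  The deterministic engine in
:mod:`newtflow.engine` shares none of this code path: it never calls
msprime, and msprime knows nothing of the moment system.

Scaled demographies from the model registry are converted to msprime
``Demography`` objects with an explicit ancestral size ``N_A`` (diploid
individuals); times convert as ``t_gen = 2 N_A tau`` and migration as
``m = M / (2 N_A)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from .models import DemographicModel, model_registry
from .sfs import Spectrum, corner_mask

__all__ = [
    "SimulationConfig",
    "GenotypeDataset",
    "Locus",
    "simulate_dataset",
    "add_observation_noise",
    "sample_sfs",
    "montecarlo_expected_sfs",
    "to_msprime_demography",
    "write_dataset",
]

BASES = np.array(["A", "C", "G", "T"])

# Default sampling layout: localities per in-group individual.  One individual
# per locality yields 4 Lv + 5 Lm, i.e. the 8 x 10 spectrum shape used
# throughout.
DEFAULT_LAYOUT = {
    "Lv": ["lv_A", "lv_A", "lv_B", "lv_B", "lv_C", "lv_D"],
    "Lm": ["lm_A", "lm_A", "lm_B", "lm_C", "lm_D", "lm_E"],
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults emulate the transcriptome study design: ~10^3 transcript-like
    loci of 500 bp, 6 diploid individuals per species (localities as in
    ``DEFAULT_LAYOUT``), one outgroup individual, free recombination between
    loci and none within (``rho`` configurable for goodness-of-fit runs).
    """

    model: str = "SCGHET"
    params: tuple = ()
    N_A: float = 10_000.0           # ancestral diploid size
    mu: float = 6.3e-9              # per bp per generation
    n_loci: int = 1000
    locus_length: int = 500
    rho: float = 0.0                # per-locus scaled recombination 4 N_A r L
    layout: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_LAYOUT.items()})
    outgroup_divergence: float = 0.05   # per-site divergence of the outgroup
    heterogeneity_p: float | None = None  # override P for class assignment
    seed: int = 1

    def __post_init__(self):
        m = model_registry(self.model)
        if not self.params:
            raise ValueError("params must be given")
        if len(self.params) != m.n_params:
            raise ValueError(
                f"{self.model} expects {m.n_params} parameters {m.param_names}"
            )
        for name, value in [("N_A", self.N_A), ("mu", self.mu),
                            ("n_loci", self.n_loci), ("locus_length", self.locus_length)]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        p = self.heterogeneity_fraction
        if not 0.0 <= p <= 1.0:
            raise ValueError("heterogeneity fraction must lie in [0, 1]")
        if p > 0.0 and p < 1.0 and not m.het:
            raise ValueError(
                f"heterogeneity requested (P={p}) for non-heterogeneous model "
                f"{self.model}"
            )

    @property
    def demographic_model(self) -> DemographicModel:
        return model_registry(self.model)

    @property
    def heterogeneity_fraction(self) -> float:
        if self.heterogeneity_p is not None:
            return float(self.heterogeneity_p)
        return self.demographic_model.mixture_weight(self.params) \
            if self.demographic_model.het else 0.0


@dataclass
class Locus:
    """One simulated transcript-like locus."""

    name: str
    length: int
    orf: tuple[int, int]              # 0-based half-open on the locus
    ancestral_seq: str                # ancestral (outgroup-ancestor) sequence
    genotypes: np.ndarray             # (sites, individuals, 2) byte codes 0..3
    depth: np.ndarray                 # (sites, individuals) int
    gq: np.ndarray                    # (sites, individuals) int
    site_qual: np.ndarray             # (sites,) float
    outgroup: np.ndarray              # (sites,) byte code 0..3, or -1 missing
    mito: bool = False
    migration_class: int = 0          # truth label (simulation only)
    truth_genotypes: np.ndarray | None = None  # pre-noise copy


@dataclass
class GenotypeDataset:
    """Loci x individuals diploid genotype data with metadata."""

    loci: list[Locus]
    individuals: list[str]
    species: dict[str, str]           # individual -> species label
    locality: dict[str, str]          # individual -> locality label
    outgroup_name: str = "Lh_1"

    def individuals_of(self, species: str) -> list[str]:
        return [i for i in self.individuals if self.species[i] == species]


# ---------------------------------------------------------------------------
# msprime demography
# ---------------------------------------------------------------------------

def to_msprime_demography(model: DemographicModel | str, params, N_A: float,
                          rate_class: int = 0) -> msprime.Demography:
    """Convert a scaled registry demography to an msprime ``Demography``.

    Population 1 is ``Lv``, population 2 ``Lm``; the ancestral population
    ``ANC`` has constant diploid size ``N_A``.
    """
    if isinstance(model, str):
        model = model_registry(model)
    epochs = model.epochs(params, rate_class)
    demog = msprime.Demography()
    last = epochs[-1]
    # growth rate of the most recent epoch (forward exponential -> msprime alpha)
    def alpha(ep, pop):
        d_gen = 2.0 * N_A * ep.duration
        if not ep.has_growth or d_gen == 0:
            return 0.0
        return np.log(ep.end[pop] / ep.start[pop]) / d_gen

    demog.add_population(name="Lv", initial_size=last.end[0] * N_A,
                         growth_rate=alpha(last, 0))
    demog.add_population(name="Lm", initial_size=last.end[1] * N_A,
                         growth_rate=alpha(last, 1))
    demog.add_population(name="ANC", initial_size=N_A)
    # m12: fraction of Lv that are new migrants from Lm == backwards rate Lv->Lm
    demog.set_migration_rate(source="Lv", dest="Lm", rate=last.mig[0] / (2.0 * N_A))
    demog.set_migration_rate(source="Lm", dest="Lv", rate=last.mig[1] / (2.0 * N_A))

    # older epochs, walking backwards in time
    t_back = 0.0
    for older, recent in zip(epochs[-2::-1], epochs[::-1]):
        t_back += 2.0 * N_A * recent.duration
        demog.add_population_parameters_change(
            time=t_back, population="Lv", initial_size=older.end[0] * N_A,
            growth_rate=alpha(older, 0))
        demog.add_population_parameters_change(
            time=t_back, population="Lm", initial_size=older.end[1] * N_A,
            growth_rate=alpha(older, 1))
        demog.add_migration_rate_change(
            time=t_back, source="Lv", dest="Lm", rate=older.mig[0] / (2.0 * N_A))
        demog.add_migration_rate_change(
            time=t_back, source="Lm", dest="Lv", rate=older.mig[1] / (2.0 * N_A))
    t_split = 2.0 * N_A * sum(e.duration for e in epochs)
    demog.add_population_split(time=t_split, derived=["Lv", "Lm"], ancestral="ANC")
    demog.sort_events()
    return demog


# ---------------------------------------------------------------------------
# Monte Carlo oracle for the expected SFS
# ---------------------------------------------------------------------------

def montecarlo_expected_sfs(model: DemographicModel | str, params, n1: int, n2: int,
                            n_reps: int = 20_000, seed: int = 1,
                            N_A: float = 1000.0) -> tuple[Spectrum, Spectrum]:
    """Monte Carlo estimate of the per-unit-theta expected joint SFS.

    Averages the branch-mode allele frequency spectrum (expected mutation
    counts per unit mutation rate) over ``n_reps`` independent genealogies
    simulated with msprime, divided by ``4 N_A`` to express the result per
    unit theta.  Heterogeneous models are handled as mixtures at the level of
    expected spectra.  Returns ``(mean, standard_error)`` spectra.

    This estimator is the independent oracle for :func:`newtflow.engine.
    expected_sfs`; it shares no numerics with the moment system.
    """
    if isinstance(model, str):
        model = model_registry(model)
    if model.het:
        P = model.mixture_weight(params)
        r1 = int(round(n_reps * P))
        mean1, se1 = _mc_class(model, params, n1, n2, max(r1, 2), seed, N_A, 0)
        mean2, se2 = _mc_class(model, params, n1, n2, max(n_reps - r1, 2),
                               seed + 1, N_A, 1)
        mean = P * mean1.data + (1 - P) * mean2.data
        se = np.sqrt((P * se1.data) ** 2 + ((1 - P) * se2.data) ** 2)
        return Spectrum(mean), Spectrum(se)
    return _mc_class(model, params, n1, n2, n_reps, seed, N_A, 0)


def _mc_class(model, params, n1, n2, n_reps, seed, N_A, rate_class):
    demog = to_msprime_demography(model, params, N_A, rate_class)
    reps = msprime.sim_ancestry(
        samples={"Lv": n1 // 2, "Lm": n2 // 2}, demography=demog,
        sequence_length=1, ploidy=2, num_replicates=n_reps, random_seed=seed)
    total = np.zeros((n1 + 1, n2 + 1))
    total_sq = np.zeros_like(total)
    for ts in reps:
        sets = [ts.samples(population=0), ts.samples(population=1)]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sets, mode="branch", polarised=True, span_normalise=True)
        total += afs
        total_sq += afs * afs
    mean = total / n_reps
    var = np.maximum(total_sq / n_reps - mean**2, 0.0)
    se = np.sqrt(var / n_reps)
    return Spectrum(mean / (4.0 * N_A)), Spectrum(se / (4.0 * N_A))


# ---------------------------------------------------------------------------
# Poisson sampling of an expected spectrum
# ---------------------------------------------------------------------------

def sample_sfs(expected: Spectrum, theta: float, seed: int) -> Spectrum:
    """Draw an observed spectrum, each unmasked cell ``Poisson(theta * cell)``."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if np.any(expected.data[~expected.mask] < 0):
        raise ValueError("expected spectrum has negative cells")
    rng = np.random.default_rng(seed)
    data = np.zeros_like(expected.data)
    unmasked = ~expected.mask
    data[unmasked] = rng.poisson(theta * expected.data[unmasked])
    return Spectrum(data, expected.mask.copy(), expected.pop_ids)


# ---------------------------------------------------------------------------
# Full dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> GenotypeDataset:
    """Simulate a transcriptome-like genotype dataset under a registry model.

    Loci are independent (free recombination between loci).  Each locus is
    simulated under the structured coalescent for the configured demography;
    mutations are placed under infinite sites at rate
    ``theta_locus = 4 N_A mu length`` with multi-hit placements rejected
    (additional mutations at an already-hit site are discarded; at the
    default ``theta_locus`` well under one mutation per site this loses a
    negligible fraction of mutations).  Diploid individuals are formed by
    msprime's random pairing of chromosomes within each population; locality
    labels are bookkeeping only (panmixia within species).  Heterogeneous
    models assign each locus independently to migration class 1 with
    probability ``P`` (Bernoulli truth labels are retained).

    The outgroup individual carries the ancestral allele plus private
    divergence: each site independently substitutes with probability
    ``config.outgroup_divergence``.  Depth and quality default to saturating
    values (60x, GQ 99, site QUAL 228); use :func:`add_observation_noise` to
    degrade them.
    """
    model = config.demographic_model
    rng = np.random.default_rng(config.seed)
    P = config.heterogeneity_fraction
    # migration-class truth labels: class 0 (rates *_1) with probability P,
    # class 1 (rates *_2) otherwise; homogeneous models are all class 0
    if model.het:
        classes = (rng.random(config.n_loci) >= P).astype(int)
    else:
        classes = np.zeros(config.n_loci, dtype=int)
    demogs = {}
    for rc in (0, 1) if model.het else (0,):
        demogs[rc] = to_msprime_demography(model, config.params, config.N_A, rc)

    layout = config.layout
    individuals = []
    species = {}
    locality = {}
    samples = []
    for sp in ("Lv", "Lm"):
        for k, loc in enumerate(layout[sp]):
            name = f"{sp}_{k + 1}"
            individuals.append(name)
            species[name] = sp
            locality[name] = loc
    n_lv = len(layout["Lv"])
    n_lm = len(layout["Lm"])

    seeds = rng.integers(1, 2**31 - 1, size=(config.n_loci, 2))
    loci = []
    for l in range(config.n_loci):
        truth_class = int(classes[l])
        ts = msprime.sim_ancestry(
            samples={"Lv": n_lv, "Lm": n_lm},
            demography=demogs[truth_class if model.het else 0],
            sequence_length=config.locus_length,
            recombination_rate=(config.rho / (4.0 * config.N_A * config.locus_length)),
            ploidy=2, random_seed=int(seeds[l, 0]))
        loci.append(_locus_from_ts(ts, config, l, truth_class, int(seeds[l, 1])))
    return GenotypeDataset(loci, individuals, species, locality)


def _locus_from_ts(ts, config: SimulationConfig, index: int, truth_class: int,
                   seed: int) -> Locus:
    rng = np.random.default_rng(seed)
    L = config.locus_length
    n_ind = ts.num_samples // 2
    anc = rng.integers(0, 4, size=L)

    # infinite-sites mutation with multi-hit rejection on the finite locus
    mts = msprime.sim_mutations(
        ts, rate=config.mu, model=msprime.BinaryMutationModel(),
        discrete_genome=True, random_seed=seed)
    geno = np.repeat(anc[:, None, None], n_ind, axis=1)
    geno = np.repeat(geno, 2, axis=2)  # (sites, individuals, 2)
    hit = np.zeros(L, dtype=bool)
    for var in mts.variants():
        pos = int(var.site.position)
        if hit[pos]:
            continue  # reject multi-hit placement
        # restrict to simple single-mutation sites of the binary model
        if len(var.site.mutations) != 1:
            continue
        hit[pos] = True
        derived = (anc[pos] + rng.integers(1, 4)) % 4
        carriers = var.genotypes.astype(bool)  # haploid genotypes, 1 = derived
        carr = carriers.reshape(n_ind, 2)
        geno[pos][carr] = derived

    # outgroup: ancestral allele with private divergence
    outg = anc.copy()
    div = rng.random(L) < config.outgroup_divergence
    shift = rng.integers(1, 4, size=L)
    outg[div] = (outg[div] + shift[div]) % 4

    depth = np.full((L, n_ind), 60, dtype=int)
    gq = np.full((L, n_ind), 99, dtype=int)
    site_qual = np.full(L, 228.0)
    orf_len = 3 * (L // 3)
    return Locus(
        name=f"locus_{index:05d}", length=L, orf=(0, orf_len),
        ancestral_seq="".join(BASES[anc]),
        genotypes=geno.astype(np.int8), depth=depth, gq=gq,
        site_qual=site_qual, outgroup=outg.astype(np.int8),
        mito=False, migration_class=int(truth_class),
    )


def add_observation_noise(data: GenotypeDataset, depth_mean: float,
                          depth_dispersion: float, miss_rate: float,
                          seed: int) -> GenotypeDataset:
    """Overlay sequencing-like observation noise on a simulated dataset.

    Per-site per-individual read depth is negative-binomial with the given
    mean and dispersion (``Var = mean + mean^2 / dispersion``); genotype
    quality follows the monotone map ``GQ = min(99, 2 * depth)`` (deeper
    sites are called more confidently); site quality is
    ``min(228, 3 * mean depth at the site)``; genotypes are additionally set
    missing (depth 0) with probability ``miss_rate``.  Truth genotypes are
    retained on each locus for test assertions.
    """
    if depth_mean <= 0 or depth_dispersion <= 0:
        raise ValueError("depth parameters must be positive")
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError("miss_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = depth_dispersion / (depth_dispersion + depth_mean)
    out_loci = []
    for locus in data.loci:
        depth = rng.negative_binomial(depth_dispersion, p, size=locus.depth.shape)
        missing = rng.random(locus.depth.shape) < miss_rate
        depth[missing] = 0
        gq = np.minimum(99, 2 * depth)
        site_qual = np.minimum(228.0, 3.0 * depth.mean(axis=1))
        out_loci.append(dataclasses.replace(
            locus, depth=depth.astype(int), gq=gq.astype(int),
            site_qual=site_qual,
            truth_genotypes=locus.genotypes.copy()))
    return GenotypeDataset(out_loci, list(data.individuals), dict(data.species),
                           dict(data.locality), data.outgroup_name)


# ---------------------------------------------------------------------------
# On-disk trio: VCF + locus annotation + sample sheet
# ---------------------------------------------------------------------------

def write_dataset(data: GenotypeDataset, outdir) -> dict:
    """Write the VCF / annotation-table / sample-sheet trio.

    The VCF (v4.2) is *all-sites*: every position of every locus gets a
    record with ``GT:DP:GQ`` per sample (in-group individuals plus the
    outgroup) and ``INFO/AA`` carrying the outgroup allele, so downstream
    callability and effective-length accounting need no side channel.
    Positions are 1-based in the VCF; the annotation table keeps 0-based
    half-open ORF coordinates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_path = outdir / "dataset.vcf"
    ann_path = outdir / "loci.tsv"
    sheet_path = outdir / "samples.tsv"

    names = list(data.individuals) + [data.outgroup_name]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral (outgroup) allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for locus in data.loci:
            fh.write(f"##contig=<ID={locus.name},length={locus.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for locus in data.loci:
            _write_locus_records(fh, locus, len(data.individuals))

    with open(ann_path, "w") as fh:
        fh.write("locus\tlength\torf_start\torf_end\tmito\n")
        for locus in data.loci:
            fh.write(f"{locus.name}\t{locus.length}\t{locus.orf[0]}\t"
                     f"{locus.orf[1]}\t{int(locus.mito)}\n")

    with open(sheet_path, "w") as fh:
        fh.write("individual\tspecies\tlocality\n")
        for ind in data.individuals:
            fh.write(f"{ind}\t{data.species[ind]}\t{data.locality[ind]}\n")
        fh.write(f"{data.outgroup_name}\toutgroup\toutgroup\n")

    return {"vcf": vcf_path, "annotation": ann_path, "samples": sheet_path}


def _write_locus_records(fh, locus: Locus, n_ingroup: int):
    geno = locus.genotypes
    for pos in range(locus.length):
        ref = locus.ancestral_seq[pos]
        site_alleles = [ref]
        codes = {ref: 0}
        out_code = int(locus.outgroup[pos])
        out_base = BASES[out_code] if out_code >= 0 else "."
        fields = []
        for ind in range(geno.shape[1]):
            a, b = geno[pos, ind]
            dp = int(locus.depth[pos, ind])
            gq = int(locus.gq[pos, ind])
            if dp == 0:
                fields.append(f"./.:{dp}:{gq}")
                continue
            gt = []
            for allele in (a, b):
                base = BASES[int(allele)]
                if base not in codes:
                    codes[base] = len(site_alleles)
                    site_alleles.append(base)
                gt.append(codes[base])
            fields.append(f"{min(gt)}/{max(gt)}:{dp}:{gq}")
        # outgroup column: genotype from the outgroup allele, saturating metadata
        if out_base != "." and out_base not in codes:
            codes[out_base] = len(site_alleles)
            site_alleles.append(out_base)
        og = codes[out_base] if out_base != "." else None
        fields.append(f"{og}/{og}:60:99" if og is not None else "./.:0:0")
        alt = ",".join(site_alleles[1:]) if len(site_alleles) > 1 else "."
        fh.write(f"{locus.name}\t{pos + 1}\t.\t{ref}\t{alt}\t"
                 f"{locus.site_qual[pos]:.0f}\t.\tAA={out_base}\tGT:DP:GQ\t"
                 + "\t".join(fields) + "\n")
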