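"""Dataset construction: callability, locus and site filters, joint SFS.

Reads the VCF / locus-annotation / sample-sheet trio (as written by
:mod:`newtflow.simulate`, or real data in the same formats -- the VCF must
be *all-sites* with ``GT:DP:GQ`` per sample and ``INFO/AA`` giving the
outgroup allele) and applies the study's filters:

* a genotype is *known* only if covered by >= 12 reads, genotype quality
  >= 20 Phred, and an outgroup allele is aligned at the position;
* loci are retained when known genotypes cover >= 70% of the ORF (and >= 35
  full codons) in at least three individuals per species, and are excluded
  when mitochondrial, denser than 60 SNP/kb, or containing a putative-paralog
  site (every genotyped individual of a species heterozygous);
* SFS sites must be callable in all selected individuals, biallelic, site
  quality >= 30 Phred, polarizable (the outgroup allele segregates in the
  in-group) and flanked on both sides by bases identical in all three
  species and nonpolymorphic.

Internally all coordinates are 0-based half-open; VCF positions are 1-based
on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .sfs import Spectrum

__all__ = [
    "CallabilityRules",
    "LocusData",
    "Dataset",
    "read_dataset",
    "call_consensus",
    "filter_loci",
    "sfs_site_filter",
    "build_joint_sfs",
    "select_one_per_locality",
    "var_alignments",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

# standard genetic code on base codes (0=A,1=C,2=G,3=T)
_CODON_TABLE = {}


def _codon_aa(c0: int, c1: int, c2: int) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import unambiguous_dna_by_id
        table = unambiguous_dna_by_id[1]
        for codon, aa in table.forward_table.items():
            key = tuple(_BASE_CODE[b] for b in codon)
            _CODON_TABLE[key] = aa
        for codon in table.stop_codons:
            _CODON_TABLE[tuple(_BASE_CODE[b] for b in codon)] = "*"
    return _CODON_TABLE[(c0, c1, c2)]


@dataclass(frozen=True)
class CallabilityRules:
    """Thresholds of the callability, locus and site filters."""

    min_depth: int = 12
    min_gq: int = 20
    min_site_qual: float = 30.0
    orf_coverage: float = 0.70
    min_codons: int = 35
    min_inds_per_species: int = 3
    snp_density_per_kb: float = 60.0
    paralog_min_genotyped: int = 6
    flank: int = 1

    def __post_init__(self):
        if not 0.0 < self.orf_coverage <= 1.0:
            raise ValueError("orf_coverage must lie in (0, 1]")
        for name in ("min_depth", "min_gq", "min_site_qual", "min_codons",
                     "min_inds_per_species", "snp_density_per_kb",
                     "paralog_min_genotyped", "flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class LocusData:
    """Arrays for one locus: (sites, individuals) layout, in-group only."""

    name: str
    length: int
    orf: tuple[int, int]
    mito: bool
    ref: np.ndarray          # (L,) base codes of the reference sequence
    geno: np.ndarray         # (L, n_ind, 2) codes, -1 missing
    depth: np.ndarray        # (L, n_ind)
    gq: np.ndarray           # (L, n_ind)
    qual: np.ndarray         # (L,)
    aa: np.ndarray           # (L,) outgroup allele codes, -1 missing


@dataclass
class Dataset:
    loci: dict[str, LocusData]
    individuals: list[str]               # in-group, VCF column order
    species: dict[str, str]
    locality: dict[str, str]

    def individuals_of(self, sp: str) -> list[str]:
        return [i for i in self.individuals if self.species[i] == sp]

    @property
    def species_labels(self) -> tuple[str, str]:
        seen = []
        for i in self.individuals:
            if self.species[i] not in seen:
                seen.append(self.species[i])
        if len(seen) != 2:
            raise ValueError(f"expected exactly two in-group species, got {seen}")
        return tuple(seen)


# ---------------------------------------------------------------------------
# Reading the trio
# ---------------------------------------------------------------------------

def read_dataset(vcf_path, annotation_path, samples_path) -> Dataset:
    """Load the VCF / annotation / sample-sheet trio into memory."""
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    ingroup = sheet[sheet.species != "outgroup"]
    individuals = list(ingroup.individual)
    species = dict(zip(ingroup.individual, ingroup.species))
    locality = dict(zip(ingroup.individual, ingroup.locality))

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"mito": int})
    loci: dict[str, LocusData] = {}
    for row in ann.itertuples():
        L = int(row.length)
        n = len(individuals)
        loci[row.locus] = LocusData(
            name=row.locus, length=L,
            orf=(int(row.orf_start), int(row.orf_end)), mito=bool(row.mito),
            ref=np.full(L, -1, dtype=np.int8),
            geno=np.full((L, n, 2), -1, dtype=np.int8),
            depth=np.zeros((L, n), dtype=np.int32),
            gq=np.zeros((L, n), dtype=np.int32),
            qual=np.zeros(L), aa=np.full(L, -1, dtype=np.int8),
        )

    vcf = pysam.VariantFile(str(vcf_path))
    col = {name: k for k, name in enumerate(vcf.header.samples)}
    idx = [col[i] for i in individuals]
    for rec in vcf:
        locus = loci.get(rec.chrom)
        if locus is None:
            continue
        pos = rec.pos - 1
        alleles = rec.alleles
        codes = np.array([_BASE_CODE.get(a, -1) for a in alleles], dtype=np.int8)
        locus.ref[pos] = codes[0]
        locus.qual[pos] = rec.qual if rec.qual is not None else 0.0
        aa = rec.info.get("AA")
        if aa in _BASE_CODE:
            locus.aa[pos] = _BASE_CODE[aa]
        samples = list(rec.samples.values())
        for k, ci in enumerate(idx):
            s = samples[ci]
            gt = s.get("GT")
            dp = s.get("DP") or 0
            gq = s.get("GQ") or 0
            locus.depth[pos, k] = dp
            locus.gq[pos, k] = gq
            if gt is not None and None not in gt:
                locus.geno[pos, k] = [codes[g] for g in gt]
    return Dataset(loci, individuals, species, locality)


# ---------------------------------------------------------------------------
# Callability
# ---------------------------------------------------------------------------

def call_consensus(data: Dataset, rules: CallabilityRules | None = None,
                   individuals: list[str] | None = None) -> dict[str, np.ndarray]:
    """Known/missing grid per locus: (sites, individuals) boolean arrays.

    A genotype is known iff read depth >= ``min_depth``, genotype quality
    >= ``min_gq``, the genotype itself was called, and an outgroup allele is
    aligned at the position.
    """
    rules = rules or CallabilityRules()
    individuals = individuals if individuals is not None else data.individuals
    sel = [data.individuals.index(i) for i in individuals]
    grids = {}
    for name, locus in data.loci.items():
        has_gt = (locus.geno[:, sel] >= 0).all(axis=2)
        grids[name] = (
            (locus.depth[:, sel] >= rules.min_depth)
            & (locus.gq[:, sel] >= rules.min_gq)
            & has_gt
            & (locus.aa >= 0)[:, None]
        )
    return grids


# ---------------------------------------------------------------------------
# Locus filters
# ---------------------------------------------------------------------------

def _orf_pass_count(locus: LocusData, known: np.ndarray, rules, members) -> int:
    """Individuals of ``members`` meeting the ORF-coverage quota."""
    a, b = locus.orf
    orf_known = known[a:b]
    orf_len = b - a
    n_codons = orf_len // 3
    count = 0
    for k in members:
        cov = orf_known[:, k].sum() / orf_len if orf_len else 0.0
        codons = orf_known[: 3 * n_codons, k].reshape(n_codons, 3).all(axis=1).sum() \
            if n_codons else 0
        if cov >= rules.orf_coverage and codons >= rules.min_codons:
            count += 1
    return count


def filter_loci(data: Dataset, known: dict[str, np.ndarray] | None = None,
                rules: CallabilityRules | None = None) -> tuple[list[str], pd.DataFrame]:
    """Apply the locus-level filters; return retained names and diagnostics.

    Retains loci with sufficient ORF coverage in >= ``min_inds_per_species``
    individuals of each species; drops mitochondrial loci, loci with SNP
    density strictly above ``snp_density_per_kb`` (SNPs over callable locus
    length), and putative paralogs (>= 1 site at which every genotyped
    individual of a species is heterozygous, with at least
    ``paralog_min_genotyped`` genotyped).
    """
    rules = rules or CallabilityRules()
    if known is None:
        known = call_consensus(data, rules)
    sp1, sp2 = data.species_labels
    members = {sp: [data.individuals.index(i) for i in data.individuals_of(sp)]
               for sp in (sp1, sp2)}
    rows, retained = [], []
    for name, locus in data.loci.items():
        k = known[name]
        geno = np.where(k[:, :, None], locus.geno, -1)
        reasons = []
        if locus.mito:
            reasons.append("mito")
        for sp in (sp1, sp2):
            if _orf_pass_count(locus, k, rules, members[sp]) < rules.min_inds_per_species:
                reasons.append(f"orf_coverage_{sp}")
        # SNP density over callable length
        callable_len = int((k.any(axis=1)).sum())
        chroms = geno.reshape(locus.length, -1)
        n_alleles = np.stack([(chroms == a).any(axis=1) for a in range(4)]).sum(axis=0)
        n_snps = int((n_alleles == 2).sum())
        if callable_len and n_snps / (callable_len / 1000.0) > rules.snp_density_per_kb:
            reasons.append("snp_density")
        # paralog rule
        het = (geno[:, :, 0] != geno[:, :, 1]) & (geno >= 0).all(axis=2)
        genotyped = (geno >= 0).all(axis=2)
        for sp in (sp1, sp2):
            g = genotyped[:, members[sp]]
            h = het[:, members[sp]]
            n_g = g.sum(axis=1)
            all_het = (h.sum(axis=1) == n_g) & (n_g >= rules.paralog_min_genotyped)
            if all_het.any():
                reasons.append(f"paralog_{sp}")
                break
        rows.append({"locus": name, "retained": not reasons,
                     "reasons": ",".join(reasons), "n_snps": n_snps,
                     "callable_len": callable_len})
        if not reasons:
            retained.append(name)
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Site-level SFS filter
# ---------------------------------------------------------------------------

def _classify_site(locus: LocusData, pos: int, observed: set[int]) -> str:
    """Synonymous / noncoding / other classification of one site.

    Inside the ORF a variant site is synonymous iff every observed in-group
    allele yields the same amino acid in the annotated frame (codon context
    from the reference; sites whose codon has another variant position are
    ambiguous and classified "other"); an invariant site is synonymous iff
    fourfold degenerate.  Sites outside the ORF are noncoding.
    """
    a, b = locus.orf
    if not (a <= pos < b):
        return "noncoding"
    frame = (pos - a) % 3
    c_start = pos - frame
    if c_start + 3 > b:
        return "other"  # partial codon at ORF end
    codon = [int(locus.ref[c_start + i]) for i in range(3)]
    if any(c < 0 for c in codon):
        return "other"
    try:
        if len(observed) > 1:
            aas = set()
            for allele in observed:
                c = codon.copy()
                c[frame] = allele
                aas.add(_codon_aa(*c))
            return "synonymous" if len(aas) == 1 else "other"
        aas = {_codon_aa(*(codon[:frame] + [x] + codon[frame + 1:]))
               for x in range(4)}
        return "synonymous" if len(aas) == 1 else "other"
    except KeyError:
        return "other"


def sfs_site_filter(data: Dataset, individuals: list[str],
                    rules: CallabilityRules | None = None,
                    loci: list[str] | None = None) -> pd.DataFrame:
    """Polarized biallelic site list plus callable invariant-site counts.

    Returns a data frame with one row per *site callable in all selected
    individuals* (columns: locus, pos, category, variant flag, derived
    counts d1/d2 per species).  SNP rows additionally satisfied: biallelic,
    site quality, polarizable (outgroup allele segregates in-group), both
    flanking bases identical in all three species and nonpolymorphic.
    Callable invariant rows carry ``d1 = d2 = 0`` and feed the effective
    length ``L``; variant sites failing an SNP criterion are excluded
    entirely (they enter neither the spectrum nor ``L``).
    """
    rules = rules or CallabilityRules()
    if loci is None:
        loci = list(data.loci)
    known = call_consensus(data, rules, individuals)
    sp1, sp2 = data.species_labels
    sel = [data.individuals.index(i) for i in individuals]
    is_sp1 = np.array([data.species[i] == sp1 for i in individuals])
    rows = []
    for name in loci:
        locus = data.loci[name]
        k = known[name]
        all_known = k.all(axis=1)
        geno = locus.geno[:, sel]  # (L, sel, 2)
        chroms = geno.reshape(locus.length, -1)
        present = np.stack([(chroms == a).any(axis=1) for a in range(4)])
        n_alleles = present.sum(axis=0)
        # per-site flank validity: monomorphic in-group matching the outgroup
        ingroup_mono = (n_alleles == 1)
        mono_allele = present.argmax(axis=0)
        flank_ok_site = all_known & ingroup_mono & (locus.aa == mono_allele) \
            & (locus.aa >= 0)
        for pos in np.nonzero(all_known)[0]:
            variant = n_alleles[pos] > 1
            observed = {int(a) for a in range(4) if present[a, pos]}
            if not variant:
                rows.append((name, int(pos),
                             _classify_site(locus, int(pos), observed),
                             False, 0, 0))
                continue
            if n_alleles[pos] != 2:
                continue
            if locus.qual[pos] < rules.min_site_qual:
                continue
            anc = int(locus.aa[pos])
            if anc not in observed:
                continue  # ancestral state not established in-group
            f = rules.flank
            lo, hi = pos - f, pos + f
            if lo < 0 or hi >= locus.length:
                continue
            flanks = list(range(lo, pos)) + list(range(pos + 1, hi + 1))
            if not all(flank_ok_site[q] for q in flanks):
                continue
            derived = ({a for a in observed if a != anc}).pop()
            d_counts = (chroms[pos] == derived).reshape(len(sel), 2).sum(axis=1)
            d1 = int(d_counts[is_sp1].sum())
            d2 = int(d_counts[~is_sp1].sum())
            rows.append((name, int(pos),
                         _classify_site(locus, int(pos), observed),
                         True, d1, d2))
    return pd.DataFrame(rows, columns=["locus", "pos", "category", "variant",
                                       "d1", "d2"])


# ---------------------------------------------------------------------------
# SFS construction
# ---------------------------------------------------------------------------

def select_one_per_locality(data: Dataset, seed: int | None = None) -> list[str]:
    """One individual per locality per species.

    Deterministic by default (lexicographically first individual id in each
    locality); pass a seed for a random choice instead.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    chosen = []
    for sp in data.species_labels:
        by_loc: dict[str, list[str]] = {}
        for ind in data.individuals_of(sp):
            by_loc.setdefault(data.locality[ind], []).append(ind)
        if not by_loc:
            raise ValueError(f"species {sp} has no individuals")
        for loc in sorted(by_loc):
            pool = sorted(by_loc[loc])
            chosen.append(pool[0] if rng is None else
                          pool[int(rng.integers(len(pool)))])
    return chosen


def build_joint_sfs(data: Dataset, rules: CallabilityRules | None = None,
                    one_per_locality: bool = True, seed: int | None = None,
                    categories: tuple[str, ...] | None = None,
                    loci: list[str] | None = None,
                    ) -> tuple[Spectrum, dict[str, Spectrum]]:
    """Unfolded joint SFS (and per-locus spectra) from a loaded dataset.

    Applies the locus filters, selects individuals (one per locality by
    default), runs the SFS site filter, and counts derived alleles per
    species.  ``categories`` restricts sites ("synonymous", "noncoding",
    "other"); the effective length ``L`` counts all callable sites (variant
    and invariant) of those categories.  Returns the pooled spectrum and a
    per-locus dict (for bootstrap resampling); ``Spectrum.L`` is set on all.
    """
    rules = rules or CallabilityRules()
    if loci is None:
        loci, _ = filter_loci(data, rules=rules)
    individuals = select_one_per_locality(data, seed) if one_per_locality \
        else list(data.individuals)
    sp1, _ = data.species_labels
    n1 = 2 * sum(1 for i in individuals if data.species[i] == sp1)
    n2 = 2 * len(individuals) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("a species has no selected individuals")
    sites = sfs_site_filter(data, individuals, rules, loci)
    if categories is not None:
        sites = sites[sites.category.isin(categories)]
    per_locus = {}
    total = np.zeros((n1 + 1, n2 + 1))
    for name, grp in sites.groupby("locus"):
        arr = np.zeros((n1 + 1, n2 + 1))
        snps = grp[grp.variant]
        np.add.at(arr, (snps.d1.to_numpy(), snps.d2.to_numpy()), 1)
        spec = Spectrum(arr, L=int(len(grp)))
        # corner mask removes any fixed-derived leakage from the count
        per_locus[name] = spec
        total += arr
    pooled = Spectrum(total, L=int(len(sites)))
    return pooled, per_locus


# ---------------------------------------------------------------------------
# Var-style alignments for summary statistics
# ---------------------------------------------------------------------------

def var_alignments(data: Dataset, rules: CallabilityRules | None = None,
                   categories: tuple[str, ...] = ("synonymous",),
                   loci: list[str] | None = None):
    """Masked per-locus alignments restricted to a site class.

    For each retained locus, returns ``(genotypes, species_array)`` where
    genotypes are known-masked (unknown set to -1) and restricted to sites
    of the requested categories (classified from the reference codon
    context, all individuals considered).  Suitable input for
    :func:`newtflow.sumstats.locus_stats`.
    """
    rules = rules or CallabilityRules()
    if loci is None:
        loci, _ = filter_loci(data, rules=rules)
    known = call_consensus(data, rules)
    species_arr = np.array([data.species[i] for i in data.individuals])
    out = {}
    for name in loci:
        locus = data.loci[name]
        k = known[name]
        geno = np.where(k[:, :, None], locus.geno, -1)
        chroms = geno.reshape(locus.length, -1)
        cats = []
        for pos in range(locus.length):
            observed = {int(a) for a in np.unique(chroms[pos]) if a >= 0}
            cats.append(_classify_site(locus, pos, observed) if observed else "other")
        keep = np.array([c in categories for c in cats])
        out[name] = (geno[keep], species_arr)
    return out
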