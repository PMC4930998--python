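"""Callability, locus and site filters, and SFS construction."""

import numpy as np
import pandas as pd
import pytest

from newtflow.builder import (CallabilityRules, Dataset, LocusData,
                              build_joint_sfs, call_consensus, filter_loci,
                              read_dataset, select_one_per_locality,
                              sfs_site_filter)
from newtflow.sfs import Spectrum

A, C, G, T = 0, 1, 2, 3


def make_dataset(n_per_species=3, length=9, orf=(0, 9), depth=40, gq=60,
                 qual=100.0, localities=None):
    """Minimal in-memory dataset: monomorphic reference 'A' everywhere."""
    n = 2 * n_per_species
    inds = [f"Lv_{i}" for i in range(n_per_species)] + \
           [f"Lm_{i}" for i in range(n_per_species)]
    species = {i: i.split("_")[0] for i in inds}
    if localities is None:
        locality = {i: f"loc_{i}" for i in inds}
    else:
        locality = dict(zip(inds, localities))
    locus = LocusData(
        name="L1", length=length, orf=orf, mito=False,
        ref=np.full(length, A, dtype=np.int8),
        geno=np.full((length, n, 2), A, dtype=np.int8),
        depth=np.full((length, n), depth, dtype=np.int32),
        gq=np.full((length, n), gq, dtype=np.int32),
        qual=np.full(length, qual),
        aa=np.full(length, A, dtype=np.int8),
    )
    return Dataset({"L1": locus}, inds, species, locality)


# -- callability boundaries -------------------------------------------------

def test_consensus_depth_boundary():
    ds = make_dataset()
    ds.loci["L1"].depth[0, 0] = 11   # below the 12-read minimum
    ds.loci["L1"].depth[1, 0] = 12
    known = call_consensus(ds)["L1"]
    assert not known[0, 0] and known[1, 0]


def test_consensus_gq_boundary():
    ds = make_dataset()
    ds.loci["L1"].gq[0, 0] = 19      # below 20 Phred, depth is fine
    ds.loci["L1"].gq[1, 0] = 20
    known = call_consensus(ds)["L1"]
    assert not known[0, 0] and known[1, 0]


def test_consensus_requires_outgroup_alignment():
    ds = make_dataset()
    ds.loci["L1"].aa[2] = -1
    known = call_consensus(ds)["L1"]
    assert not known[2].any() and known[1].all()


# -- locus filters ----------------------------------------------------------

def test_orf_coverage_quota():
    """An individual covering only 2/3 of the ORF does not count toward the
    three-per-species quota; the locus drops when too few individuals pass."""
    ds = make_dataset(n_per_species=3, length=300, orf=(0, 300))
    rules = CallabilityRules(min_codons=35)
    # all individuals fully covered -> retained
    retained, _ = filter_loci(ds, rules=rules)
    assert retained == ["L1"]
    # one Lv individual down to 200/300 known positions (66.7% < 70%)
    ds.loci["L1"].depth[200:, 0] = 0
    retained, diag = filter_loci(ds, rules=rules)
    assert retained == []
    assert "orf_coverage_Lv" in diag.reasons.iloc[0]


def test_min_full_codons_requirement():
    """Coverage fraction alone is not enough: fewer than 35 full codons
    fails even at 100% ORF coverage."""
    ds = make_dataset(length=90, orf=(0, 90))  # 30 codons < 35
    retained, diag = filter_loci(ds, rules=CallabilityRules())
    assert retained == []


def test_snp_density_strict_inequality():
    """1000-bp locus: 61 SNPs (>60/kb) excluded, 60 SNPs retained."""
    for n_snps, keep in ((61, False), (60, True)):
        ds = make_dataset(length=1002, orf=(0, 999))
        geno = ds.loci["L1"].geno
        for p in range(n_snps):
            geno[p, 0] = [A, T]   # one het individual -> biallelic site
        # callable length trimmed to exactly 1000 bases
        ds.loci["L1"].depth[1000:, :] = 0
        ds.loci["L1"].aa[1000:] = -1
        retained, diag = filter_loci(ds, rules=CallabilityRules(min_codons=0))
        assert diag.callable_len.iloc[0] == 1000
        assert (retained == ["L1"]) is keep


def test_paralog_all_heterozygous_site():
    """A site at which every genotyped individual of one species is
    heterozygous (six genotyped) flags the locus as a putative paralog."""
    ds = make_dataset(n_per_species=6, length=120, orf=(0, 120))
    rules = CallabilityRules(min_codons=35)
    geno = ds.loci["L1"].geno
    geno[5, 0:6] = [A, G]          # all six Lv heterozygous
    retained, diag = filter_loci(ds, rules=rules)
    assert retained == [] and "paralog_Lv" in diag.reasons.iloc[0]
    # five heterozygotes out of six genotyped -> kept
    geno[5, 0] = [A, A]
    retained, _ = filter_loci(ds, rules=rules)
    assert retained == ["L1"]


def test_mito_locus_dropped():
    ds = make_dataset(length=120)
    ds.loci["L1"].mito = True
    retained, diag = filter_loci(ds, rules=CallabilityRules(min_codons=0))
    assert retained == [] and "mito" in diag.reasons.iloc[0]


# -- site filter ------------------------------------------------------------

def site_filter_frame(ds, rules=None):
    return sfs_site_filter(ds, ds.individuals,
                           rules or CallabilityRules(min_codons=0),
                           loci=["L1"])


def test_triallelic_site_excluded():
    ds = make_dataset(length=9)
    ds.loci["L1"].geno[4, 0] = [T, T]
    ds.loci["L1"].geno[4, 3] = [G, G]
    sites = site_filter_frame(ds)
    assert not sites[(sites.pos == 4) & sites.variant].shape[0]


def test_unpolarizable_site_excluded():
    """Outgroup C while the in-group segregates only A/T: no established
    ancestral state, the SNP is dropped (not an error)."""
    ds = make_dataset(length=9)
    ds.loci["L1"].geno[4, :3] = [T, T]
    ds.loci["L1"].aa[4] = C
    sites = site_filter_frame(ds)
    assert not sites[(sites.pos == 4) & sites.variant].shape[0]


def test_flank_divergent_in_outgroup_excluded():
    """A flanking base differing in the outgroup violates the
    identical-in-all-species flank criterion."""
    ds = make_dataset(length=9)
    ds.loci["L1"].geno[4, 0] = [A, T]
    sites = site_filter_frame(ds)
    assert sites[(sites.pos == 4) & sites.variant].shape[0] == 1
    ds.loci["L1"].aa[5] = G        # outgroup differs at the right flank
    sites = site_filter_frame(ds)
    assert not sites[(sites.pos == 4) & sites.variant].shape[0]


def test_flank_polymorphic_ingroup_excluded():
    ds = make_dataset(length=9)
    ds.loci["L1"].geno[4, 0] = [A, T]
    ds.loci["L1"].geno[3, 1] = [A, G]   # left flank polymorphic in-group
    sites = site_filter_frame(ds)
    assert not sites[(sites.pos == 4) & sites.variant].shape[0]


def test_site_quality_threshold():
    ds = make_dataset(length=9)
    ds.loci["L1"].geno[4, 0] = [A, T]
    ds.loci["L1"].qual[4] = 29.0
    sites = site_filter_frame(ds)
    assert not sites[(sites.pos == 4) & sites.variant].shape[0]
    ds.loci["L1"].qual[4] = 30.0
    sites = site_filter_frame(ds)
    assert sites[(sites.pos == 4) & sites.variant].shape[0] == 1


def test_edge_sites_have_no_flanks():
    ds = make_dataset(length=9)
    ds.loci["L1"].geno[0, 0] = [A, T]
    ds.loci["L1"].geno[8, 0] = [A, T]
    sites = site_filter_frame(ds)
    assert not sites.variant.any()


# -- SFS construction -------------------------------------------------------

def test_derived_count_lands_in_correct_cell():
    """One SNP with 3 derived copies in species 1 and none in species 2
    increments cell (3, 0)."""
    ds = make_dataset(n_per_species=3, length=9)
    ds.loci["L1"].geno[4, 0] = [T, T]
    ds.loci["L1"].geno[4, 1] = [A, T]
    sfs, per_locus = build_joint_sfs(ds, CallabilityRules(min_codons=0),
                                     one_per_locality=False, loci=["L1"])
    assert sfs.data[3, 0] == 1 and sfs.sum() == 1
    assert per_locus["L1"].data[3, 0] == 1


def test_monomorphic_dataset_zero_cells_positive_length():
    ds = make_dataset(length=9)
    sfs, _ = build_joint_sfs(ds, CallabilityRules(min_codons=0),
                             one_per_locality=False, loci=["L1"])
    assert sfs.sum() == 0 and sfs.L == 9


def test_one_per_locality_selection():
    """Six individuals over five localities: five selected, lexicographically
    first individual in the shared locality."""
    ds = make_dataset(n_per_species=6, length=9,
                      localities=["p1", "p1", "p2", "p3", "p4", "p5",
                                  "q1", "q2", "q3", "q4", "q5", "q6"])
    chosen = select_one_per_locality(ds)
    lv = [c for c in chosen if c.startswith("Lv")]
    assert lv == ["Lv_0", "Lv_2", "Lv_3", "Lv_4", "Lv_5"]
    assert len([c for c in chosen if c.startswith("Lm")]) == 6


def test_sfs_sum_equals_retained_snps(sc_dataset, sc_trio):
    data = read_dataset(sc_trio["vcf"], sc_trio["annotation"], sc_trio["samples"])
    sfs, per_locus = build_joint_sfs(data)
    sites = sfs_site_filter(data, select_one_per_locality(data),
                            loci=list(per_locus))
    assert sfs.sum() == int(sites.variant.sum())
    assert sfs.L == len(sites)
    # per-locus spectra add up to the pooled spectrum
    total = sum(s.data.sum() for s in per_locus.values())
    assert total == sfs.data.sum()


def test_filters_are_order_independent(sc_dataset, sc_trio):
    """Restricting sites to retained loci before or after site filtering
    yields the same spectrum."""
    data = read_dataset(sc_trio["vcf"], sc_trio["annotation"], sc_trio["samples"])
    retained, _ = filter_loci(data)
    inds = select_one_per_locality(data)
    after = sfs_site_filter(data, inds, loci=retained)
    before = sfs_site_filter(data, inds)
    before = before[before.locus.isin(retained)].reset_index(drop=True)
    pd.testing.assert_frame_equal(before, after.reset_index(drop=True))


def test_noise_free_sfs_matches_truth_haplotypes(sc_dataset, sc_trio):
    """With saturating depth/quality the built SFS equals the spectrum
    counted directly from the simulated truth genotypes."""
    data = read_dataset(sc_trio["vcf"], sc_trio["annotation"], sc_trio["samples"])
    retained, _ = filter_loci(data)
    inds = select_one_per_locality(data)
    sfs, _ = build_joint_sfs(data, loci=retained)

    sel = [sc_dataset.individuals.index(i) for i in inds]
    is_lv = np.array([sc_dataset.species[i] == "Lv" for i in inds])
    truth = np.zeros_like(sfs.data)
    for locus in sc_dataset.loci:
        if locus.name not in retained:
            continue
        geno = locus.genotypes[:, sel]
        anc = np.frombuffer(locus.ancestral_seq.encode(), dtype=np.uint8)
        anc = np.array([{65: 0, 67: 1, 71: 2, 84: 3}[b] for b in anc])
        outg = locus.outgroup
        for pos in range(locus.length):
            alleles = set(geno[pos].ravel().tolist())
            if len(alleles) != 2 or int(outg[pos]) not in alleles:
                continue
            if pos == 0 or pos == locus.length - 1:
                continue
            # flanks must be invariant and outgroup-identical
            ok = True
            for q in (pos - 1, pos + 1):
                flank = set(geno[q].ravel().tolist())
                if len(flank) != 1 or int(outg[q]) not in flank:
                    ok = False
            if not ok:
                continue
            derived = (alleles - {int(outg[pos])}).pop()
            d = (geno[pos] == derived).sum(axis=1)
            truth[d[is_lv].sum(), d[~is_lv].sum()] += 1
    truth[0, 0] = truth[-1, -1] = 0
    assert np.array_equal(sfs.data[~sfs.mask], truth[~sfs.mask])
    assert sfs.sum() > 0  # the check is non-vacuous


def test_species_with_no_individuals_rejected():
    ds = make_dataset()
    for i in list(ds.species):
        if i.startswith("Lm"):
            ds.species[i] = "Lv"
    with pytest.raises(ValueError):
        build_joint_sfs(ds, CallabilityRules(min_codons=0), loci=["L1"])
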