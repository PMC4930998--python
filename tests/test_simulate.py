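"""Coalescent data generator: determinism, neutral expectations, noise."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from newtflow.engine import expected_sfs
from newtflow.simulate import (SimulationConfig, add_observation_noise,
                               montecarlo_expected_sfs, sample_sfs,
                               simulate_dataset)


def small_config(**kw):
    base = dict(model="SI", params=(1.0, 1.0, 0.5), N_A=20_000, mu=1e-7,
                n_loci=30, locus_length=200, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        small_config(params=(1.0, 1.0))          # wrong arity
    with pytest.raises(ValueError):
        small_config(N_A=-5)
    with pytest.raises(ValueError):
        small_config(heterogeneity_p=0.5)        # non-HET model
    with pytest.raises(KeyError):
        small_config(model="NOPE")


def test_fixed_seed_reproduces_dataset_bitwise():
    a = simulate_dataset(small_config())
    b = simulate_dataset(small_config())
    assert len(a.loci) == len(b.loci)
    for la, lb in zip(a.loci, b.loci):
        assert la.ancestral_seq == lb.ancestral_seq
        assert np.array_equal(la.genotypes, lb.genotypes)
        assert np.array_equal(la.outgroup, lb.outgroup)
    c = simulate_dataset(small_config(seed=8))
    assert any(not np.array_equal(la.genotypes, lc.genotypes)
               for la, lc in zip(a.loci, c.loci))


def test_truth_class_labels_follow_bernoulli_p():
    cfg = SimulationConfig(
        model="IMHET", params=(0.5, 0.5, 0.1, 0.1, 2.0, 2.0, 0.8),
        N_A=5_000, mu=1e-8, n_loci=300, locus_length=50, seed=3)
    ds = simulate_dataset(cfg)
    labels = np.array([l.migration_class for l in ds.loci])
    # class 0 carries weight P = 0.8
    assert stats.binomtest((labels == 0).sum(), 300, 0.8).pvalue > 1e-4


def test_neutral_diversity_matches_four_n_mu():
    """Constant-size panmixia (SI at T ~ 0): mean pairwise diversity over
    many loci approaches 4 N_A mu per site."""
    cfg = small_config(params=(1.0, 1.0, 1e-6), n_loci=300, locus_length=100,
                       N_A=20_000, mu=1e-7, seed=11)
    ds = simulate_dataset(cfg)
    diffs = total = 0.0
    for locus in ds.loci:
        chroms = locus.genotypes.reshape(locus.length, -1)
        n = chroms.shape[1]
        counts = np.stack([(chroms == a).sum(axis=1) for a in range(4)], axis=1)
        same = (counts * (counts - 1) / 2.0).sum(axis=1)
        diffs += (1.0 - same / (n * (n - 1) / 2.0)).sum()
        total += locus.length
    pi = diffs / total
    expected = 4 * cfg.N_A * cfg.mu
    assert pi == pytest.approx(expected, rel=0.15)


def test_shared_polymorphism_vanishes_with_divergence_time():
    """Under strict isolation the fraction of shared polymorphisms decays
    monotonically with split time."""
    fractions = []
    for T in (0.05, 0.5, 2.0):
        cfg = small_config(params=(1.0, 1.0, T), n_loci=150,
                           locus_length=150, seed=5)
        ds = simulate_dataset(cfg)
        shared = snps = 0
        for locus in ds.loci:
            g = locus.genotypes
            lv = g[:, :6].reshape(locus.length, -1)
            lm = g[:, 6:].reshape(locus.length, -1)
            for pos in range(locus.length):
                alle = set(g[pos].ravel().tolist())
                if len(alle) != 2:
                    continue
                snps += 1
                if len(set(lv[pos])) > 1 and len(set(lm[pos])) > 1:
                    shared += 1
        fractions.append(shared / max(snps, 1))
    assert fractions[0] > fractions[1] > fractions[2]


def test_population_exchange_symmetry_of_pooled_spectrum():
    """For symmetric parameters and equal sample sizes the pooled observed
    spectrum is statistically symmetric under population exchange."""
    layout = {"Lv": ["a", "b", "c"], "Lm": ["x", "y", "z"]}
    cfg = SimulationConfig(model="IM", params=(0.5, 0.8, 0.6, 0.6),
                           N_A=20_000, mu=2e-7, n_loci=400, locus_length=120,
                           layout=layout, seed=13)
    ds = simulate_dataset(cfg)
    n = 6
    sfs = np.zeros((n + 1, n + 1))
    for locus in ds.loci:
        g = locus.genotypes
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for pos in range(locus.length):
            alle = set(g[pos].ravel().tolist())
            if len(alle) != 2:
                continue
            anc = code[locus.ancestral_seq[pos]]
            derived = (alle - {int(anc)})
            if len(derived) != 1:
                continue
            d = (g[pos] == derived.pop()).sum(axis=1)
            sfs[d[:3].sum(), d[3:].sum()] += 1
    x = y = 0.0
    chi = 0.0
    for i in range(n + 1):
        for j in range(i + 1, n + 1):
            a, b = sfs[i, j], sfs[j, i]
            if a + b >= 5:
                chi += (a - b) ** 2 / (a + b)
                x += 1
    p = stats.chi2.sf(chi, max(int(x), 1))
    assert p > 0.01


def test_sample_sfs_poisson_properties():
    exp = expected_sfs("SI", [1.0, 0.5, 0.5], 4, 4)
    zero = sample_sfs(exp, 0.0, seed=1)
    assert zero.sum() == 0
    a = sample_sfs(exp, 50.0, seed=2)
    b = sample_sfs(exp, 50.0, seed=2)
    assert np.array_equal(a.data, b.data)
    with pytest.raises(ValueError):
        sample_sfs(exp, -1.0, seed=1)
    # replicate mean of one cell ~ theta * cell within 4 SE
    cell = (1, 0)
    lam = 20.0 * exp.data[cell]
    draws = np.array([sample_sfs(exp, 20.0, seed=s).data[cell]
                      for s in range(400)])
    se = np.sqrt(lam / draws.size)
    assert abs(draws.mean() - lam) < 4 * se


def test_observation_noise_properties():
    ds = simulate_dataset(small_config(n_loci=10))
    noisy = add_observation_noise(ds, depth_mean=6.0, depth_dispersion=3.0,
                                  miss_rate=0.1, seed=5)
    depths = np.concatenate([l.depth.ravel() for l in noisy.loci])
    assert (depths < 12).mean() > 0.3          # depth 6 leaves many below 12x
    assert noisy.loci[0].truth_genotypes is not None
    # monotone map: higher depth never lowers GQ
    l0 = noisy.loci[0]
    order = np.argsort(l0.depth.ravel())
    assert (np.diff(l0.gq.ravel()[order]) >= 0).all()
    again = add_observation_noise(ds, 6.0, 3.0, 0.1, seed=5)
    assert np.array_equal(again.loci[0].depth, noisy.loci[0].depth)
    with pytest.raises(ValueError):
        add_observation_noise(ds, -1.0, 1.0, 0.0, seed=1)
    with pytest.raises(ValueError):
        add_observation_noise(ds, 5.0, 1.0, 1.5, seed=1)


def test_montecarlo_oracle_matches_neutral_closed_form():
    """The branch-length oracle reproduces theta/i for a single panmictic
    population (SI at T ~ 0) within Monte Carlo error."""
    mean, se = montecarlo_expected_sfs("SI", [1.0, 1.0, 1e-9], 4, 4,
                                       n_reps=4000, seed=9)
    marg = mean.data.sum(axis=1)[1:4]
    expect = 1.0 / np.arange(1, 4)
    assert np.allclose(marg, expect, rtol=0.1)
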