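"""Per-locus polymorphism and divergence statistics.

Computes, per locus and missing-data-aware: nucleotide diversity (pi),
Watterson's theta, Tajima's D for each species; F_ST (as ``1 - pi_S/pi_T``
with ``pi_S`` the mean within-species diversity and ``pi_T`` the pooled
diversity), mean (``d_XY``) and net (``d_A = d_XY - pi_S``) interspecific
divergence; and the counts of SNPs private to each species (Sx), shared
(Ss), and fixed between species (Sf).

All statistics are pairwise-difference based and therefore phase-free, so an
unphased diploid consensus (each individual contributing two chromosomes of
unknown phase) is a valid input.  Per-site computations use only the
chromosomes genotyped at that site; a site enters the per-locus denominator
when at least two chromosomes per species are genotyped there.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["LocusStats", "locus_stats", "classify_sites", "summarize_dataset"]

_MISSING = -1


@dataclass
class LocusStats:
    """Summary statistics for one locus (per-site scales unless noted)."""

    locus: str
    n_sites: int                  # denominator: analyzed sites with coverage
    pi_1: float | None
    pi_2: float | None
    thetaw_1: float | None
    thetaw_2: float | None
    tajima_d_1: float | None
    tajima_d_2: float | None
    fst: float | None
    dxy: float | None
    da: float | None
    sx1: int = 0
    sx2: int = 0
    ss: int = 0
    sf: int = 0

    def as_dict(self):
        return asdict(self)


def _allele_counts(chroms: np.ndarray) -> np.ndarray:
    """Per-site allele counts: (sites, 4) from a (sites, chromosomes) array."""
    return np.stack([(chroms == a).sum(axis=1) for a in range(4)], axis=1)


def _pairwise_pi(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site heterozygosity and sample size from allele counts.

    Returns ``(pi_site, n_site)`` where ``pi_site`` is the mean pairwise
    difference among the genotyped chromosomes (0 where fewer than 2).
    """
    n = counts.sum(axis=1)
    pairs = n * (n - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pairs > 0, 1.0 - same / np.where(pairs > 0, pairs, 1.0), 0.0)
    return pi, n


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n))) if n >= 2 else np.nan


def _tajima_d(S: int, pi_total: float, n: int) -> float | None:
    """Tajima's D from segregating sites, total pi and sample size.

    Uses the standard variance constants; undefined (None) when ``S == 0``
    or ``n < 2``.
    """
    if S == 0 or n < 2:
        return None
    a1 = _harmonic(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return None
    return float((pi_total - S / a1) / np.sqrt(var))


def classify_sites(genotypes: np.ndarray, species: np.ndarray,
                   labels: tuple[str, str] = ("Lv", "Lm")) -> tuple[int, int, int, int]:
    """Count biallelic SNPs private to species 1/2, shared, and fixed.

    ``genotypes``: (sites, individuals, 2) allele codes with -1 missing;
    monomorphic or >2-allele sites are excluded from all four counts.
    Returns ``(Sx1, Sx2, Ss, Sf)``.
    """
    chroms = genotypes.reshape(genotypes.shape[0], -1)
    sp_chrom = np.repeat(species, 2)
    c1 = _allele_counts(chroms[:, sp_chrom == labels[0]])
    c2 = _allele_counts(chroms[:, sp_chrom == labels[1]])
    tot = c1 + c2
    biallelic = (tot > 0).sum(axis=1) == 2
    poly1 = (c1 > 0).sum(axis=1) > 1
    poly2 = (c2 > 0).sum(axis=1) > 1
    mono_diff = (~poly1 & ~poly2
                 & (c1.sum(axis=1) > 0) & (c2.sum(axis=1) > 0)
                 & (np.argmax(c1, axis=1) != np.argmax(c2, axis=1)))
    sf = int(np.sum(biallelic & mono_diff))
    ss = int(np.sum(biallelic & poly1 & poly2))
    sx1 = int(np.sum(biallelic & poly1 & ~poly2))
    sx2 = int(np.sum(biallelic & poly2 & ~poly1))
    return sx1, sx2, ss, sf


def locus_stats(genotypes: np.ndarray, species: np.ndarray, locus: str = "",
                labels: tuple[str, str] = ("Lv", "Lm")) -> LocusStats:
    """Per-locus statistics from an unphased consensus alignment.

    ``genotypes``: (sites, individuals, 2) allele codes 0..3 with -1 for
    missing; ``species``: per-individual labels.  Sites already restricted
    to the analyzed class (e.g. synonymous).  Statistics are per analyzed
    site using the covered-site denominator; undefined statistics are None.
    """
    chroms = genotypes.reshape(genotypes.shape[0], -1)
    sp_chrom = np.repeat(species, 2)
    c1 = _allele_counts(chroms[:, sp_chrom == labels[0]])
    c2 = _allele_counts(chroms[:, sp_chrom == labels[1]])
    pi1_site, n1_site = _pairwise_pi(c1)
    pi2_site, n2_site = _pairwise_pi(c2)
    covered = (n1_site >= 2) & (n2_site >= 2)
    n_sites = int(covered.sum())
    if n_sites == 0:
        return LocusStats(locus, 0, *([None] * 9))

    out = {}
    seg_counts = {}
    for tag, (csp, pis, ns) in {
        "1": (c1, pi1_site, n1_site), "2": (c2, pi2_site, n2_site)
    }.items():
        pis = pis[covered]
        ns = ns[covered]
        csp = csp[covered]
        seg = (csp > 0).sum(axis=1) > 1
        S = int(seg.sum())
        a1_sites = np.array([_harmonic(int(n)) for n in ns])
        out[f"pi_{tag}"] = float(pis.mean())
        out[f"thetaw_{tag}"] = float(np.sum(seg / a1_sites) / n_sites)
        n_typ = int(np.median(ns))
        out[f"tajima_d_{tag}"] = _tajima_d(S, float(pis.sum()), n_typ)
        seg_counts[tag] = S

    # pooled and between-species quantities on covered sites
    cc1, cc2 = c1[covered], c2[covered]
    pool_pi, _ = _pairwise_pi(cc1 + cc2)
    pi_t = float(pool_pi.mean())
    pi_s = (out["pi_1"] + out["pi_2"]) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = cc1 / np.maximum(cc1.sum(axis=1, keepdims=True), 1)
        f2 = cc2 / np.maximum(cc2.sum(axis=1, keepdims=True), 1)
    dxy = float(np.mean(1.0 - (f1 * f2).sum(axis=1)))
    fst = None if pi_t == 0 else float(1.0 - pi_s / pi_t)

    cov_geno = genotypes[covered]
    sx1, sx2, ss, sf = classify_sites(cov_geno, species, labels)
    return LocusStats(locus, n_sites,
                      out["pi_1"], out["pi_2"],
                      out["thetaw_1"], out["thetaw_2"],
                      out["tajima_d_1"], out["tajima_d_2"],
                      fst, dxy, dxy - pi_s, sx1, sx2, ss, sf)


def summarize_dataset(stats: list[LocusStats]) -> dict:
    """Dataset-level summary: per-statistic mean +/- SD and SNP categories.

    Loci with an undefined value are skipped per statistic (their count is
    reported); the SD uses the n-1 denominator and is 0 for a single locus.
    SNP-category totals come with percentages of all classified SNPs.
    """
    if not stats:
        raise ValueError("no loci")
    frame = pd.DataFrame([s.as_dict() for s in stats])
    num_cols = ["pi_1", "pi_2", "thetaw_1", "thetaw_2",
                "tajima_d_1", "tajima_d_2", "fst", "dxy", "da"]
    rows = []
    for col in num_cols:
        vals = frame[col].dropna().astype(float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append({"statistic": col,
                     "mean": float(vals.mean()) if len(vals) else np.nan,
                     "sd": sd, "n_loci": int(len(vals))})
    cats = {c: int(frame[c].sum()) for c in ("sf", "ss", "sx1", "sx2")}
    total = sum(cats.values())
    pct = {c: (100.0 * v / total if total else np.nan) for c, v in cats.items()}
    return {"statistics": pd.DataFrame(rows),
            "snp_categories": cats,
            "snp_total": total,
            "snp_percent": pct}
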