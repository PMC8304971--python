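"""Simulation studies validating the scan's statistical behaviour.

Two reusable procedures:

* :func:`null_calibration` — type-I error and p-value uniformity of the
  four contrast tests on independent SNP pairs with pure-noise phenotypes;
* :func:`planted_pair_recovery` — whether a planted epistatic pair is
  recovered as the top-ranked hit of a genome-wide scan, with the correct
  effect type.

The planting rule deliberately targets common variants: on each of two
different chromosomes the SNP whose realized minor allele frequency is
nearest ``target_maf`` (default 0.3) receives the planted effect.  The
interaction contrasts weight double-homozygote cells, whose expected counts
scale with the product of squared allele frequencies, so a rare-by-rare
pair is non-estimable or powerless at any realistic sample size; a power
study therefore plants where all nine two-locus genotype classes are
populated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import agls_engine as engine
from .agls_engine import adjust_phenotype
from .scan import ScanConfig, run_scan
from .synthetic_data import SimConfig, plant_epistasis, simulate_genotypes, simulate_phenotypes


@dataclass
class NullCalibration:
    """Outcome of a pure-noise calibration run."""

    p_values: np.ndarray        # all estimable per-test p-values
    n_tests: int
    ks_statistic: float
    ks_pvalue: float
    alpha_prime: float
    n_rejected: int             # tests with p < alpha_prime
    type1_rate: float


def null_calibration(n_pairs: int = 10_000, n_individuals: int = 1_000,
                     seed: int = 0, maf_range=(0.05, 0.5),
                     alpha_prime: float = 1e-4) -> NullCalibration:
    """Contrast tests on independent null pairs with standard-normal noise.

    Each pair gets two independent Hardy-Weinberg SNPs with allele
    frequency uniform in ``maf_range`` and a fresh N(0,1) phenotype, so
    every estimable test statistic is exactly Student-t under the null.
    Returns the pooled estimable p-values with a Kolmogorov-Smirnov
    uniformity test and the rejection count at ``alpha_prime``.
    """
    rng = np.random.default_rng(seed)
    counts = np.empty((n_pairs, 9), dtype=np.int64)
    ysum = np.empty((n_pairs, 9))
    ysq = np.empty((n_pairs, 9))
    for i in range(n_pairs):
        f1, f2 = rng.uniform(*maf_range, size=2)
        g1 = rng.binomial(2, f1, size=n_individuals).astype(np.int8)
        g2 = rng.binomial(2, f2, size=n_individuals).astype(np.int8)
        y = rng.standard_normal(n_individuals)
        counts[i], ysum[i], ysq[i] = engine._cell_stats(y, g1, g2)
    res = engine.contrast_tests_block(counts, ysum, ysq)
    p = res["p"][res["estimable"]]
    ks = stats.kstest(p, "uniform")
    n_rej = int((p < alpha_prime).sum())
    return NullCalibration(
        p_values=p, n_tests=p.size, ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue), alpha_prime=alpha_prime,
        n_rejected=n_rej, type1_rate=n_rej / p.size)


@dataclass
class RecoveryOutcome:
    """One seed's planted-pair scan outcome."""

    seed: int
    planted_snps: tuple[str, str]
    planted_type: str
    top_snps: tuple[str, str]
    top_type: str
    top_log10_inv_p: float
    recovered: bool             # top pair is the planted pair with its type


def _plant_targets(panel, target_maf: float) -> tuple[int, int]:
    """SNP nearest target MAF, then the nearest on a different chromosome."""
    maf = panel.maf()
    chrom = np.asarray(panel.chrom, dtype=str)
    i = int(np.argmin(np.abs(maf - target_maf)))
    cand = np.flatnonzero(chrom != chrom[i])
    if cand.size == 0:
        raise ValueError("need at least two chromosomes to plant an inter pair")
    j = int(cand[np.argmin(np.abs(maf[cand] - target_maf))])
    return i, j


def planted_pair_recovery(effect_type: str, seed: int, *,
                          n_individuals: int = 5_000,
                          n_chromosomes: int = 10,
                          snps_per_chrom: int = 20,
                          effect_size: float = 0.5,
                          target_maf: float = 0.3,
                          ld_rho: float = 0.3) -> RecoveryOutcome:
    """Scan a panel with one planted pair; report whether it ranks first.

    The pair is planted at the two common variants chosen by the rule in
    the module docstring, with ``effect_size`` in residual-SD units, then
    the full genome-wide scan is run and the top record compared against
    the ground truth (both SNPs and the attributed effect type).
    """
    cfg = SimConfig(n_individuals=n_individuals, n_chromosomes=n_chromosomes,
                    snps_per_chrom=snps_per_chrom, seed=seed, ld_rho=ld_rho)
    panel = simulate_genotypes(cfg)
    i, j = _plant_targets(panel, target_maf)
    truth = plant_epistasis(panel, [(i, j, effect_type, effect_size)], seed,
                            n_sire_families=cfg.n_sire_families)
    records = simulate_phenotypes(panel, truth)
    y_adj = adjust_phenotype(records)
    result = run_scan(panel, y_adj, ScanConfig(k=10, n_traits=1),
                      trait_name=f"recovery_{effect_type}")
    top = result.records.iloc[0]
    planted = (panel.snp_ids[i], panel.snp_ids[j])
    top_pair = (top["snp1"], top["snp2"])
    recovered = (set(top_pair) == set(planted)
                 and top["effect_type"] == effect_type)
    return RecoveryOutcome(
        seed=seed, planted_snps=planted, planted_type=effect_type,
        top_snps=top_pair, top_type=str(top["effect_type"]),
        top_log10_inv_p=float(top["log10_inv_p"]), recovered=recovered)
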