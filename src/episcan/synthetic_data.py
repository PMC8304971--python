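"""Synthetic genotype/phenotype generator with planted epistatic pairs.

The generator emulates the statistical structure the pairwise scan relies
on, at configurable scale:

* biallelic SNPs on ~30 chromosomes (29 autosomes plus X, X treated as a
  30th autosome), minor allele frequencies in a configurable range with a
  0.05 floor by default;
* within-chromosome linkage disequilibrium from a first-order Markov chain
  over haplotype alleles, with allele frequencies following a slowly
  varying bounded random walk along the chromosome so the target
  adjacent-SNP correlation ``ld_rho`` is attainable at every step;
* Hardy-Weinberg genotypes (two independent haplotypes per individual);
* a polygenic additive value ``a`` with half-sib sire-family structure and
  a predicted-transmitting-ability (PTA) proxy of configurable
  reliability, so the scan's ``y - 2*PTA`` adjustment has something real
  to remove;
* planted epistatic SNP pairs whose 3x3 genotypic-value matrices are pure
  interaction surfaces (zero marginal additive and dominance main effects
  by construction).

Everything is reproducible from integer seeds via ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agls_engine import W_ADDITIVE, W_DOMINANCE, EFFECT_TYPES
from .io_formats import CHROMOSOME_ORDER, SnpPanel, TraitRecords

_W = {"A": W_ADDITIVE, "D": W_DOMINANCE}

#: Step of the along-chromosome allele-frequency random walk.
_FREQ_WALK_STEP = 0.015


@dataclass
class SimConfig:
    """Panel-generation parameters.

    Defaults give a small dairy-like panel: 30 chromosomes of 100 Mb, MAF in
    [0.05, 0.5], moderate adjacent-SNP LD, 25 half-sib sire families.
    """

    n_individuals: int = 2000
    n_chromosomes: int = 30
    snps_per_chrom: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3
    chrom_length_bp: int = 100_000_000
    n_sire_families: int = 25
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_individuals, self.n_chromosomes, self.snps_per_chrom,
               self.chrom_length_bp, self.n_sire_families) <= 0:
            raise ValueError("all counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_chromosomes > len(CHROMOSOME_ORDER):
            raise ValueError(f"at most {len(CHROMOSOME_ORDER)} chromosomes supported")


@dataclass
class PlantedPair:
    """One planted epistatic pair and its genotypic-value surface."""

    snp_i: int
    snp_j: int
    effect_type: str
    effect_size: float          # residual-SD units
    gmatrix: np.ndarray         # (3,3) trait-unit genotypic values


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    planted_pairs: list[PlantedPair]
    sigma2_a: float
    sigma2_e: float
    pta_reliability: float
    true_a: np.ndarray
    seed: int
    sire_family: np.ndarray = field(default=None)


def _frequency_walk(rng: np.random.Generator, m: int,
                    maf_range: tuple[float, float]) -> np.ndarray:
    """Reflecting random walk of allele frequencies within maf_range."""
    lo, hi = maf_range
    f = np.empty(m)
    f[0] = rng.uniform(lo, hi)
    steps = rng.normal(0.0, _FREQ_WALK_STEP, size=m - 1) if m > 1 else []
    for k in range(1, m):
        x = f[k - 1] + steps[k - 1]
        # reflect into [lo, hi]
        while x < lo or x > hi:
            if x < lo:
                x = 2 * lo - x
            else:
                x = 2 * hi - x
        f[k] = x
    return f


def _markov_haplotypes(rng: np.random.Generator, n_hap: int,
                       freqs: np.ndarray, rho: float) -> np.ndarray:
    """First-order Markov haplotypes with adjacent-allele correlation rho.

    Conditional allele probabilities are chosen so both the marginal
    frequency of every SNP and the adjacent correlation are exact (up to
    clipping, which the frequency walk makes rare).
    """
    m = len(freqs)
    h = np.empty((n_hap, m), dtype=np.int8)
    h[:, 0] = rng.random(n_hap) < freqs[0]
    for k in range(1, m):
        fp, fk = freqs[k - 1], freqs[k]
        d = rho * np.sqrt(fp * (1 - fp) * fk * (1 - fk))
        p_given1 = np.clip(fk + d / fp, 0.0, 1.0)
        p_given0 = np.clip(fk - d / (1 - fp), 0.0, 1.0)
        prob = np.where(h[:, k - 1] == 1, p_given1, p_given0)
        h[:, k] = rng.random(n_hap) < prob
    return h


def simulate_genotypes(cfg: SimConfig) -> SnpPanel:
    """Generate a sorted, validated genotype panel from the config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    chroms, positions, snp_ids, geno_cols = [], [], [], []
    for c in range(cfg.n_chromosomes):
        label = CHROMOSOME_ORDER[c]
        freqs = _frequency_walk(rng, cfg.snps_per_chrom, cfg.maf_range)
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=cfg.snps_per_chrom,
                                 replace=False)) + 1
        hap = _markov_haplotypes(rng, 2 * n, freqs, cfg.ld_rho)
        g = hap[:n] + hap[n:]
        geno_cols.append(g.astype(np.int8))
        chroms.extend([label] * cfg.snps_per_chrom)
        positions.append(pos)
        snp_ids.extend(f"chr{label}_snp{k:04d}" for k in range(cfg.snps_per_chrom))
    panel = SnpPanel(
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.concatenate(positions).astype(np.int64),
        genotypes=np.concatenate(geno_cols, axis=1),
        counted_allele=["B"] * (cfg.n_chromosomes * cfg.snps_per_chrom),
        individual_ids=[f"ind{i:06d}" for i in range(n)],
    )
    panel.validate()
    return panel


def epistasis_value_matrix(effect_type: str, effect_size: float,
                           sigma2_e: float = 1.0) -> np.ndarray:
    """Pure-interaction 3x3 genotypic-value matrix for one planted pair.

    The matrix is ``effect_size * sqrt(sigma2_e) * outer(w1, w2)`` with the
    additive/dominance basis contrasts at each locus, so the effect size is
    expressed in residual standard deviations and the surface has zero
    marginal main effects at both loci.
    """
    if effect_type not in EFFECT_TYPES:
        raise ValueError(f"unknown effect type {effect_type!r}")
    w1, w2 = _W[effect_type[0]], _W[effect_type[1]]
    return effect_size * np.sqrt(sigma2_e) * np.outer(w1, w2)


def _resolve_snp(panel: SnpPanel, snp) -> int:
    if isinstance(snp, (int, np.integer)):
        if not 0 <= snp < panel.n_snps:
            raise ValueError(f"SNP index {snp} out of range")
        return int(snp)
    try:
        return panel.snp_ids.index(snp)
    except ValueError:
        raise ValueError(f"SNP id {snp!r} not in panel") from None


def plant_epistasis(panel: SnpPanel, specs, seed: int, *,
                    sigma2_a: float = 0.5, sigma2_e: float = 1.0,
                    pta_reliability: float = 0.6,
                    n_sire_families: int = 25) -> SimTruth:
    """Build simulation ground truth: planted pairs plus the polygenic layer.

    ``specs`` is an iterable of ``(snp_i, snp_j, effect_type, effect_size)``
    with SNPs given by panel index or id and effect sizes in residual-SD
    units.  The polygenic values use a half-sib family structure: sire
    breeding values contribute a quarter of ``sigma2_a``, the Mendelian/dam
    term the rest.
    """
    if sigma2_a < 0 or sigma2_e <= 0:
        raise ValueError("need sigma2_a >= 0 and sigma2_e > 0")
    if not 0.0 <= pta_reliability <= 1.0:
        raise ValueError("pta_reliability must be in [0, 1]")
    planted: list[PlantedPair] = []
    seen = set()
    for snp_i, snp_j, effect_type, effect_size in specs:
        i, j = _resolve_snp(panel, snp_i), _resolve_snp(panel, snp_j)
        if i == j:
            raise ValueError("planted pair must involve two distinct SNPs")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate planted pair {key}")
        seen.add(key)
        planted.append(PlantedPair(
            snp_i=i, snp_j=j, effect_type=effect_type, effect_size=effect_size,
            gmatrix=epistasis_value_matrix(effect_type, effect_size, sigma2_e)))

    rng = np.random.default_rng([seed, 101])
    n = panel.n_individuals
    family = np.arange(n) % n_sire_families
    sire_bv = rng.normal(0.0, np.sqrt(sigma2_a), size=n_sire_families)
    mendelian = rng.normal(0.0, np.sqrt(0.75 * sigma2_a), size=n)
    true_a = sire_bv[family] / 2.0 + mendelian
    return SimTruth(planted_pairs=planted, sigma2_a=sigma2_a, sigma2_e=sigma2_e,
                    pta_reliability=pta_reliability, true_a=true_a, seed=seed,
                    sire_family=family)


def simulate_phenotypes(panel: SnpPanel, truth: SimTruth,
                        trait_name: str = "sim_trait",
                        mu: float = 0.0) -> TraitRecords:
    """Draw phenotype and PTA records from a panel and its ground truth.

    The phenotype is ``y = mu + sum of planted genotypic values + a + e``;
    the PTA proxy satisfies ``corr(pta, a/2)^2 = pta_reliability`` by
    construction (reliability 1 makes ``y - 2*pta`` remove ``a`` exactly).
    """
    if len(truth.true_a) != panel.n_individuals:
        raise ValueError("truth not consistent with panel size")
    rng = np.random.default_rng([truth.seed, 202])
    n = panel.n_individuals
    y = np.full(n, mu, dtype=float)
    for pair in truth.planted_pairs:
        g1 = panel.genotypes[:, pair.snp_i]
        g2 = panel.genotypes[:, pair.snp_j]
        ok = (g1 >= 0) & (g2 >= 0)
        y[ok] += pair.gmatrix[g1[ok], g2[ok]]
    y += truth.true_a
    y += rng.normal(0.0, np.sqrt(truth.sigma2_e), size=n)

    r2 = truth.pta_reliability
    half_a = truth.true_a / 2.0
    noise_var = r2 * (1.0 - r2) * truth.sigma2_a / 4.0
    pta = r2 * half_a + rng.normal(0.0, np.sqrt(noise_var), size=n)
    rec = TraitRecords(individual_ids=list(panel.individual_ids),
                       y=y, pta=pta, trait_name=trait_name)
    rec.validate()
    return rec


def simulate_dataset(cfg: SimConfig, specs=(), **truth_kwargs):
    """Convenience: panel, truth and records in one call, all from cfg.seed."""
    panel = simulate_genotypes(cfg)
    truth = plant_epistasis(panel, specs, cfg.seed,
                            n_sire_families=cfg.n_sire_families, **truth_kwargs)
    records = simulate_phenotypes(panel, truth)
    return panel, truth, records
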