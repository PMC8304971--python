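"""Genome-wide pairwise scan: enumeration, thresholds, top-K ranking, summaries.

The scan evaluates all unordered SNP pairs (optionally restricted to a SNP
subset), runs the four epistasis contrast tests per pair, and keeps the K
pairs with the largest best-contrast significance.  Significance is
declared against a Bonferroni threshold over the full design's test count
(pairs x effect types x traits).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agls_engine as engine
from .agls_engine import AdjustedTrait
from .io_formats import SnpPanel, chrom_sort_key

logger = logging.getLogger(__name__)

FOUR_MEGABASES = 4_000_000


def count_pairs(n_snps: int) -> int:
    """Number of unordered SNP pairs, C(n_snps, 2)."""
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    return n_snps * (n_snps - 1) // 2


def count_total_tests(n_snps: int, n_effect_types: int = 4,
                      n_traits: int = 1) -> int:
    """Total test count of the design: pairs x effect types x traits."""
    if min(n_effect_types, n_traits) < 1:
        raise ValueError("counts must be positive")
    return count_pairs(n_snps) * n_effect_types * n_traits


@dataclass
class ThresholdSpec:
    """Bonferroni threshold for a given genome-wide false-positive rate."""

    alpha: float
    n_tests: int
    p_threshold: float
    log10_threshold: float
    n_snps: int | None = None
    n_effect_types: int | None = None
    n_traits: int | None = None


def bonferroni_threshold(alpha: float, n_tests: int, **design) -> ThresholdSpec:
    """Per-test p threshold alpha/n_tests and its log10(1/p) scale value."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return ThresholdSpec(
        alpha=alpha, n_tests=n_tests, p_threshold=alpha / n_tests,
        log10_threshold=math.log10(n_tests / alpha), **design)


def design_threshold(n_snps: int, alpha: float = 0.05,
                     n_effect_types: int = 4, n_traits: int = 8) -> ThresholdSpec:
    """Bonferroni threshold for a full scan design (defaults: 4 types, 8 traits)."""
    n_tests = count_total_tests(n_snps, n_effect_types, n_traits)
    return bonferroni_threshold(alpha, n_tests, n_snps=n_snps,
                                n_effect_types=n_effect_types, n_traits=n_traits)


def count_intra_inter(panel: SnpPanel):
    """Intra-/inter-chromosome pair counts and percentages for a panel."""
    if panel.n_snps < 2:
        raise ValueError("panel needs at least 2 SNPs")
    _, sizes = np.unique(np.asarray(panel.chrom, dtype=str), return_counts=True)
    n_intra = int(sum(m * (m - 1) // 2 for m in sizes))
    total = count_pairs(panel.n_snps)
    n_inter = total - n_intra
    return n_intra, n_inter, 100.0 * n_intra / total, 100.0 * n_inter / total


@dataclass
class ScanConfig:
    """Scan options: top-K size, threshold design, optional SNP subset."""

    k: int = 50_000
    alpha: float = 0.05
    n_effect_types: int = 4
    n_traits: int = 8
    snp_indices: np.ndarray | None = None   # restrict the scan to these SNPs
    block_elements: int = 4_000_000         # workspace cap for the block kernel


@dataclass
class ScanResult:
    """Ranked top-K pairs of one trait's scan."""

    trait_name: str
    records: pd.DataFrame
    threshold: ThresholdSpec
    n_pairs_tested: int
    n_skipped_degenerate: int
    k: int
    n_significant: int = 0
    per_type_columns: tuple = field(
        default=("log10_aa", "log10_ad", "log10_da", "log10_dd"))


_RECORD_COLUMNS = [
    "rank", "snp1", "chrom1", "pos1", "snp2", "chrom2", "pos2",
    "effect_type", "L", "t", "p", "log10_inv_p",
    "log10_aa", "log10_ad", "log10_da", "log10_dd", "intra", "within_4mb",
]


def _order_candidates(cand: dict) -> np.ndarray:
    """Deterministic ranking: log10 desc, then map position lexicographic."""
    return np.lexsort((cand["pos2"], cand["c2rank"], cand["pos1"],
                       cand["c1rank"], -cand["log10_inv_p"]))


def run_scan(panel: SnpPanel, y_adj: AdjustedTrait,
             cfg: ScanConfig | None = None,
             trait_name: str = "trait") -> ScanResult:
    """Scan all unordered SNP pairs and keep the top-K by best contrast.

    Each pair is ranked by the maximum log10(1/p) over its estimable
    contrasts and attributed that arg-max effect type (ties broken in
    AA, AD, DA, DD order).  Pairs with no residual degrees of freedom or no
    estimable contrast are skipped and tallied, never fatal.  Individuals
    are matched to the panel by id (inner join, panel order).
    """
    cfg = cfg or ScanConfig()
    if panel.n_snps < 2:
        raise ValueError("panel needs at least 2 SNPs")

    if list(y_adj.individual_ids) == list(panel.individual_ids):
        y = np.asarray(y_adj.y_adj, dtype=float)
        G = panel.genotypes
    else:
        lookup = {ind: i for i, ind in enumerate(y_adj.individual_ids)}
        rows = [(i, lookup[ind]) for i, ind in enumerate(panel.individual_ids)
                if ind in lookup]
        if not rows:
            raise ValueError("no individuals shared between panel and phenotype")
        pi, yi = map(np.asarray, zip(*rows))
        y = np.asarray(y_adj.y_adj, dtype=float)[yi]
        G = panel.genotypes[pi]

    idx = (np.arange(panel.n_snps) if cfg.snp_indices is None
           else np.asarray(cfg.snp_indices))
    m = len(idx)
    chrom = np.asarray(panel.chrom, dtype=str)[idx]
    crank = np.array([chrom_sort_key(c) for c in chrom], dtype=np.int64)
    pos = panel.pos_bp[idx]
    G = G[:, idx]
    n = G.shape[0]
    block_cols = max(1, cfg.block_elements // max(n, 1))

    threshold = design_threshold(panel.n_snps, cfg.alpha,
                                 cfg.n_effect_types, cfg.n_traits)

    pool: dict[str, np.ndarray] | None = None
    n_tested = 0
    n_skipped = 0
    n_significant = 0

    for a in range(m - 1):
        for b0 in range(a + 1, m, block_cols):
            b1 = min(b0 + block_cols, m)
            counts, ysum, ysq = engine.pair_block_stats(G[:, a], G[:, b0:b1], y)
            res = engine.contrast_tests_block(counts, ysum, ysq)
            nblk = b1 - b0
            n_tested += nblk
            any_est = res["estimable"].any(axis=1)
            n_skipped += int((~any_est).sum())
            if not any_est.any():
                continue
            log10p = np.where(res["estimable"], res["log10_inv_p"], -np.inf)
            best_j = np.argmax(log10p, axis=1)
            sel = np.flatnonzero(any_est)
            bj = best_j[sel]
            best_log10 = log10p[sel, bj]
            n_significant += int((best_log10 > threshold.log10_threshold).sum())
            cand = {
                "i1": np.full(len(sel), idx[a], dtype=np.int64),
                "i2": idx[b0 + sel].astype(np.int64),
                "c1rank": np.full(len(sel), crank[a], dtype=np.int64),
                "c2rank": crank[b0 + sel],
                "pos1": np.full(len(sel), pos[a], dtype=np.int64),
                "pos2": pos[b0 + sel],
                "best_j": bj,
                "log10_inv_p": best_log10,
                "L": res["L"][sel, bj],
                "t": res["t"][sel, bj],
                "p": res["p"][sel, bj],
            }
            for j, col in enumerate(("log10_aa", "log10_ad", "log10_da", "log10_dd")):
                cand[col] = np.where(res["estimable"][sel, j],
                                     res["log10_inv_p"][sel, j], np.nan)
            if pool is None:
                pool = cand
            else:
                pool = {key: np.concatenate([pool[key], cand[key]]) for key in pool}
            if len(pool["log10_inv_p"]) > 4 * cfg.k:
                order = _order_candidates(pool)[: cfg.k]
                pool = {key: val[order] for key, val in pool.items()}
        if (a + 1) % 50 == 0:
            logger.info("scan %s: left SNP %d/%d, %d pairs tested",
                        trait_name, a + 1, m, n_tested)

    if pool is None:
        records = pd.DataFrame(columns=_RECORD_COLUMNS)
    else:
        order = _order_candidates(pool)[: cfg.k]
        pool = {key: val[order] for key, val in pool.items()}
        i1, i2 = pool["i1"], pool["i2"]
        chrom_all = np.asarray(panel.chrom, dtype=str)
        effect = np.array(engine.EFFECT_TYPES, dtype=object)[pool["best_j"]]
        intra = chrom_all[i1] == chrom_all[i2]
        records = pd.DataFrame({
            "rank": np.arange(1, len(i1) + 1),
            "snp1": [panel.snp_ids[i] for i in i1],
            "chrom1": chrom_all[i1],
            "pos1": panel.pos_bp[i1],
            "snp2": [panel.snp_ids[i] for i in i2],
            "chrom2": chrom_all[i2],
            "pos2": panel.pos_bp[i2],
            "effect_type": effect,
            "L": pool["L"],
            "t": pool["t"],
            "p": pool["p"],
            "log10_inv_p": pool["log10_inv_p"],
            "log10_aa": pool["log10_aa"],
            "log10_ad": pool["log10_ad"],
            "log10_da": pool["log10_da"],
            "log10_dd": pool["log10_dd"],
            "intra": intra,
            "within_4mb": intra & (np.abs(panel.pos_bp[i1] - panel.pos_bp[i2])
                                   < FOUR_MEGABASES),
        })
    logger.info("scan %s: %d pairs tested, %d skipped, %d significant "
                "(log10 threshold %.2f)", trait_name, n_tested, n_skipped,
                n_significant, threshold.log10_threshold)
    return ScanResult(trait_name=trait_name, records=records,
                      threshold=threshold, n_pairs_tested=n_tested,
                      n_skipped_degenerate=n_skipped, k=cfg.k,
                      n_significant=n_significant)


def summarize(scan: ScanResult):
    """Intra/inter and effect-type summary tables of a scan's top-K records.

    Returns ``(table_a, table_b)``: table A gives per intra/inter class the
    frequency (% of records), min-max log10(1/p) and count at or above the
    Bonferroni threshold; table B cross-tabulates the attributed effect
    type (AA, AD+DA pooled, DD) by intra/inter, with percentages of the
    record total.
    """
    df = scan.records
    n_rec = len(df)
    thr = scan.threshold.log10_threshold
    rows_a = []
    for label, mask in (("intra", df["intra"]), ("inter", ~df["intra"])):
        sub = df[mask]
        rows_a.append({
            "class": label,
            "count": len(sub),
            "freq_pct": 100.0 * len(sub) / n_rec if n_rec else 0.0,
            "log10_min": sub["log10_inv_p"].min() if len(sub) else np.nan,
            "log10_max": sub["log10_inv_p"].max() if len(sub) else np.nan,
            "n_significant": int((sub["log10_inv_p"] >= thr).sum()),
        })
    table_a = pd.DataFrame(rows_a).set_index("class")

    groups = {"AA": ("AA",), "AD+DA": ("AD", "DA"), "DD": ("DD",)}
    rows_b = []
    for label, mask in (("intra", df["intra"]), ("inter", ~df["intra"])):
        sub = df[mask]
        row = {"class": label}
        for gname, types in groups.items():
            cnt = int(sub["effect_type"].isin(types).sum())
            row[f"{gname}_count"] = cnt
            row[f"{gname}_pct"] = 100.0 * cnt / n_rec if n_rec else 0.0
        rows_b.append(row)
    table_b = pd.DataFrame(rows_b).set_index("class")
    return table_a, table_b
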