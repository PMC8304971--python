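"""Readers and writers for genotype panels, trait records and scan results.

Two genotype dialects are supported:

``tsv_matrix``
    A self-contained tab-separated matrix, individuals in rows and SNPs in
    columns, with three leading comment lines carrying the SNP map::

        #chrom  14      5
        #pos    1200    88000
        #allele A       B
        id      snp_1   snp_2
        cow001  0       2
        cow002  1       NA

``plink_raw``
    PLINK ``--recode A`` output (``FID IID PAT MAT SEX PHENOTYPE`` followed
    by one ``<snp>_<allele>`` column per SNP, additive 0/1/2 coding), with a
    companion ``.bim``-style 6-column map file giving chromosome and bp
    position per SNP.

Phenotypes are long-format TSV with columns ``id``, ``trait``, ``y``
(yield deviation) and ``pta`` (predicted transmitting ability).

All text is UTF-8, tab-separated, ``.`` decimal.  Missing genotype tokens
``NA``, ``-9`` and the empty string map to the in-memory sentinel
:data:`MISSING` (-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in the int8 genotype matrix.
MISSING = np.int8(-1)

#: Tokens read as a missing genotype.
MISSING_TOKENS = frozenset({"NA", "-9", "", "nan", "NaN"})

#: Chromosome display/sort order: bovine autosomes 1-29 followed by X.
CHROMOSOME_ORDER = tuple(str(i) for i in range(1, 30)) + ("X",)

_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOME_ORDER)}


class ParseError(ValueError):
    """A malformed value in an input file (names the offending row/column)."""


class ConsistencyError(ValueError):
    """Inputs that parse but contradict each other (e.g. SNP missing from map)."""


def chrom_sort_key(label: str) -> int:
    """Rank of a chromosome label in the canonical 1..29, X ordering.

    Labels outside the canonical set sort after X, alphabetically, so that
    non-bovine maps still order deterministically.
    """
    label = str(label)
    if label in _CHROM_RANK:
        return _CHROM_RANK[label]
    return len(CHROMOSOME_ORDER) + sum(ord(ch) for ch in label)


@dataclass
class SnpPanel:
    """A genotype matrix with its SNP map.

    Genotypes count copies of ``counted_allele`` (0/1/2) with -1 for
    missing.  SNPs are kept sorted by (chromosome, position);
    ``source_order`` records each (sorted) SNP's column index in the file
    it was read from, so the original layout is recoverable.
    """

    snp_ids: list[str]
    chrom: np.ndarray          # str per SNP
    pos_bp: np.ndarray         # int64, 1-based
    genotypes: np.ndarray      # (n_individuals, n_snps) int8
    counted_allele: list[str]
    individual_ids: list[str]
    source_order: np.ndarray | None = field(default=None)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing genotypes."""
        g = self.genotypes
        valid = g >= 0
        with np.errstate(invalid="ignore"):
            freq = np.where(valid, g, 0).sum(axis=0) / (2.0 * valid.sum(axis=0))
        return np.minimum(freq, 1.0 - freq)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        n, m = self.genotypes.shape
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos_bp)
                == len(self.counted_allele) == m):
            raise ValueError("SNP metadata length does not match genotype columns")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match genotype rows")
        if np.any(self.pos_bp <= 0):
            raise ValueError("pos_bp must be strictly positive")
        g = self.genotypes
        if g.min(initial=0) < -1 or g.max(initial=0) > 2:
            raise ValueError("genotypes must be in {0,1,2} or missing (-1)")
        keys = [(chrom_sort_key(c), p) for c, p in zip(self.chrom, self.pos_bp)]
        if keys != sorted(keys):
            raise ValueError("SNPs not sorted by (chromosome, position)")

    def subset_snps(self, idx: np.ndarray) -> "SnpPanel":
        idx = np.asarray(idx)
        return SnpPanel(
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            genotypes=self.genotypes[:, idx],
            counted_allele=[self.counted_allele[i] for i in idx],
            individual_ids=list(self.individual_ids),
            source_order=None if self.source_order is None else self.source_order[idx],
        )


@dataclass
class TraitRecords:
    """Per-individual yield deviation and PTA for one trait."""

    individual_ids: list[str]
    y: np.ndarray
    pta: np.ndarray
    trait_name: str

    def validate(self) -> None:
        if not (len(self.individual_ids) == len(self.y) == len(self.pta)):
            raise ValueError("y/pta length does not match individual_ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual id in trait records")


def sort_panel(panel: SnpPanel) -> SnpPanel:
    """Return the panel with SNPs stably sorted by (chromosome, position)."""
    keys = np.array([chrom_sort_key(c) for c in panel.chrom], dtype=np.int64)
    order = np.lexsort((np.arange(panel.n_snps), panel.pos_bp, keys))
    out = panel.subset_snps(order)
    out.source_order = (np.arange(panel.n_snps)[order]
                        if panel.source_order is None
                        else panel.source_order[order])
    return out


def _parse_genotype_block(tokens: list[list[str]], snp_ids: list[str],
                          row_ids: list[str]) -> np.ndarray:
    g = np.empty((len(tokens), len(snp_ids)), dtype=np.int8)
    for i, row in enumerate(tokens):
        for j, tok in enumerate(row):
            if tok in MISSING_TOKENS:
                g[i, j] = MISSING
            elif tok in ("0", "1", "2"):
                g[i, j] = np.int8(int(tok))
            else:
                raise ParseError(
                    f"malformed genotype token {tok!r} for individual "
                    f"{row_ids[i]!r}, SNP {snp_ids[j]!r}"
                )
    return g


def _apply_maf_floor(panel: SnpPanel, maf_floor: float) -> SnpPanel:
    if maf_floor <= 0:
        return panel
    keep = panel.maf() >= maf_floor
    dropped = int((~keep).sum())
    if dropped:
        logger.info("MAF filter (floor %.3f) removed %d of %d SNPs",
                    maf_floor, dropped, panel.n_snps)
        panel = panel.subset_snps(np.flatnonzero(keep))
    return panel


def read_genotypes(path, dialect: str = "tsv_matrix", map_path=None,
                   maf_floor: float = 0.05) -> SnpPanel:
    """Read a genotype panel in the ``tsv_matrix`` or ``plink_raw`` dialect.

    SNPs are re-sorted by (chromosome, position); the original column order
    is recorded in ``source_order``.  SNPs with MAF below ``maf_floor`` are
    dropped (pass 0 to keep everything).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv_matrix":
        panel = _read_tsv_matrix(path)
    elif dialect == "plink_raw":
        panel = _read_plink_raw(path, map_path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    panel = sort_panel(panel)
    panel = _apply_maf_floor(panel, maf_floor)
    panel.validate()
    return panel


def _read_tsv_matrix(path: Path) -> SnpPanel:
    header: dict[str, list[str]] = {}
    rows: list[list[str]] = []
    row_ids: list[str] = []
    snp_ids: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0].startswith("#"):
                header[fields[0][1:]] = fields[1:]
            elif snp_ids is None:
                if fields[0] != "id":
                    raise ParseError(f"{path}: expected 'id' header row, got {fields[0]!r}")
                snp_ids = fields[1:]
            else:
                row_ids.append(fields[0])
                rows.append(fields[1:])
    if snp_ids is None:
        raise ParseError(f"{path}: no header row")
    for key in ("chrom", "pos"):
        if key not in header:
            raise ConsistencyError(f"{path}: missing '#{key}' map line")
        if len(header[key]) != len(snp_ids):
            raise ConsistencyError(f"{path}: '#{key}' length != number of SNP columns")
    alleles = header.get("allele", ["A"] * len(snp_ids))
    g = _parse_genotype_block(rows, snp_ids, row_ids)
    try:
        pos = np.array([int(p) for p in header["pos"]], dtype=np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer position in '#pos': {exc}") from exc
    return SnpPanel(snp_ids=snp_ids, chrom=np.array(header["chrom"], dtype=object),
                    pos_bp=pos, genotypes=g, counted_allele=list(alleles),
                    individual_ids=row_ids)


_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path: Path, map_path) -> SnpPanel:
    if map_path is None:
        for suffix in (".bim", ".map"):
            cand = path.with_suffix(suffix)
            if cand.exists():
                map_path = cand
                break
        else:
            raise ConsistencyError(f"no companion .bim/.map file found for {path}")
    bim = pd.read_csv(map_path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str})
    chrom_of = dict(zip(bim["snp"], bim["chrom"]))
    pos_of = dict(zip(bim["snp"], bim["pos"].astype(np.int64)))

    with open(path, encoding="utf-8") as fh:
        head = fh.readline().split()
        if tuple(head[:6]) != _PLINK_META:
            raise ParseError(f"{path}: not a PLINK .raw header")
        snp_ids, alleles = [], []
        for col in head[6:]:
            snp, _, allele = col.rpartition("_")
            if not snp:
                raise ParseError(f"{path}: SNP column {col!r} lacks '_<allele>' suffix")
            snp_ids.append(snp)
            alleles.append(allele)
        rows, row_ids = [], []
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            row_ids.append(fields[1])   # IID
            rows.append(fields[6:])
    missing = [s for s in snp_ids if s not in chrom_of]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} SNPs in {path} absent from map {map_path} "
            f"(first: {missing[0]!r})")
    g = _parse_genotype_block(rows, snp_ids, row_ids)
    return SnpPanel(
        snp_ids=snp_ids,
        chrom=np.array([chrom_of[s] for s in snp_ids], dtype=object),
        pos_bp=np.array([pos_of[s] for s in snp_ids], dtype=np.int64),
        genotypes=g, counted_allele=alleles, individual_ids=row_ids)


def write_genotypes(panel: SnpPanel, path) -> None:
    """Write a panel in the ``tsv_matrix`` dialect (lossless round-trip)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chrom\t" + "\t".join(str(c) for c in panel.chrom) + "\n")
        fh.write("#pos\t" + "\t".join(str(p) for p in panel.pos_bp) + "\n")
        fh.write("#allele\t" + "\t".join(panel.counted_allele) + "\n")
        fh.write("id\t" + "\t".join(panel.snp_ids) + "\n")
        for i, ind in enumerate(panel.individual_ids):
            row = ("NA" if v < 0 else str(int(v)) for v in panel.genotypes[i])
            fh.write(ind + "\t" + "\t".join(row) + "\n")


def read_phenotypes(path, trait: str) -> TraitRecords:
    """Read one trait's records from a long-format phenotype TSV.

    Rows with missing ``y`` are dropped (count reported in the log); a
    missing ``pta`` is treated as 0 adjustment would be wrong, so those rows
    are dropped too.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "trait": str})
    required = {"id", "trait", "y", "pta"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: phenotype file must have columns {sorted(required)}")
    sub = df[df["trait"] == trait]
    if sub.empty:
        available = sorted(df["trait"].unique())
        raise ValueError(f"trait {trait!r} not in {path}; available: {available}")
    ok = sub["y"].notna() & sub["pta"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d records with missing y/pta for trait %s",
                    n_dropped, trait)
    sub = sub[ok]
    rec = TraitRecords(individual_ids=list(sub["id"]),
                       y=sub["y"].to_numpy(dtype=float),
                       pta=sub["pta"].to_numpy(dtype=float),
                       trait_name=trait)
    rec.validate()
    return rec


def write_phenotypes(records: TraitRecords | list[TraitRecords], path) -> None:
    if isinstance(records, TraitRecords):
        records = [records]
    frames = [
        pd.DataFrame({"id": r.individual_ids, "trait": r.trait_name,
                      "y": r.y, "pta": r.pta})
        for r in records
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.17g")


def align(panel: SnpPanel, records: TraitRecords):
    """Inner-join panel individuals with trait records, panel order preserved.

    Returns ``(row_idx, y, pta)`` where ``row_idx`` indexes panel rows.
    """
    lookup = {ind: i for i, ind in enumerate(records.individual_ids)}
    rows, recs = [], []
    for i, ind in enumerate(panel.individual_ids):
        j = lookup.get(ind)
        if j is not None:
            rows.append(i)
            recs.append(j)
    rows = np.asarray(rows, dtype=np.intp)
    recs = np.asarray(recs, dtype=np.intp)
    return rows, records.y[recs], records.pta[recs]


RESULT_COLUMNS = ["rank", "snp1", "chrom1", "pos1", "snp2", "chrom2", "pos2",
                  "effect_type", "L", "t", "p", "log10_inv_p", "intra_inter"]


def write_results(scan, path) -> None:
    """Write a scan's ranked pair table as TSV (rank ascending).

    Numeric fields are written at full double precision so a write/read
    round trip is value-identical.
    """
    df = scan.records
    out = pd.DataFrame({
        "rank": df["rank"], "snp1": df["snp1"], "chrom1": df["chrom1"],
        "pos1": df["pos1"], "snp2": df["snp2"], "chrom2": df["chrom2"],
        "pos2": df["pos2"], "effect_type": df["effect_type"], "L": df["L"],
        "t": df["t"], "p": df["p"], "log10_inv_p": df["log10_inv_p"],
        "intra_inter": np.where(df["intra"], "intra", "inter"),
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    """Read a results TSV back into a frame (adds the boolean intra flag)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: results file missing columns {sorted(missing)}")
    df["intra"] = df["intra_inter"] == "intra"
    return df
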