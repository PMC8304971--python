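"""Manhattan and circular (chord) views of pairwise epistasis scans.

Two idioms:

* :func:`manhattan_pairs` — each top-K pair contributes two points, one at
  each SNP's cumulative genome coordinate, at height log10(1/p) of the
  pair's best contrast, with a horizontal genome-wide threshold line.
* :func:`circos_pairs` — chromosomes as arcs of a circle sized by bp
  length, one chord per pair; in genome mode chords are red when
  intra-chromosome and blue when inter-chromosome, in single-chromosome
  mode red when the two SNPs are closer than 4 Mb and blue otherwise.

Rendering is deterministic: no jitter, fixed ordering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath

from .io_formats import chrom_sort_key

logger = logging.getLogger(__name__)

FOUR_MEGABASES = 4_000_000

PLOT_KINDS = ("manhattan_intra", "manhattan_inter",
              "circos_genome", "circos_chromosome")


@dataclass
class PlotSpec:
    kind: str
    out_path: str
    threshold_line: float = 12.27
    image_format: str = "png"
    chromosome: str | None = None     # circos_chromosome mode
    colors: dict = field(default_factory=lambda: {"intra_4mb": "red",
                                                  "other": "blue"})

    def validate(self):
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}")
        if self.threshold_line < 0:
            raise ValueError("threshold_line must be >= 0")
        if self.kind == "circos_chromosome" and self.chromosome is None:
            raise ValueError("circos_chromosome mode needs a chromosome")


def chromosome_lengths(records: pd.DataFrame) -> dict[str, int]:
    """Per-chromosome length proxy: max observed bp position in the records."""
    lengths: dict[str, int] = {}
    for ccol, pcol in (("chrom1", "pos1"), ("chrom2", "pos2")):
        for c, p in zip(records[ccol].astype(str), records[pcol]):
            lengths[c] = max(lengths.get(c, 0), int(p))
    return lengths


def genome_offsets(lengths: dict[str, int]) -> dict[str, int]:
    """Cumulative bp offset of each chromosome in canonical order."""
    offsets, acc = {}, 0
    for c in sorted(lengths, key=chrom_sort_key):
        offsets[c] = acc
        acc += lengths[c]
    return offsets


def genome_coordinate(chrom, pos, offsets) -> float:
    return offsets[str(chrom)] + float(pos)


def _records(scan) -> pd.DataFrame:
    return scan if isinstance(scan, pd.DataFrame) else scan.records


def manhattan_pairs(scan, spec: PlotSpec, lengths: dict[str, int] | None = None):
    """Manhattan plot of pair significance; returns the output path."""
    spec.validate()
    df = _records(scan)
    if spec.kind == "manhattan_intra":
        df = df[df["intra"]]
    elif spec.kind == "manhattan_inter":
        df = df[~df["intra"]]
    else:
        raise ValueError(f"{spec.kind!r} is not a manhattan kind")
    fig, ax = plt.subplots(figsize=(10, 4))
    if df.empty:
        logger.warning("manhattan: no records to plot for kind %s", spec.kind)
    else:
        lengths = lengths or chromosome_lengths(_records(scan))
        offsets = genome_offsets(lengths)
        chroms = sorted(offsets, key=chrom_sort_key)
        palette = ["#1f77b4", "#ff7f0e"]
        xs = np.concatenate([
            [genome_coordinate(c, p, offsets)
             for c, p in zip(df["chrom1"], df["pos1"])],
            [genome_coordinate(c, p, offsets)
             for c, p in zip(df["chrom2"], df["pos2"])],
        ])
        ys = np.concatenate([df["log10_inv_p"], df["log10_inv_p"]])
        cidx = np.concatenate([
            [chroms.index(str(c)) for c in df["chrom1"]],
            [chroms.index(str(c)) for c in df["chrom2"]],
        ])
        colors = [palette[i % 2] for i in cidx]
        ax.scatter(xs, ys, s=6, c=colors, linewidths=0)
        ticks = [offsets[c] + lengths[c] / 2 for c in chroms]
        ax.set_xticks(ticks, chroms, fontsize=7)
    ax.axhline(spec.threshold_line, color="black", linestyle="--", linewidth=1)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("log10(1/p)")
    ax.set_title(f"{getattr(scan, 'trait_name', '')} {spec.kind}".strip())
    fig.savefig(spec.out_path, format=spec.image_format, dpi=150)
    plt.close(fig)
    return spec.out_path


@dataclass
class CircosLayout:
    """Angular layout of chromosome arcs around the unit circle."""

    chroms: list[str]
    lengths: dict[str, int]
    gap_rad: float = 0.03
    starts: dict[str, float] = field(init=False)
    spans: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.chroms = sorted(self.chroms, key=chrom_sort_key)
        total_bp = sum(self.lengths[c] for c in self.chroms)
        avail = 2 * math.pi - self.gap_rad * len(self.chroms)
        if avail <= 0:
            raise ValueError("gap too large for the number of chromosomes")
        self.starts, self.spans = {}, {}
        theta = 0.0
        for c in self.chroms:
            span = avail * self.lengths[c] / total_bp
            self.starts[c] = theta
            self.spans[c] = span
            theta += span + self.gap_rad

    def angle(self, chrom, pos) -> float:
        """Angle (radians) of a bp position on its chromosome arc."""
        c = str(chrom)
        return self.starts[c] + self.spans[c] * float(pos) / self.lengths[c]


def _chord_patch(theta1: float, theta2: float, color: str) -> PathPatch:
    p1 = (math.cos(theta1), math.sin(theta1))
    p2 = (math.cos(theta2), math.sin(theta2))
    path = MplPath([p1, (0.0, 0.0), p2],
                   [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3])
    return PathPatch(path, fill=False, edgecolor=color, linewidth=0.6, alpha=0.7)


def circos_pairs(scan, spec: PlotSpec, lengths: dict[str, int] | None = None):
    """Chord diagram of pair interactions; returns the output path.

    Genome mode draws every record, red for intra-chromosome pairs and blue
    for inter-chromosome; single-chromosome mode keeps only pairs with both
    SNPs on ``spec.chromosome`` (skips logged), red when the SNPs are
    within 4 Mb and blue otherwise.
    """
    spec.validate()
    df = _records(scan)
    lengths = lengths or chromosome_lengths(df)
    red = spec.colors.get("intra_4mb", "red")
    blue = spec.colors.get("other", "blue")

    if spec.kind == "circos_chromosome":
        target = str(spec.chromosome)
        keep = (df["chrom1"].astype(str) == target) & (df["chrom2"].astype(str) == target)
        skipped = int((~keep).sum())
        if skipped:
            logger.info("circos chromosome %s: skipped %d records on other "
                        "chromosomes", target, skipped)
        df = df[keep]
        layout = CircosLayout([target], {target: lengths[target]})
        colors = np.where(np.abs(df["pos1"] - df["pos2"]) < FOUR_MEGABASES,
                          red, blue)
    elif spec.kind == "circos_genome":
        layout = CircosLayout(list(lengths), lengths)
        colors = np.where(df["intra"], red, blue)
    else:
        raise ValueError(f"{spec.kind!r} is not a circos kind")

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_aspect("equal")
    ax.axis("off")
    # ideogram ring
    ring = []
    for c in layout.chroms:
        arc = np.linspace(layout.starts[c], layout.starts[c] + layout.spans[c], 64)
        ring.append(np.column_stack([np.cos(arc), np.sin(arc)]))
        mid = layout.starts[c] + layout.spans[c] / 2
        ax.text(1.12 * math.cos(mid), 1.12 * math.sin(mid), c,
                ha="center", va="center", fontsize=7)
    ax.add_collection(LineCollection(ring, colors="black", linewidths=3))
    for (_, row), color in zip(df.iterrows(), colors):
        t1 = layout.angle(row["chrom1"], row["pos1"])
        t2 = layout.angle(row["chrom2"], row["pos2"])
        ax.add_patch(_chord_patch(t1, t2, color))
    ax.set_xlim(-1.25, 1.25)
    ax.set_ylim(-1.25, 1.25)
    ax.set_title(f"{getattr(scan, 'trait_name', '')} {spec.kind}".strip())
    fig.savefig(spec.out_path, format=spec.image_format, dpi=150)
    plt.close(fig)
    return spec.out_path
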