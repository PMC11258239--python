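"""Methylated adenine cluster (MAC) detection.

MACs are runs of methylated AT-dinucleotide motifs in which at most ``d``
unmethylated motif occurrences intervene between consecutive methylated
ones.  The relative distance ``d`` is chosen by scanning d = 1..40 and
maximizing a density x efficiency score:

* recall(d)  — fraction of methylated motifs genome-wide that end up inside
  clusters (efficiency of recovery),
* purity(d)  — fraction of motif occurrences spanned by clusters that are
  methylated (within-cluster modification density),
* score(d)   = recall(d) * purity(d).

Recall is monotone non-decreasing and purity non-increasing in ``d``, so
the product has an interior optimum; ties break toward the smaller, more
conservative distance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from macscan.genome_io import GeneModel, GenomeIndex


@dataclass
class MotifTrack:
    """Ordered motif occurrences per contig with methylation flags.

    ``positions[contig]`` holds the start coordinate of each plus-strand
    occurrence (strictly increasing); ``flags[contig]`` marks occurrences
    where either adenine of the pair carries a filtered site.
    """

    motif: str
    positions: dict[str, np.ndarray]
    flags: dict[str, np.ndarray]

    @property
    def n_occurrences(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @property
    def n_methylated(self) -> int:
        return sum(int(f.sum()) for f in self.flags.values())


@dataclass
class MAC:
    """One methylated adenine cluster."""

    contig: str
    start: int  # first methylated motif
    end: int  # last methylated motif start + motif length (half-open)
    n_methylated: int
    n_spanned: int  # total motif occurrences within the span
    first_index: int  # occurrence indices into the contig's track
    last_index: int

    @property
    def density(self) -> float:
        return self.n_methylated / self.n_spanned

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def in_size_range(self) -> bool:
        """Whether the span falls in the empirically reported 50-500 bp range."""
        return 50 <= self.size <= 500


@dataclass
class DistanceScan:
    """Per-distance recall/purity/score table and the selected distance."""

    table: pd.DataFrame  # columns d, n_clusters, recall, purity, score
    d_star: int


def build_motif_track(
    genome: GenomeIndex, sites: pd.DataFrame, motif: str = "AT"
) -> MotifTrack:
    """Enumerate plus-strand motif occurrences and flag the methylated ones.

    For the default ``AT`` motif an occurrence at ``i`` is methylated when a
    filtered site sits at ``(i, +)`` or ``(i+1, -)`` — the two opposed
    adenines.  Occurrences are scanned left to right without overlap.
    """
    if not motif or set(motif) - set("ACGT"):
        raise ValueError(f"motif must be a non-empty ACGT string, got {motif!r}")
    plus_keys: dict[str, set[int]] = {}
    minus_keys: dict[str, set[int]] = {}
    for contig, sub in sites.groupby("contig", sort=False):
        plus_keys[contig] = set(sub.loc[sub["strand"] == "+", "position"])
        minus_keys[contig] = set(sub.loc[sub["strand"] == "-", "position"])
    positions = {}
    flags = {}
    pattern = re.compile(re.escape(motif))
    for contig, seq in genome.sequences.items():
        occ = np.array([m.start() for m in pattern.finditer(seq)], dtype=np.int64)
        positions[contig] = occ
        pk = plus_keys.get(contig, set())
        mk = minus_keys.get(contig, set())
        flags[contig] = np.array(
            [p in pk or (p + 1) in mk for p in occ], dtype=bool
        )
    return MotifTrack(motif=motif, positions=positions, flags=flags)


def cluster_at_distance(
    track: MotifTrack, d: int, min_methylated: int = 2
) -> list[MAC]:
    """Cluster methylated motifs allowing <= ``d`` unmethylated ones between.

    Clusters are maximal chains of methylated occurrences; the gap metric is
    the number of intervening motif occurrences (all unmethylated, by
    construction), not base pairs.  Chains with fewer than
    ``min_methylated`` motifs are discarded.  Clusters never span contigs.
    """
    if d < 1:
        raise ValueError("relative distance d must be >= 1")
    macs = []
    motif_len = len(track.motif)
    for contig, occ in track.positions.items():
        meth_idx = np.flatnonzero(track.flags[contig])
        if len(meth_idx) == 0:
            continue
        # split chains where more than d unmethylated occurrences intervene
        breaks = np.flatnonzero(np.diff(meth_idx) - 1 > d)
        for chain in np.split(meth_idx, breaks + 1):
            if len(chain) < min_methylated:
                continue
            first, last = int(chain[0]), int(chain[-1])
            macs.append(
                MAC(
                    contig=contig,
                    start=int(occ[first]),
                    end=int(occ[last]) + motif_len,
                    n_methylated=len(chain),
                    n_spanned=last - first + 1,
                    first_index=first,
                    last_index=last,
                )
            )
    return macs


def scan_distances(
    track: MotifTrack,
    d_range: range = range(1, 41),
    min_methylated: int = 2,
) -> DistanceScan:
    """Evaluate recall, purity and score for every relative distance.

    The optimum ``d_star`` maximizes score; ties break toward the smallest
    distance.  Raises when the track holds no methylated occurrence.
    """
    total_meth = track.n_methylated
    if total_meth == 0:
        raise ValueError("nothing to cluster: no methylated motif occurrences")
    rows = []
    for d in d_range:
        macs = cluster_at_distance(track, d, min_methylated)
        in_clusters = sum(m.n_methylated for m in macs)
        spanned = sum(m.n_spanned for m in macs)
        recall = in_clusters / total_meth
        purity = in_clusters / spanned if spanned else 0.0
        rows.append((d, len(macs), recall, purity, recall * purity))
    table = pd.DataFrame(rows, columns=["d", "n_clusters", "recall", "purity", "score"])
    d_star = int(table.loc[table["score"].idxmax(), "d"])  # idxmax takes first max
    return DistanceScan(table=table, d_star=d_star)


def detect_macs(
    genome: GenomeIndex,
    sites: pd.DataFrame,
    motif: str = "AT",
    d_range: range = range(1, 41),
    min_methylated: int = 2,
) -> tuple[DistanceScan, list[MAC]]:
    """Build the motif track, select the optimal distance, and call MACs.

    The 50-500 bp size range is annotated on each MAC
    (:attr:`MAC.in_size_range`) but never used as a filter: it is an
    observed property of clusters, not a calling criterion.
    """
    track = build_motif_track(genome, sites, motif)
    scan = scan_distances(track, d_range, min_methylated)
    macs = cluster_at_distance(track, scan.d_star, min_methylated)
    return scan, macs


def macs_to_frame(macs: list[MAC]) -> pd.DataFrame:
    rows = [
        (
            m.contig, m.start, m.end, f"MAC_{i + 1}", m.n_methylated, ".",
            m.n_spanned, round(m.density, 6), m.size, m.in_size_range,
        )
        for i, m in enumerate(macs)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "name", "n_methylated", "strand",
            "n_spanned", "density", "size", "in_size_range",
        ],
    )


def tss_window(gene: GeneModel, window: tuple[int, int] = (-150, 400)) -> tuple[int, int]:
    """Strand-oriented half-open TSS window in forward coordinates.

    For a plus-strand gene with offsets (a, b) the window is
    ``[TSS + a, TSS + b)``; for minus-strand genes it is mirrored to
    ``[TSS - b, TSS - a)``.
    """
    a, b = window
    if gene.strand == "+":
        return gene.tss + a, gene.tss + b
    return gene.tss - b, gene.tss - a


def assign_macs_to_genes(
    macs: list[MAC],
    genes: list[GeneModel],
    window: tuple[int, int] = (-150, 400),
    min_sites: int = 1,
) -> pd.DataFrame:
    """Count, per gene, the MACs overlapping its TSS window.

    ``min_sites`` filters which MACs count by their number of methylated
    motifs: 1 for plain MAC-gene association, 10 for the stricter selection
    used to pick methylated genes for term enrichment.
    """
    eligible = [m for m in macs if m.n_methylated >= min_sites]
    by_contig: dict[str, list[MAC]] = {}
    for m in eligible:
        by_contig.setdefault(m.contig, []).append(m)
    rows = []
    for gene in genes:
        w0, w1 = tss_window(gene, window)
        n = sum(
            1
            for m in by_contig.get(gene.contig, [])
            if m.start < w1 and m.end > w0
        )
        rows.append((gene.gene_id, n))
    return pd.DataFrame(rows, columns=["gene_id", "n_macs"])
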