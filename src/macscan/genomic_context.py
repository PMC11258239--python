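"""Feature partition, observed/expected enrichment, and metagene profiles.

The genome is totally partitioned into exon / 5'UTR / 3'UTR / intron /
repeat / promoter / intergenic, with promoters fixed at 600 bp upstream of
the TSS.  Enrichment per class is log2(observed / expected) where the
expectation is base-composition aware: a class is expected to collect sites
in proportion to the number of eligible bases it holds (adenines on both
strands for 6mA, context-matched cytosines for 5mC), not its length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from macscan.genome_io import GeneModel, GenomeIndex

#: partition classes, in precedence order (earlier wins on overlap)
CLASSES = ["exon", "5utr", "3utr", "intron", "repeat", "promoter", "intergenic"]
_CLASS_CODE = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class FeaturePartition:
    """Total labeling of every genomic base into one feature class."""

    labels: dict[str, np.ndarray]  # per contig, uint8 codes into CLASSES
    class_bases: pd.Series  # total bp per class

    def label_at(self, contig: str, position: int) -> str:
        return CLASSES[self.labels[contig][position]]


def build_partition(
    genome: GenomeIndex,
    genes: list[GeneModel],
    repeats: pd.DataFrame | None = None,
    promoter_len: int = 600,
) -> FeaturePartition:
    """Label every base, resolving overlaps by class precedence.

    Precedence is exon > UTR > intron > repeat > promoter > intergenic:
    gene structure wins over repeats, and promoters only claim bases not
    otherwise annotated.  Painting proceeds from lowest to highest
    precedence so the later, higher-precedence paint wins.
    """
    labels = {
        contig: np.full(length, _CLASS_CODE["intergenic"], dtype=np.uint8)
        for contig, length in genome.lengths.items()
    }

    def paint(contig: str, start: int, end: int, cls: str) -> None:
        arr = labels[contig]
        start = max(0, start)
        end = min(len(arr), end)
        if end > start:
            arr[start:end] = _CLASS_CODE[cls]

    for gene in genes:
        if gene.strand == "+":
            paint(gene.contig, gene.tss - promoter_len, gene.tss, "promoter")
        else:
            paint(gene.contig, gene.tss + 1, gene.tss + 1 + promoter_len, "promoter")
    if repeats is not None:
        for row in repeats.itertuples(index=False):
            paint(row.contig, row.start, row.end, "repeat")
    n_overlap = 0
    for gene in genes:
        arr = labels[gene.contig]
        span = arr[gene.start : gene.end]
        n_overlap += int(np.isin(span, [_CLASS_CODE["exon"], _CLASS_CODE["intron"]]).sum())
        paint(gene.contig, gene.start, gene.end, "intron")
    for gene in genes:
        for s, e in gene.utr5:
            paint(gene.contig, s, e, "5utr")
        for s, e in gene.utr3:
            paint(gene.contig, s, e, "3utr")
    for gene in genes:
        for s, e in gene.exons:
            paint(gene.contig, s, e, "exon")
    if n_overlap:
        warnings.warn(f"{n_overlap} gene bases overlapped another gene; resolved by precedence")
    totals = np.zeros(len(CLASSES), dtype=np.int64)
    for arr in labels.values():
        totals += np.bincount(arr, minlength=len(CLASSES))
    return FeaturePartition(labels=labels, class_bases=pd.Series(totals, index=CLASSES))


def _eligible_per_position(genome: GenomeIndex, contig: str, eligible: str) -> np.ndarray:
    """How many eligible bases (0/1/2, counting both strands) sit at each position."""
    arr = genome.array(contig)
    if eligible == "A":
        return ((arr == ord("A")) | (arr == ord("T"))).astype(np.uint8)
    if eligible in ("CG", "CHG", "CHH"):
        from macscan.cytosine_methylation import context_code_arrays, CONTEXT_CODES

        plus, minus = context_code_arrays(genome, contig)
        code = CONTEXT_CODES[eligible]
        return ((plus == code).astype(np.uint8) + (minus == code).astype(np.uint8))
    raise ValueError(f"unknown eligible-base spec {eligible!r}")


def enrichment(
    sites: pd.DataFrame,
    partition: FeaturePartition,
    genome: GenomeIndex,
    eligible: str = "A",
) -> pd.DataFrame:
    """Observed vs expected site counts per feature class.

    expected(class) = total_sites * eligible_bases(class) / eligible_bases(genome).
    Classes with zero eligible bases get NaN (undefined) instead of a fold
    change; observed and expected counts each sum to the total site count.
    """
    if len(sites) == 0:
        raise ValueError("no sites: enrichment undefined")
    observed = np.zeros(len(CLASSES), dtype=np.int64)
    eligible_counts = np.zeros(len(CLASSES), dtype=np.int64)
    for contig, labels in partition.labels.items():
        weights = _eligible_per_position(genome, contig, eligible)
        eligible_counts += np.bincount(labels, weights=weights, minlength=len(CLASSES)).astype(
            np.int64
        )
        sub = sites[sites["contig"] == contig]
        if len(sub):
            observed += np.bincount(
                labels[sub["position"].to_numpy()], minlength=len(CLASSES)
            )
    total = observed.sum()
    total_eligible = eligible_counts.sum()
    expected = total * eligible_counts / total_eligible
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(
            eligible_counts > 0, np.log2(observed / expected), np.nan
        )
    return pd.DataFrame(
        {
            "feature": CLASSES,
            "eligible_bases": eligible_counts,
            "observed": observed,
            "expected": expected,
            "log2fc": log2fc,
        }
    )


# ---------------------------------------------------------------------------
# Metagene profiles


@dataclass
class MetageneProfile:
    """Per-bin signal averaged over elements (bodies scaled, flanks unscaled)."""

    values: np.ndarray
    n_body: int
    n_flank: int
    body_len: int
    flank_len: int
    n_elements: int
    n_skipped: int
    mode: str

    @property
    def n_bins(self) -> int:
        return self.n_body + 2 * self.n_flank

    def to_frame(self) -> pd.DataFrame:
        section = (
            ["upstream"] * self.n_flank + ["body"] * self.n_body + ["downstream"] * self.n_flank
        )
        return pd.DataFrame(
            {"bin": range(self.n_bins), "section": section, "value": self.values}
        )


def element_bin_edges(
    start: int,
    end: int,
    strand: str,
    flank_len: int,
    n_body: int,
    n_flank: int,
) -> list[tuple[int, int]]:
    """Genomic (lo, hi) intervals for each profile bin, in 5'->3' order.

    The body [start, end) is split into ``n_body`` near-equal bins; each
    flank spans ``flank_len`` bp in ``n_flank`` equal bins.  Minus-strand
    elements are mirrored so bin 0 is always the far 5' upstream bin.
    """
    body_bounds = [start + round(k * (end - start) / n_body) for k in range(n_body + 1)]
    body = list(zip(body_bounds, body_bounds[1:]))
    up_bounds = [start - flank_len + round(k * flank_len / n_flank) for k in range(n_flank + 1)]
    upstream = list(zip(up_bounds, up_bounds[1:]))
    down_bounds = [end + round(k * flank_len / n_flank) for k in range(n_flank + 1)]
    downstream = list(zip(down_bounds, down_bounds[1:]))
    bins = upstream + body + downstream
    if strand == "-":
        bins = bins[::-1]
    return bins


def metagene_profile(
    sites: pd.DataFrame,
    elements: list,
    body_len: int = 1500,
    flank_len: int = 500,
    n_body: int = 60,
    n_flank: int = 20,
) -> MetageneProfile:
    """Site-frequency metagene profile (count per bp per bin, element-averaged).

    ``elements`` may be :class:`GeneModel` objects or ``(contig, start, end,
    strand)`` tuples.  Elements shorter than ``n_body`` bp cannot fill the
    body bins and are skipped (counted in ``n_skipped``).  Bin values are
    site counts divided by bin width, so the scaled body and unscaled flanks
    are on a common per-bp frequency scale.
    """
    norm = [
        (e.contig, e.start, e.end, e.strand) if isinstance(e, GeneModel) else tuple(e)
        for e in elements
    ]
    positions = {
        contig: np.sort(sub["position"].to_numpy())
        for contig, sub in sites.groupby("contig", sort=False)
    }
    contig_lengths = {}
    n_bins = n_body + 2 * n_flank
    acc = []
    n_skipped = 0
    for contig, start, end, strand in norm:
        if end - start < n_body:
            n_skipped += 1
            continue
        pos = positions.get(contig, np.empty(0, dtype=np.int64))
        vals = np.full(n_bins, np.nan)
        for j, (lo, hi) in enumerate(
            element_bin_edges(start, end, strand, flank_len, n_body, n_flank)
        ):
            lo = max(0, lo)
            if hi <= lo:
                continue
            count = np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
            vals[j] = count / (hi - lo)
        acc.append(vals)
    if not acc:
        raise ValueError("no usable elements for metagene profile")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(np.vstack(acc), axis=0)
    return MetageneProfile(
        values=mean,
        n_body=n_body,
        n_flank=n_flank,
        body_len=body_len,
        flank_len=flank_len,
        n_elements=len(acc),
        n_skipped=n_skipped,
        mode="count",
    )


def tss_window_counts(
    sites: pd.DataFrame,
    macs: list,
    genes: list[GeneModel],
    window: tuple[int, int] = (-150, 400),
) -> pd.DataFrame:
    """Per-gene 6mA site and MAC counts in the strand-oriented TSS window."""
    from macscan.mac_detection import assign_macs_to_genes, tss_window

    positions = {
        contig: np.sort(sub["position"].to_numpy())
        for contig, sub in sites.groupby("contig", sort=False)
    }
    rows = []
    for gene in genes:
        w0, w1 = tss_window(gene, window)
        pos = positions.get(gene.contig, np.empty(0, dtype=np.int64))
        n_sites = int(np.searchsorted(pos, w1) - np.searchsorted(pos, max(0, w0)))
        rows.append((gene.gene_id, n_sites))
    out = pd.DataFrame(rows, columns=["gene_id", "n_sites"])
    out = out.merge(assign_macs_to_genes(macs, genes, window), on="gene_id")
    return out
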