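"""Filtering and classification of 6mA sites.

Covers the per-site quality filter, strand-symmetry classification at ApT
dinucleotides, flanking-context extraction with a position-frequency-matrix
motif summary, the genome-wide 6mA level, the in-silico DpnI/DpnII
isoschizomer digest, and telomeric-repeat search.

Symmetry is defined at ApT dinucleotides only: 5'-AT-3' reads as 5'-AT-3'
on both strands, so the two adenines sit physically opposed.  A site whose
adenine is not part of an ApT is asymmetric by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from macscan.genome_io import GenomeIndex, revcomp

#: IUPAC code for each non-empty subset of {A, C, G, T}
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class FilterPolicy:
    """Per-site 6mA quality filter.

    Sites pass with ``coverage >= min_coverage`` and ``mQv > min_mqv``
    (strict, matching the "> 25mQv" convention).  ``mqv_absent`` controls
    sites that carry no quality score: simulated tables have none, so the
    default lets them through.
    """

    min_coverage: int = 15
    min_mqv: float = 25.0
    mqv_absent: str = "pass"  # "pass" | "fail"

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.mqv_absent not in ("pass", "fail"):
            raise ValueError("mqv_absent must be 'pass' or 'fail'")


#: lower-coverage fallback used for shallow sequencing runs
FALLBACK_POLICY = FilterPolicy(min_coverage=5, min_mqv=20.0)


def filter_sites(
    sites: pd.DataFrame, policy: FilterPolicy = FilterPolicy()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the coverage / mQv filter; returns (retained, removal counts)."""
    cov_ok = sites["coverage"] >= policy.min_coverage
    mqv = sites["mqv"]
    mqv_ok = np.where(
        mqv.isna(), policy.mqv_absent == "pass", mqv > policy.min_mqv
    )
    removed = {
        "low_coverage": int((~cov_ok).sum()),
        "low_mqv": int((cov_ok & ~mqv_ok).sum()),
    }
    return sites[cov_ok & mqv_ok].reset_index(drop=True), removed


# ---------------------------------------------------------------------------
# Strand symmetry at ApT dinucleotides


@dataclass
class SymmetrySummary:
    pairs: pd.DataFrame  # contig, at_position, watson_ratio, crick_ratio, symmetry
    n_sites: int
    n_symmetric_sites: int
    n_hemi_sites: int
    n_non_apt_sites: int
    fraction_symmetric: float
    fraction_apt: float


def classify_symmetry(sites: pd.DataFrame, genome: GenomeIndex) -> SymmetrySummary:
    """Classify filtered sites by strand symmetry at ApT dinucleotides.

    Every ApT (plus-strand ``AT`` at positions ``i, i+1``) with at least one
    methylated adenine yields one pair record: watson = plus-strand site at
    ``i``, crick = minus-strand site at ``i+1``.  The pair is symmetric when
    both adenines carry a call.  Sites not at an ApT adenine are asymmetric
    (non-ApT).  ``fraction_symmetric`` counts sites (not pairs): both sites
    of a symmetric pair are in the numerator, matching a per-site tally.
    """
    pair_map: dict[tuple[str, int], dict] = {}
    n_non_apt = 0
    for row in sites.itertuples(index=False):
        seq = genome.sequences[row.contig]
        if row.strand == "+":
            at_pos = row.position if seq[row.position : row.position + 2] == "AT" else None
            slot = "watson_ratio"
        else:
            at_pos = (
                row.position - 1
                if row.position >= 1 and seq[row.position - 1 : row.position + 1] == "AT"
                else None
            )
            slot = "crick_ratio"
        if at_pos is None:
            n_non_apt += 1
            continue
        rec = pair_map.setdefault(
            (row.contig, at_pos), {"watson_ratio": np.nan, "crick_ratio": np.nan}
        )
        rec[slot] = row.n_mod / row.coverage
    rows = []
    n_sym_sites = 0
    n_hemi = 0
    for (contig, at_pos), rec in pair_map.items():
        has_w = not np.isnan(rec["watson_ratio"])
        has_c = not np.isnan(rec["crick_ratio"])
        if has_w and has_c:
            cls = "symmetric"
            n_sym_sites += 2
        elif has_w:
            cls = "hemi-watson"
            n_hemi += 1
        else:
            cls = "hemi-crick"
            n_hemi += 1
        rows.append((contig, at_pos, rec["watson_ratio"], rec["crick_ratio"], cls))
    pairs = pd.DataFrame(
        rows, columns=["contig", "at_position", "watson_ratio", "crick_ratio", "symmetry"]
    )
    n = len(sites)
    return SymmetrySummary(
        pairs=pairs,
        n_sites=n,
        n_symmetric_sites=n_sym_sites,
        n_hemi_sites=n_hemi,
        n_non_apt_sites=n_non_apt,
        fraction_symmetric=n_sym_sites / n if n else float("nan"),
        fraction_apt=(n_sym_sites + n_hemi) / n if n else float("nan"),
    )


# ---------------------------------------------------------------------------
# Flanking-context motif summary


@dataclass
class MotifSummary:
    """Position frequency matrix over the methylated A +/- ``flank`` bases."""

    pfm: pd.DataFrame  # rows A,C,G,T; one column per window position
    consensus: str
    fraction_apt: float  # fraction of windows with T immediately 3' of the A
    n_sites: int
    n_skipped: int = 0


def summarize_contexts(
    sites: pd.DataFrame,
    genome: GenomeIndex,
    flank: int = 6,
    consensus_threshold: float = 0.25,
) -> MotifSummary:
    """Extract +/- ``flank`` nt around each site and summarize the contexts.

    Minus-strand windows are reverse complemented so the methylated adenine
    always sits at the central column.  The IUPAC consensus merges, per
    column, every base whose frequency reaches ``consensus_threshold`` —
    a deterministic replacement for motif discovery that reproduces
    degenerate codes (V, B, ...) on strongly biased context sets.
    """
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    base_index = {b: i for i, b in enumerate("ACGT")}
    n_used = 0
    n_skipped = 0
    n_apt = 0
    for row in sites.itertuples(index=False):
        seq = genome.sequences[row.contig]
        if row.position < flank or row.position + flank >= len(seq):
            n_skipped += 1
            continue
        window = seq[row.position - flank : row.position + flank + 1]
        if row.strand == "-":
            window = revcomp(window)
        if "N" in window:
            n_skipped += 1
            continue
        for j, b in enumerate(window):
            counts[base_index[b], j] += 1
        if window[flank + 1] == "T":
            n_apt += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable sites for context summarization")
    freqs = counts / n_used
    consensus = "".join(
        _IUPAC[frozenset(b for i, b in enumerate("ACGT") if freqs[i, j] >= consensus_threshold)]
        for j in range(width)
    )
    pfm = pd.DataFrame(freqs, index=list("ACGT"), columns=range(-flank, flank + 1))
    return MotifSummary(
        pfm=pfm,
        consensus=consensus,
        fraction_apt=n_apt / n_used,
        n_sites=n_used,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# Global level, digest, telomeres


def global_level(sites: pd.DataFrame, genome: GenomeIndex) -> float:
    """Genome-wide 6mA level: % of adenines (both strands) with a call."""
    total_a = genome.total_adenines
    if total_a == 0:
        raise ValueError("genome contains no adenines")
    return 100.0 * len(sites) / total_a


def insilico_digest(
    genome: GenomeIndex, sites: pd.DataFrame, enzyme: str
) -> dict[str, list[int]]:
    """Fragment lengths from a virtual DpnI or DpnII digest.

    DpnI cuts GATC only when its adenine is methylated (on either strand);
    DpnII cuts only unmethylated GATC.  The cut sits at the palindromic
    center (GA^TC, the blunt DpnI cut), the only fixed offset that keeps
    fragment multisets invariant under reverse complementation; any offset
    preserves the fragment-size contrast the digest is meant to expose.
    """
    if enzyme not in ("DpnI", "DpnII"):
        raise ValueError(f"unknown enzyme {enzyme!r}")
    site_keys = set(zip(sites["contig"], sites["position"], sites["strand"]))
    fragments = {}
    for contig, seq in genome.sequences.items():
        cuts = []
        for m in re.finditer("GATC", seq):
            i = m.start()
            methylated = (contig, i + 1, "+") in site_keys or (contig, i + 2, "-") in site_keys
            if (enzyme == "DpnI") == methylated:
                cuts.append(i + 2)
        bounds = [0] + cuts + [len(seq)]
        fragments[contig] = [b - a for a, b in zip(bounds, bounds[1:])]
    return fragments


@dataclass
class TelomereHit:
    contig: str
    start: int
    end: int
    strand: str
    n_units: int
    distance_to_end: int


def find_telomeric_repeats(
    genome: GenomeIndex, unit: str = "TTAGGG", min_units: int = 2
) -> list[TelomereHit]:
    """Maximal tandem runs of the telomeric unit (or its reverse complement)."""
    hits = []
    for strand, u in (("+", unit), ("-", revcomp(unit))):
        pattern = re.compile(f"(?:{u}){{{min_units},}}")
        for contig, seq in genome.sequences.items():
            for m in pattern.finditer(seq):
                hits.append(
                    TelomereHit(
                        contig=contig,
                        start=m.start(),
                        end=m.end(),
                        strand=strand,
                        n_units=(m.end() - m.start()) // len(unit),
                        distance_to_end=min(m.start(), len(seq) - m.end()),
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits
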