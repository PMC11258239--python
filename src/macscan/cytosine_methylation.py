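"""Bisulfite 5mC analysis: contexts, weighted levels, and element metaplots.

Weighted methylation level over a set of cytosines pools reads:
``level = sum(methylated reads) / sum(methylated + unmethylated reads)``.
Pooling makes the level invariant to how sites are split or merged and
reduces exactly to the arithmetic mean of per-site ratios when every site
has the same coverage.

Contexts follow the standard plant/fungal convention on the cytosine's own
strand: CG when the next base is G; CHG when the next base is H (A/C/T) and
the one after is G; CHH otherwise (H = A, C or T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from macscan.genome_io import GenomeIndex
from macscan.genomic_context import MetageneProfile, element_bin_edges
from macscan.genome_io import GeneModel

CONTEXTS = ["CG", "CHG", "CHH"]
#: integer codes used by the vectorized context arrays (0 = not a cytosine /
#: truncated within 2 bp of the contig end on its strand)
CONTEXT_CODES = {"CG": 1, "CHG": 2, "CHH": 3}
_CODE_TO_CONTEXT = {1: "CG", 2: "CHG", 3: "CHH"}


@dataclass(frozen=True)
class CytosineFilterPolicy:
    """Definition of a "methylated site" for counting purposes.

    Both bounds are inclusive: coverage >= 5 reads and methylation ratio
    >= 10% by default.
    """

    min_coverage: int = 5
    min_ratio: float = 0.10


@dataclass
class WeightedLevel:
    context: str
    n_meth_reads: int
    n_total_reads: int
    n_sites: int

    @property
    def level(self) -> float:
        return self.n_meth_reads / self.n_total_reads if self.n_total_reads else float("nan")


def context_code_arrays(genome: GenomeIndex, contig: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes for plus- and minus-strand cytosines.

    Positions within 2 bp of the contig end on the relevant strand are left
    at 0 (truncated: the context cannot be read) and excluded from context
    totals everywhere.
    """
    arr = genome.array(contig)
    n = len(arr)
    A, C, G, T = (ord(b) for b in "ACGT")
    plus = np.zeros(n, dtype=np.uint8)
    minus = np.zeros(n, dtype=np.uint8)
    if n >= 3:
        is_c = arr[:-2] == C
        nxt, nxt2 = arr[1:-1], arr[2:]
        plus[:-2][is_c & (nxt == G)] = CONTEXT_CODES["CG"]
        h = is_c & np.isin(nxt, [A, C, T])
        plus[:-2][h & (nxt2 == G)] = CONTEXT_CODES["CHG"]
        plus[:-2][h & (nxt2 != G)] = CONTEXT_CODES["CHH"]
        # minus strand: C on minus is G on plus; "next" bases run leftwards
        is_g = arr[2:] == G
        prv, prv2 = arr[1:-1], arr[:-2]
        minus[2:][is_g & (prv == C)] = CONTEXT_CODES["CG"]
        h = is_g & np.isin(prv, [A, G, T])  # complement of prv in {A,C,T}
        minus[2:][h & (prv2 == C)] = CONTEXT_CODES["CHG"]
        minus[2:][h & (prv2 != C)] = CONTEXT_CODES["CHH"]
    return plus, minus


def assign_context(genome: GenomeIndex, contig: str, position: int, strand: str) -> str:
    """Context of one cytosine; 'truncated' within 2 bp of the contig end."""
    if genome.base_at(contig, position, strand) != "C":
        raise ValueError(
            f"{contig}:{position}({strand}) is not a cytosine on that strand"
        )
    plus, minus = context_code_arrays(genome, contig)
    code = plus[position] if strand == "+" else minus[position]
    return _CODE_TO_CONTEXT.get(int(code), "truncated")


def assign_context_vector(
    genome: GenomeIndex, contig: str, positions: np.ndarray, strands: np.ndarray
) -> np.ndarray:
    plus, minus = context_code_arrays(genome, contig)
    codes = np.where(strands == "+", plus[positions], minus[positions])
    out = np.empty(len(positions), dtype=object)
    out[:] = "truncated"
    for code, label in _CODE_TO_CONTEXT.items():
        out[codes == code] = label
    return out


def weighted_level(
    cytosines: pd.DataFrame,
    subset: pd.DataFrame | None = None,
    by_context: bool = True,
) -> dict[str, WeightedLevel]:
    """Read-weighted pooled methylation level, per context and overall.

    ``subset`` optionally restricts to interval rows (contig, start, end).
    Contexts with zero covered reads are reported with a NaN level rather
    than zero — absence of data is not absence of methylation.
    """
    df = cytosines
    if subset is not None:
        keep = np.zeros(len(df), dtype=bool)
        for row in subset.itertuples(index=False):
            keep |= (
                (df["contig"] == row.contig).to_numpy()
                & (df["position"] >= row.start).to_numpy()
                & (df["position"] < row.end).to_numpy()
            )
        df = df[keep]
    groups = [("all", df)]
    if by_context:
        groups += [(ctx, df[df["context"] == ctx]) for ctx in CONTEXTS]
    out = {}
    for name, sub in groups:
        meth = int(sub["n_meth"].sum())
        total = meth + int(sub["n_unmeth"].sum())
        out[name] = WeightedLevel(
            context=name, n_meth_reads=meth, n_total_reads=total, n_sites=len(sub)
        )
    return out


def filter_methylated_cytosines(
    cytosines: pd.DataFrame, policy: CytosineFilterPolicy = CytosineFilterPolicy()
) -> pd.DataFrame:
    """Cytosines that count as methylated sites: >=5x coverage, >=10% ratio.

    This filter defines methylated-site *counts* (for per-gene tallies and
    associations).  Weighted levels always pool unfiltered counts, because
    filtering before pooling would inflate the level.
    """
    cov = cytosines["n_meth"] + cytosines["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = cytosines["n_meth"] / cov
    keep = (cov >= policy.min_coverage) & (ratio >= policy.min_ratio)
    return cytosines[keep].reset_index(drop=True)


def element_metaplot(
    cytosines: pd.DataFrame,
    elements: list,
    body_len: int = 3000,
    flank_len: int = 3000,
    n_body: int = 60,
    n_flank: int = 60,
) -> dict[str, MetageneProfile]:
    """Per-context weighted-level profile over scaled elements.

    Reads are pooled per bin across all elements (bodies scaled to a common
    bin grid, flanks unscaled), then each bin's weighted level is computed —
    the binning geometry is shared with the 6mA metagene profiles.
    """
    if not elements:
        raise ValueError("no elements for metaplot")
    norm = [
        (e.contig, e.start, e.end, e.strand) if isinstance(e, GeneModel) else tuple(e)
        for e in elements
    ]
    n_bins = n_body + 2 * n_flank
    by_contig = {
        contig: sub.sort_values("position")
        for contig, sub in cytosines.groupby("contig", sort=False)
    }
    out = {}
    for ctx in CONTEXTS:
        meth = np.zeros(n_bins)
        total = np.zeros(n_bins)
        n_used = 0
        n_skipped = 0
        for contig, start, end, strand in norm:
            if end - start < n_body:
                n_skipped += 1
                continue
            n_used += 1
            sub = by_contig.get(contig)
            if sub is None:
                continue
            ctx_sub = sub[sub["context"] == ctx]
            pos = ctx_sub["position"].to_numpy()
            m = ctx_sub["n_meth"].to_numpy()
            u = ctx_sub["n_unmeth"].to_numpy()
            for j, (lo, hi) in enumerate(
                element_bin_edges(start, end, strand, flank_len, n_body, n_flank)
            ):
                lo = max(0, lo)
                if hi <= lo:
                    continue
                a, b = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
                meth[j] += m[a:b].sum()
                total[j] += m[a:b].sum() + u[a:b].sum()
        if n_used == 0:
            raise ValueError("no usable elements for metaplot")
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(total > 0, meth / total, np.nan)
        out[ctx] = MetageneProfile(
            values=values,
            n_body=n_body,
            n_flank=n_flank,
            body_len=body_len,
            flank_len=flank_len,
            n_elements=n_used,
            n_skipped=n_skipped,
            mode="level",
        )
    return out
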