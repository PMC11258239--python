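"""Seeded synthetic methylomes with full ground truth.

Two regimes mirror the contrasting methylome architectures of
Mucorales-type genomes:

* ``symmetric_clustered`` — high global 6mA (~1.1% of adenines), almost all
  of it in strand-symmetric ApT pairs, concentrated in methylated adenine
  clusters planted just downstream of the TSS of (preferentially highly
  expressed) genes, per-site methylation ratio near 1, 5mC concentrated in
  repeats in CG context.
* ``asymmetric_scattered`` — low global 6mA (~0.26%), almost no symmetry,
  sites scattered over adenines with an AAA_CA-like flanking preference,
  per-site ratio near 0.5, sparse 5mC.

Every generator is deterministic under its seed and returns a truth record
describing exactly what was planted, so each analysis stage can be tested
for parameter recovery without any external data.

Planted sites are given coverage and quality scores that pass the default
per-site filter; additional noise sites carry sub-threshold coverage or
quality and exercise the filter realistically.  Scattered background sites
are kept at least 41 motif occurrences away from planted clusters and from
each other, so clusters are unambiguous at any relative distance in the
scanned 1..40 range.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from macscan.genome_io import (
    GeneModel,
    GenomeIndex,
    write_annotation,
    write_bed,
    write_cx_report,
    write_expression,
    write_genome,
    write_modification_calls,
)

#: background/cluster separation in motif occurrences; larger than the
#: maximal scanned relative distance, so scattered sites never merge into
#: or extend a planted cluster
_MIN_SEPARATION = 41


@dataclass
class RegimeParams:
    """Parameters of one 6mA planting regime.  ``seed`` is mandatory."""

    mode: str  # "symmetric_clustered" | "asymmetric_scattered"
    seed: int
    target_level_pct: float = 1.1
    target_symmetric_fraction: float = 0.92
    in_cluster_fraction: float = 0.92
    plant_prob_by_quartile: tuple[float, float, float, float] = (0.9, 0.6, 0.3, 0.05)
    cluster_start_offset: tuple[int, int] = (0, 150)
    cluster_max_span: int = 500
    cluster_gap1_prob: float = 0.3
    background_apt_fraction: float = 0.7
    ratio_range_symmetric: tuple[float, float] = (0.85, 1.0)
    ratio_range_asymmetric: tuple[float, float] = (0.3, 0.7)
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    min_passing_coverage: int = 15
    noise_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("symmetric_clustered", "asymmetric_scattered"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for p in (
            self.target_symmetric_fraction,
            self.in_cluster_fraction,
            self.cluster_gap1_prob,
            self.background_apt_fraction,
            *self.plant_prob_by_quartile,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def phycomyces_like(seed: int) -> RegimeParams:
    """High, symmetric, clustered regime (~1.1% 6mA, 92% symmetric)."""
    return RegimeParams(mode="symmetric_clustered", seed=seed)


def mucor_like(seed: int) -> RegimeParams:
    """Low, asymmetric, scattered regime (~0.26% 6mA, 0.3% symmetric)."""
    return RegimeParams(
        mode="asymmetric_scattered",
        seed=seed,
        target_level_pct=0.26,
        target_symmetric_fraction=0.003,
        in_cluster_fraction=0.0,
    )


@dataclass
class CytosineParams:
    """Parameters of the 5mC planting model."""

    seed: int
    repeat_levels: tuple[float, float, float] = (0.8, 0.1, 0.2)  # CG, CHG, CHH
    gene_level_max: tuple[float, float, float] = (0.15, 0.03, 0.05)
    background_level: float = 0.005
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    expression_log_mean: float = 1.0
    expression_log_sigma: float = 1.5
    silent_fraction: float = 0.05


def sparse_cytosine_params(seed: int) -> CytosineParams:
    """Mucor-like 5mC: uniformly sparse methylation."""
    return CytosineParams(
        seed=seed,
        repeat_levels=(0.01, 0.005, 0.005),
        gene_level_max=(0.005, 0.003, 0.003),
        background_level=0.003,
    )


@dataclass
class SyntheticTruth:
    """Exact record of everything one generator call planted."""

    params: dict
    sites: pd.DataFrame | None = None  # contig, position, strand, role, gene_id, ratio
    clusters: pd.DataFrame | None = None  # contig, start, end, gene_id, n_motifs
    element_levels: pd.DataFrame | None = None  # 5mC levels per element
    summary: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        bundle = {"params": self.params, "summary": self.summary}
        path.write_text(json.dumps(bundle, indent=2, default=str))
        for name in ("sites", "clusters", "element_levels"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(path.with_suffix(f".{name}.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome and annotation


def generate_genome_and_annotation(
    n_contigs: int = 1,
    contig_len: int = 500_000,
    n_genes: int = 200,
    n_repeats: int = 50,
    gc: float = 0.4,
    seed: int = 0,
    gene_len_range: tuple[int, int] = (800, 2000),
    repeat_len_range: tuple[int, int] = (300, 900),
) -> tuple[GenomeIndex, list[GeneModel], pd.DataFrame, SyntheticTruth]:
    """I.i.d. genome with non-overlapping genes (1-5 exons) and repeats.

    Gene and repeat intervals are laid out with random inter-element gaps;
    an infeasible request (elements do not fit) raises before anything is
    emitted.  Fully deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    # per-contig unit counts (round-robin)
    genes_per = [n_genes // n_contigs + (1 if i < n_genes % n_contigs else 0) for i in range(n_contigs)]
    reps_per = [n_repeats // n_contigs + (1 if i < n_repeats % n_contigs else 0) for i in range(n_contigs)]

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    repeat_rows = []
    gene_counter = 0
    for ci in range(n_contigs):
        contig = f"contig_{ci + 1}"
        seq = bases[rng.choice(4, size=contig_len, p=p)].tobytes().decode("ascii")
        sequences[contig] = seq
        # element lengths
        g_lens = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=genes_per[ci])
        r_lens = rng.integers(repeat_len_range[0], repeat_len_range[1] + 1, size=reps_per[ci])
        kinds = ["gene"] * genes_per[ci] + ["repeat"] * reps_per[ci]
        lens = np.concatenate([g_lens, r_lens]).astype(np.int64)
        order = rng.permutation(len(kinds))
        total = int(lens.sum())
        n_units = len(kinds)
        min_gap = 20
        free = contig_len - total - min_gap * (n_units + 1)
        if free < 0:
            raise ValueError(
                f"infeasible layout: {total} bp of elements in a {contig_len} bp contig"
            )
        gaps = min_gap + rng.multinomial(free, np.full(n_units + 1, 1.0 / (n_units + 1)))
        cursor = 0
        for k, oi in enumerate(order):
            cursor += int(gaps[k])
            start, end = cursor, cursor + int(lens[oi])
            if kinds[oi] == "gene":
                gene_counter += 1
                strand = "+" if rng.random() < 0.5 else "-"
                exons = _split_exons(start, end, rng)
                genes.append(
                    GeneModel(
                        gene_id=f"gene_{gene_counter:04d}",
                        contig=contig,
                        strand=strand,
                        start=start,
                        end=end,
                        exons=exons,
                    )
                )
            else:
                repeat_rows.append((contig, start, end, f"repeat_{len(repeat_rows) + 1:04d}"))
            cursor = end
    repeats = pd.DataFrame(repeat_rows, columns=["contig", "start", "end", "name"])
    genome = GenomeIndex(sequences)
    truth = SyntheticTruth(
        params={
            "n_contigs": n_contigs,
            "contig_len": contig_len,
            "n_genes": n_genes,
            "n_repeats": n_repeats,
            "gc": gc,
            "seed": seed,
        },
        summary={"n_genes": len(genes), "n_repeats": len(repeats)},
    )
    return genome, genes, repeats, truth


def _split_exons(start: int, end: int, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    span = end - start
    k = int(rng.integers(1, 6))
    min_seg = 30
    while k > 1 and (2 * k - 1) * min_seg > span:
        k -= 1
    if k == 1:
        return ((start, end),)
    n_seg = 2 * k - 1
    extra = rng.multinomial(span - n_seg * min_seg, np.full(n_seg, 1.0 / n_seg))
    lengths = min_seg + extra
    bounds = start + np.concatenate([[0], np.cumsum(lengths)])
    return tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2))


# ---------------------------------------------------------------------------
# 6mA planting


def _at_occurrences(genome: GenomeIndex, contig: str) -> np.ndarray:
    arr = genome.array(contig)
    return np.flatnonzero((arr[:-1] == ord("A")) & (arr[1:] == ord("T")))


def _truncated_nb(
    rng: np.random.Generator, n: int, mean: float, dispersion: float, minimum: int
) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    out = rng.negative_binomial(dispersion, p, size=n)
    while True:
        low = out < minimum
        if not low.any():
            return out.astype(np.int64)
        out[low] = rng.negative_binomial(dispersion, p, size=int(low.sum()))


def plant_6ma(
    genome: GenomeIndex,
    genes: list[GeneModel],
    expression: pd.DataFrame,
    params: RegimeParams,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant 6mA sites according to the regime; returns (site table, truth).

    Symmetric mode: genes are selected with a probability rising with their
    expression quartile; each selected gene receives one cluster of
    strand-symmetric methylated ApT pairs starting within the configured
    offset window downstream of the TSS, with at most one unmethylated AT
    motif between consecutive methylated ones.  Scattered background sites
    (symmetric pairs and hemi sites at or off ApT) bring the genome to the
    target global level and symmetric fraction.

    Asymmetric mode: sites are drawn over adenines with flanking-context
    weights favoring an AAA_CA-like pattern and a per-site ratio near 0.5;
    symmetric pairs arise only at the (tiny) target rate.
    """
    rng = np.random.default_rng(params.seed)
    total_adenines = genome.total_adenines
    n_total = int(round(params.target_level_pct / 100.0 * total_adenines))
    if n_total > total_adenines:
        raise ValueError(
            f"target level {params.target_level_pct}% unreachable: at most "
            f"{total_adenines} adenines (100%) are available"
        )
    at_occ = {c: _at_occurrences(genome, c) for c in genome.contigs}
    used: set[tuple[str, int, str]] = set()
    # availability mask over motif occurrences (for spaced background picks)
    avail = {c: np.ones(len(occ), dtype=bool) for c, occ in at_occ.items()}
    for c, occ in at_occ.items():  # keep windows clear of contig ends
        if len(occ):
            avail[c] &= (occ >= 6) & (occ <= genome.lengths[c] - 8)

    site_rows: list[tuple] = []  # contig, position, strand, role, gene_id, ratio
    cluster_rows: list[tuple] = []

    n_cluster_sites = 0
    if params.mode == "symmetric_clustered" and params.in_cluster_fraction > 0:
        n_pair_motifs = int(round(params.in_cluster_fraction * n_total / 2.0))
        n_realized = _plant_clusters(
            genome, genes, expression, params, rng, at_occ, avail, used,
            n_pair_motifs, site_rows, cluster_rows,
        )
        n_cluster_sites = 2 * n_realized

    n_sym_target = int(round(params.target_symmetric_fraction * n_total))
    n_bg_pair_sites = max(0, 2 * int(round((n_sym_target - n_cluster_sites) / 2.0)))
    n_bg_hemi = max(0, n_total - n_cluster_sites - n_bg_pair_sites)

    # background symmetric pairs at isolated ApT motifs
    for contig, occ_idx in _spaced_motif_picks(rng, at_occ, avail, n_bg_pair_sites // 2):
        pos = int(at_occ[contig][occ_idx])
        ratio = _draw_ratio(rng, params)
        site_rows.append((contig, pos, "+", "background_pair", "", ratio))
        site_rows.append((contig, pos + 1, "-", "background_pair", "", _draw_ratio(rng, params)))
        used.add((contig, pos, "+"))
        used.add((contig, pos + 1, "-"))

    if params.mode == "symmetric_clustered":
        n_bg_apt = int(round(params.background_apt_fraction * n_bg_hemi))
        for contig, occ_idx in _spaced_motif_picks(rng, at_occ, avail, n_bg_apt):
            pos = int(at_occ[contig][occ_idx])
            strand = "+" if rng.random() < 0.5 else "-"
            position = pos if strand == "+" else pos + 1
            site_rows.append((contig, position, strand, "background_hemi_apt", "", _draw_ratio(rng, params)))
            used.add((contig, position, strand))
        _plant_non_apt_hemi(genome, rng, params, n_bg_hemi - n_bg_apt, used, site_rows)
    else:
        _plant_context_weighted(genome, rng, params, n_bg_hemi, used, site_rows)

    # noise: sub-threshold coverage or quality, removed by the default filter
    n_noise = int(round(params.noise_fraction * n_total))
    noise_rows: list[tuple] = []
    _plant_non_apt_hemi(genome, rng, params, n_noise, used, noise_rows, role="noise", any_adenine=True)

    sites = _assemble_site_table(rng, params, site_rows, noise_rows)
    truth_sites = pd.DataFrame(
        site_rows + noise_rows,
        columns=["contig", "position", "strand", "role", "gene_id", "ratio"],
    )
    n_planted = len(site_rows)
    n_sym_planted = n_cluster_sites + n_bg_pair_sites
    truth = SyntheticTruth(
        params=asdict(params),
        sites=truth_sites,
        clusters=pd.DataFrame(
            cluster_rows, columns=["contig", "start", "end", "gene_id", "n_motifs"]
        ),
        summary={
            "n_sites_planted": n_planted,
            "n_noise_sites": len(noise_rows),
            "global_level_pct": 100.0 * n_planted / total_adenines,
            "symmetric_fraction": n_sym_planted / n_planted if n_planted else 0.0,
            "in_cluster_fraction": n_cluster_sites / n_planted if n_planted else 0.0,
            "n_clusters": len(cluster_rows),
        },
    )
    return sites, truth


def _plant_clusters(
    genome, genes, expression, params, rng, at_occ, avail, used,
    n_pair_motifs, site_rows, cluster_rows,
) -> int:
    """Walk AT occurrences downstream of selected TSSs; returns motifs planted."""
    from macscan.expression_integration import stratify_expression

    strata = stratify_expression(expression, n_top=max(1, len(expression) // 4))
    quartile = dict(zip(strata["gene_id"], strata["quartile"]))
    probs = dict(zip(["Q1", "Q2", "Q3", "Q4"], params.plant_prob_by_quartile))
    selected = [g for g in genes if rng.random() < probs[quartile.get(g.gene_id, "Q4")]]
    if not selected and n_pair_motifs > 0:
        raise ValueError("no genes selected for cluster planting; raise the planting probabilities")
    total_planted = 0
    for gi, gene in enumerate(selected):
        remaining = n_pair_motifs - total_planted
        if remaining <= 1:
            break
        # adaptive quota: later genes absorb earlier shortfalls
        quota = max(2, -(-remaining // (len(selected) - gi)))
        occ = at_occ[gene.contig]
        seq = genome.sequences[gene.contig]
        offset = int(rng.integers(params.cluster_start_offset[0], params.cluster_start_offset[1] + 1))
        if gene.strand == "+":
            walk_from = gene.tss + offset
            lo, hi = walk_from, min(gene.end, walk_from + params.cluster_max_span)
        else:
            walk_from = gene.tss - offset
            lo, hi = max(gene.start, walk_from - params.cluster_max_span), walk_from
        idx = np.arange(np.searchsorted(occ, lo), np.searchsorted(occ, hi))
        if gene.strand == "-":
            idx = idx[::-1]
        chosen: list[int] = []
        i = 0
        while i < len(idx) and len(chosen) < quota:
            step = 1 + (1 if (rng.random() < params.cluster_gap1_prob and i + 1 < len(idx)) else 0)
            j = i + step - 1
            # soft context preference: avoid T at -1 / A at +2 when the
            # alternative gap candidate is favored (keeps gaps <= 1)
            alt = i + (step % 2)
            if alt < len(idx) and not _favored(seq, int(occ[idx[j]])) and _favored(seq, int(occ[idx[alt]])):
                j = alt
            chosen.append(int(idx[j]))
            i = j + 1
        if len(chosen) < 2:
            continue
        chosen.sort()
        for oi in chosen:
            pos = int(occ[oi])
            site_rows.append((gene.contig, pos, "+", "cluster", gene.gene_id, _draw_ratio(rng, params)))
            site_rows.append((gene.contig, pos + 1, "-", "cluster", gene.gene_id, _draw_ratio(rng, params)))
            used.add((gene.contig, pos, "+"))
            used.add((gene.contig, pos + 1, "-"))
        lo_i = max(0, chosen[0] - _MIN_SEPARATION)
        avail[gene.contig][lo_i : chosen[-1] + _MIN_SEPARATION + 1] = False
        cluster_rows.append(
            (
                gene.contig,
                int(occ[chosen[0]]),
                int(occ[chosen[-1]]) + 2,
                gene.gene_id,
                len(chosen),
            )
        )
        total_planted += len(chosen)
    return total_planted


def _favored(seq: str, pos: int) -> bool:
    # disfavor T immediately 5' and A two bases 3' of the AT motif, pushing
    # the summarized consensus toward V..A T..B
    return (pos == 0 or seq[pos - 1] != "T") and (pos + 3 > len(seq) or seq[pos + 2 : pos + 3] != "A")


def _spaced_motif_picks(rng, at_occ, avail, n) -> list[tuple[str, int]]:
    """Pick n isolated motif occurrences, enforcing the separation margin."""
    picks: list[tuple[str, int]] = []
    contigs = list(at_occ)
    for _ in range(n):
        counts = np.array([int(avail[c].sum()) for c in contigs])
        total = int(counts.sum())
        if total == 0:
            raise ValueError("not enough isolated AT motifs for background placement")
        r = int(rng.integers(total))
        ci = int(np.searchsorted(np.cumsum(counts), r, side="right"))
        c = contigs[ci]
        i = int(np.flatnonzero(avail[c])[r - int(counts[:ci].sum())])
        picks.append((c, i))
        avail[c][max(0, i - _MIN_SEPARATION) : i + _MIN_SEPARATION + 1] = False
    return picks


def _plant_non_apt_hemi(
    genome, rng, params, n, used, rows, role: str = "background_hemi_nonapt",
    any_adenine: bool = False,
) -> None:
    """Scattered single-strand sites at (by default non-ApT) adenines."""
    contigs = genome.contigs
    lengths = np.array([genome.lengths[c] for c in contigs], dtype=float)
    w = lengths / lengths.sum()
    placed = 0
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise ValueError("could not place scattered sites; genome too small")
        c = contigs[int(rng.choice(len(contigs), p=w))]
        seq = genome.sequences[c]
        pos = int(rng.integers(6, genome.lengths[c] - 6))
        b = seq[pos]
        if b == "A":
            strand = "+"
            is_apt = seq[pos + 1] == "T"
        elif b == "T":
            strand = "-"
            is_apt = seq[pos - 1] == "A"
        else:
            continue
        if is_apt and not any_adenine:
            continue
        if (c, pos, strand) in used:
            continue
        used.add((c, pos, strand))
        rows.append((c, pos, strand, role, "", _draw_ratio(rng, params)))
        placed += 1


def _plant_context_weighted(genome, rng, params, n, used, rows) -> None:
    """Adenines drawn with AAA_CA-biased flank weights (asymmetric regime)."""
    A, C, G, T = (ord(b) for b in "ACGT")
    cand_contig: list[str] = []
    cand_pos: list[np.ndarray] = []
    cand_strand: list[str] = []
    cand_w: list[np.ndarray] = []
    for contig in genome.contigs:
        arr = genome.array(contig)
        L = len(arr)
        for strand in "+-":
            if strand == "+":
                pos = np.flatnonzero(arr == A)
                pos = pos[(pos >= 6) & (pos < L - 6)]
                flank = {k: arr[pos + k] for k in (-3, -2, -1, 1, 2)}
                pref = {-3: A, -2: A, -1: A, 1: C, 2: A}
                avoid1 = T
            else:
                pos = np.flatnonzero(arr == T)
                pos = pos[(pos >= 6) & (pos < L - 6)]
                # flank base at offset k on the minus strand is the
                # complement of the plus base at -k
                flank = {k: arr[pos - k] for k in (-3, -2, -1, 1, 2)}
                pref = {-3: T, -2: T, -1: T, 1: G, 2: T}  # complements of A,A,A,C,A
                avoid1 = A  # complement of T
            w = np.ones(len(pos))
            for k in (-3, -2, -1, 1, 2):
                w *= np.where(flank[k] == pref[k], 6.0, 1.0)
            w *= np.where(flank[1] == avoid1, 0.3, 1.0)  # discourage ApT context
            cand_contig.append(contig)
            cand_pos.append(pos)
            cand_strand.append(strand)
            cand_w.append(w)
    all_pos = np.concatenate(cand_pos)
    all_w = np.concatenate(cand_w)
    groups = np.concatenate(
        [np.full(len(p), gi) for gi, p in enumerate(cand_pos)]
    )
    take = min(n + 50, len(all_pos))
    # weighted sampling without replacement via the Gumbel-top-k trick
    keys = np.log(all_w) + rng.gumbel(size=len(all_w))
    picks = np.argpartition(-keys, take - 1)[:take]
    picks = picks[np.argsort(-keys[picks])]
    placed = 0
    for k in picks:
        if placed >= n:
            break
        gi = int(groups[k])
        key = (cand_contig[gi], int(all_pos[k]), cand_strand[gi])
        if key in used:
            continue
        used.add(key)
        rows.append((*key, "scattered", "", _draw_ratio(rng, params)))
        placed += 1
    if placed < n:
        raise ValueError("could not place the requested number of scattered sites")


def _draw_ratio(rng, params: RegimeParams) -> float:
    lo, hi = (
        params.ratio_range_symmetric
        if params.mode == "symmetric_clustered"
        else params.ratio_range_asymmetric
    )
    return float(rng.uniform(lo, hi))


def _assemble_site_table(rng, params, site_rows, noise_rows) -> pd.DataFrame:
    """Attach coverage, read counts and mQv; planted sites pass the filter."""
    n_planted = len(site_rows)
    cov = _truncated_nb(
        rng, n_planted, params.coverage_mean, params.coverage_dispersion,
        params.min_passing_coverage,
    )
    mqv = rng.uniform(30.0, 60.0, size=n_planted)
    rows = []
    for (contig, pos, strand, _role, _gid, ratio), c, q in zip(site_rows, cov, mqv):
        n_mod = max(1, int(np.rint(ratio * c)))
        rows.append((contig, pos, strand, int(c), n_mod, round(float(q), 2)))
    n_noise = len(noise_rows)
    low_cov = rng.random(n_noise) < 0.5
    for (contig, pos, strand, _role, _gid, ratio), is_low_cov in zip(noise_rows, low_cov):
        if is_low_cov:
            c = int(rng.integers(1, params.min_passing_coverage))
            q = round(float(rng.uniform(30.0, 60.0)), 2)
        else:
            c = int(
                _truncated_nb(rng, 1, params.coverage_mean, params.coverage_dispersion,
                              params.min_passing_coverage)[0]
            )
            q = round(float(rng.uniform(5.0, 20.0)), 2)
        n_mod = max(1, int(np.rint(ratio * c)))
        rows.append((contig, pos, strand, c, n_mod, q))
    df = pd.DataFrame(
        rows, columns=["contig", "position", "strand", "coverage", "n_mod", "mqv"]
    )
    df = df.sort_values(["contig", "position", "strand"]).reset_index(drop=True)
    df["ratio"] = df["n_mod"] / df["coverage"]
    return df


# ---------------------------------------------------------------------------
# 5mC and expression


def plant_5mc_and_expression(
    genome: GenomeIndex,
    genes: list[GeneModel],
    repeats: pd.DataFrame,
    params: CytosineParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Plant per-cytosine 5mC levels and a coupled expression table.

    Repeats receive high CG (and moderate CHH) methylation; gene bodies
    receive low methylation that *increases* as expression decreases (the
    classic inverse coupling).  Read counts are binomial at the planted
    level under a negative-binomial coverage model.  Expression is
    log-normal with a silent fraction.
    """
    from macscan.cytosine_methylation import CONTEXT_CODES, context_code_arrays

    rng = np.random.default_rng(params.seed)
    # expression, ranked for the inverse coupling
    n_genes = len(genes)
    abundance = rng.lognormal(params.expression_log_mean, params.expression_log_sigma, n_genes)
    silent = rng.random(n_genes) < params.silent_fraction
    abundance[silent] = 0.0
    expression = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "abundance": np.round(abundance, 4),
            "log2fc": np.nan,
            "pvalue": np.nan,
            "direction": pd.NA,
        }
    )
    order = expression["abundance"].rank(ascending=False, method="first")
    rank_pct = (order - 1) / max(1, n_genes - 1)  # 0 = most expressed
    gene_pct = dict(zip(expression["gene_id"], rank_pct))

    element_rows = []
    cx_frames = []
    for contig in genome.contigs:
        L = genome.lengths[contig]
        lev = {ctx: np.full(L, params.background_level) for ctx in ("CG", "CHG", "CHH")}
        for row in repeats[repeats["contig"] == contig].itertuples(index=False):
            levels = tuple(
                float(np.clip(rng.normal(m, 0.03), 0.001, 0.98))
                for m in params.repeat_levels
            )
            for ctx, v in zip(("CG", "CHG", "CHH"), levels):
                lev[ctx][row.start : row.end] = v
            element_rows.append((row.name, "repeat", *levels))
        for gene in (g for g in genes if g.contig == contig):
            pct = gene_pct[gene.gene_id]
            levels = tuple(
                float(np.clip(m * pct + params.background_level, 0.0, 0.98))
                for m in params.gene_level_max
            )
            for ctx, v in zip(("CG", "CHG", "CHH"), levels):
                lev[ctx][gene.start : gene.end] = v
            element_rows.append((gene.gene_id, "gene", *levels))
        plus_codes, minus_codes = context_code_arrays(genome, contig)
        for strand, codes in (("+", plus_codes), ("-", minus_codes)):
            pos = np.flatnonzero(codes > 0)
            ctx = np.empty(len(pos), dtype=object)
            level = np.empty(len(pos))
            for name, code in CONTEXT_CODES.items():
                m = codes[pos] == code
                ctx[m] = name
                level[m] = lev[name][pos[m]]
            cov = np.maximum(
                1,
                rng.negative_binomial(
                    params.coverage_dispersion,
                    params.coverage_dispersion / (params.coverage_dispersion + params.coverage_mean),
                    size=len(pos),
                ),
            )
            n_meth = rng.binomial(cov, level)
            cx_frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "position": pos,
                        "strand": strand,
                        "context": ctx,
                        "n_meth": n_meth,
                        "n_unmeth": cov - n_meth,
                    }
                )
            )
    cx = (
        pd.concat(cx_frames)
        .sort_values(["contig", "position", "strand"])
        .reset_index(drop=True)
    )
    truth = SyntheticTruth(
        params=asdict(params),
        element_levels=pd.DataFrame(
            element_rows, columns=["name", "kind", "cg", "chg", "chh"]
        ),
        summary={
            "n_cytosines": len(cx),
            "inverse_expression_coupling": True,
            "background_level": params.background_level,
        },
    )
    return cx, expression, truth


# ---------------------------------------------------------------------------
# One-call dataset emission


def simulate_dataset(
    outdir: str | Path,
    regime: RegimeParams,
    cytosine: CytosineParams | None = None,
    n_contigs: int = 1,
    contig_len: int = 500_000,
    n_genes: int = 200,
    n_repeats: int = 50,
    gc: float = 0.4,
) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset plus truth files.

    Child seeds for the three generator stages are derived from
    ``regime.seed`` so one seed determines the whole dataset.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = int(regime.seed) % (2**31 - 5)
    genome, genes, repeats, truth_genome = generate_genome_and_annotation(
        n_contigs, contig_len, n_genes, n_repeats, gc, seed=base
    )
    cyt = cytosine
    if cyt is None:
        cyt = (
            CytosineParams(seed=base + 1)
            if regime.mode == "symmetric_clustered"
            else sparse_cytosine_params(seed=base + 1)
        )
    cx, expression, truth_5mc = plant_5mc_and_expression(genome, genes, repeats, cyt)
    regime_seeded = RegimeParams(**{**asdict(regime), "seed": base + 2})
    sites, truth_6ma = plant_6ma(genome, genes, expression, regime_seeded)

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "repeats": outdir / "repeats.bed",
        "sites": outdir / "sites.tsv",
        "cx_report": outdir / "cx_report.txt",
        "expression": outdir / "expression.tsv",
        "truth_6ma": outdir / "truth_6ma.json",
        "truth_5mc": outdir / "truth_5mc.json",
    }
    write_genome(genome, paths["genome"])
    write_annotation(genes, paths["annotation"])
    write_bed(repeats, paths["repeats"])
    write_modification_calls(sites, paths["sites"])
    write_cx_report(cx, paths["cx_report"])
    write_expression(expression, paths["expression"])
    truth_6ma.save(paths["truth_6ma"])
    truth_5mc.save(paths["truth_5mc"])
    return paths
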