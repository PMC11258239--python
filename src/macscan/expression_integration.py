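"""Joining methylation features to gene expression.

Implements expression stratification (quartiles and top/bottom-n sets),
per-stratum methylation summaries, MAC gain/loss between conditions,
per-site methylation-ratio shifts tested with Welch's unequal-variance t
test, and Fisher-based term enrichment for gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from macscan.genome_io import GeneModel
from macscan.mac_detection import tss_window


def stratify_expression(expression: pd.DataFrame, n_top: int = 400) -> pd.DataFrame:
    """Rank genes by abundance into quartiles and top/bottom-n sets.

    Q1 holds the most highly expressed genes.  Ties break deterministically
    by gene id.  Zero-abundance genes are flagged ``silent`` and forced into
    Q4.  When fewer than ``2 * n_top`` genes exist the top and bottom sets
    are truncated to disjoint halves.
    """
    df = expression[["gene_id", "abundance"]].copy()
    df = df.sort_values(["abundance", "gene_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["quartile"] = ["Q" + str(r * 4 // n + 1) for r in range(n)]
    df["silent"] = df["abundance"] == 0
    df.loc[df["silent"], "quartile"] = "Q4"
    k = n_top
    if n < 2 * n_top:
        warnings.warn(
            f"only {n} genes for top/bottom-{n_top} sets; truncating to {n // 2}"
        )
        k = n // 2
    df["in_top"] = df["rank"] <= k
    df["in_bottom"] = df["rank"] > n - k
    return df


def methylation_by_stratum(
    strata: pd.DataFrame, per_gene_counts: pd.DataFrame
) -> pd.DataFrame:
    """Site-count distribution summaries and MAC-bearing proportion per stratum.

    ``per_gene_counts`` carries gene_id, n_sites and n_macs (typically from
    the TSS-window counting).  Whisker-style summaries use the 10th/90th
    percentiles around the quartile box.
    """
    joined = strata.merge(per_gene_counts, on="gene_id", how="left")
    n_missing = int(joined["n_sites"].isna().sum())
    if len(joined) and n_missing / len(joined) > 0.05:
        warnings.warn(
            f"{n_missing}/{len(joined)} genes missing methylation counts in the join"
        )
    joined = joined.dropna(subset=["n_sites"])
    groups = [(f"Q{i}", joined[joined["quartile"] == f"Q{i}"]) for i in range(1, 5)]
    groups += [("top", joined[joined["in_top"]]), ("bottom", joined[joined["in_bottom"]])]
    rows = []
    for name, g in groups:
        if len(g) == 0:
            continue
        ns = g["n_sites"].to_numpy(dtype=float)
        rows.append(
            {
                "stratum": name,
                "n_genes": len(g),
                "p10": np.percentile(ns, 10),
                "q25": np.percentile(ns, 25),
                "median": np.median(ns),
                "q75": np.percentile(ns, 75),
                "p90": np.percentile(ns, 90),
                "mean_sites": ns.mean(),
                "prop_with_mac": float((g["n_macs"] >= 1).mean()),
            }
        )
    return pd.DataFrame(rows)


def mac_gain_loss(
    macs_a: list,
    macs_b: list,
    genes: list[GeneModel],
    window: tuple[int, int] = (-150, 400),
    min_sites: int = 1,
) -> pd.DataFrame:
    """Per-gene MAC presence change between condition A and condition B.

    Labels are presence-based: ``gained`` (MAC in A's window, none in B),
    ``lost`` (the converse), ``stable`` (both — even if the MACs shifted
    within the window), ``none`` (neither).
    """
    from macscan.mac_detection import assign_macs_to_genes

    a = assign_macs_to_genes(macs_a, genes, window, min_sites).rename(
        columns={"n_macs": "n_macs_a"}
    )
    b = assign_macs_to_genes(macs_b, genes, window, min_sites).rename(
        columns={"n_macs": "n_macs_b"}
    )
    df = a.merge(b, on="gene_id")
    conditions = [
        (df["n_macs_a"] >= 1) & (df["n_macs_b"] == 0),
        (df["n_macs_a"] == 0) & (df["n_macs_b"] >= 1),
        (df["n_macs_a"] >= 1) & (df["n_macs_b"] >= 1),
    ]
    df["change"] = np.select(conditions, ["gained", "lost", "stable"], default="none")
    return df


# ---------------------------------------------------------------------------
# Welch's t test and ratio shifts


@dataclass
class WelchResult:
    t: float
    df: float
    pvalue: float
    n1: int
    n2: int


def welch_ttest(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Two-tailed Welch unequal-variance t test.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom; p from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test needs at least 2 observations per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        # both samples constant: identical means give no evidence, different
        # means give an unbounded statistic
        diff = x.mean() - y.mean()
        if diff == 0:
            return WelchResult(t=0.0, df=float(n1 + n2 - 2), pvalue=1.0, n1=n1, n2=n2)
        return WelchResult(
            t=float(np.inf if diff > 0 else -np.inf),
            df=float(n1 + n2 - 2), pvalue=0.0, n1=n1, n2=n2,
        )
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), pvalue=float(p), n1=n1, n2=n2)


def _sites_in_windows(
    sites: pd.DataFrame, genes: list[GeneModel], window: tuple[int, int]
) -> pd.DataFrame:
    keep = np.zeros(len(sites), dtype=bool)
    pos = sites["position"].to_numpy()
    contigs = sites["contig"].to_numpy()
    for gene in genes:
        w0, w1 = tss_window(gene, window)
        keep |= (contigs == gene.contig) & (pos >= w0) & (pos < w1)
    return sites[keep]


def ratio_shift_test(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    gene_sets: dict[str, list[GeneModel]],
    window: tuple[int, int] = (-150, 400),
) -> dict:
    """Per-site methylation-ratio fold changes in DEG windows, Welch-tested.

    Sites are matched across conditions by (contig, position, strand) within
    each gene set's TSS windows; fold = ratio_A / ratio_B, so fold > 1 means
    more methylation in condition A (treatment).  When exactly two sets are
    given (e.g. up- and down-regulated genes) their fold distributions are
    compared with a two-tailed Welch test.  Sets with fewer than two matched
    sites leave the test undefined (reported as None).
    """
    per_set = {}
    folds = {}
    for name, genes in gene_sets.items():
        a = _sites_in_windows(sites_a, genes, window)
        b = _sites_in_windows(sites_b, genes, window)
        merged = a.merge(
            b, on=["contig", "position", "strand"], suffixes=("_a", "_b")
        )
        n_unmatched = len(a) - len(merged)
        usable = merged[merged["ratio_b"] > 0]
        fold = (usable["ratio_a"] / usable["ratio_b"]).to_numpy()
        folds[name] = fold
        per_set[name] = {
            "n_sites": len(fold),
            "n_unmatched": n_unmatched,
            "n_zero_control": int(len(merged) - len(usable)),
            "mean_fold": float(fold.mean()) if len(fold) else None,
        }
    result = {"per_set": per_set, "welch": None}
    names = list(gene_sets)
    if len(names) == 2:
        x, y = folds[names[0]], folds[names[1]]
        if len(x) >= 2 and len(y) >= 2:
            result["welch"] = welch_ttest(x, y)
    return result


# ---------------------------------------------------------------------------
# Term enrichment (Fisher / hypergeometric)


def term_enrichment(
    selected_genes: set[str],
    background_genes: set[str],
    annotations: dict[str, set[str]],
    alpha: float = 0.05,
    correct: str | None = None,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of annotation terms in a gene selection.

    For each term the p-value is the hypergeometric upper tail
    P(X >= observed overlap) for drawing ``len(selected)`` genes from the
    background.  No multiple-testing correction is applied by default;
    ``correct='bh'`` adds Benjamini-Hochberg q-values.
    """
    if not selected_genes:
        raise ValueError("empty gene selection")
    if not selected_genes <= background_genes:
        raise ValueError("selection must be a subset of the background")
    term_to_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene in background_genes:
            for t in terms:
                term_to_genes.setdefault(t, set()).add(gene)
    big_n = len(background_genes)
    n_sel = len(selected_genes)
    rows = []
    for term, genes_with in sorted(term_to_genes.items()):
        k_bg = len(genes_with)
        k_sel = len(genes_with & selected_genes)
        p = float(stats.hypergeom.sf(k_sel - 1, big_n, k_bg, n_sel))
        rows.append(
            {
                "term": term,
                "selected_with": k_sel,
                "selected_without": n_sel - k_sel,
                "background_with": k_bg - k_sel,
                "background_without": big_n - n_sel - (k_bg - k_sel),
                "pvalue": p,
            }
        )
    df = pd.DataFrame(rows)
    if correct == "bh" and len(df):
        df["qvalue"] = stats.false_discovery_control(df["pvalue"], method="bh")
        df["significant"] = df["qvalue"] < alpha
    elif len(df):
        df["significant"] = df["pvalue"] < alpha
    return df
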