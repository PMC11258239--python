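"""End-to-end characterization and two-condition comparison runs.

``characterize`` chains the full single-condition analysis: site filtering,
symmetry classification, motif summary, global level, MAC scan, feature
enrichment, metagene profiles, TSS-window counts, weighted 5mC levels, and
expression-stratified association.  Every output is a TSV/BED/text file in
the run directory, together with the resolved configuration, so a run is
reproducible from its own outputs.  All stages are deterministic; re-running
with the same resolved config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from macscan import (
    cytosine_methylation as cm,
    expression_integration as ei,
    genome_io as gio,
    genomic_context as gc_,
    mac_detection as md,
    site_classification as sc,
)


@dataclass
class RunConfig:
    """Resolved parameters of one characterization run (fully serializable)."""

    genome: str
    annotation: str
    sites: str
    outdir: str
    repeats: str | None = None
    cx_report: str | None = None
    expression: str | None = None
    # 6mA site filter
    min_coverage: int = 15
    min_mqv: float = 25.0
    mqv_absent: str = "pass"
    # MAC scan
    motif: str = "AT"
    d_max: int = 40
    min_methylated: int = 2
    # windows and geometry
    tss_window: tuple[int, int] = (-150, 400)
    promoter_len: int = 600
    gene_body_len: int = 1500
    gene_flank_len: int = 500
    n_body_bins: int = 60
    n_flank_bins: int = 20
    te_body_len: int = 3000
    te_flank_len: int = 3000
    # cytosine filter
    c_min_coverage: int = 5
    c_min_ratio: float = 0.10
    # expression strata
    n_top: int = 400

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "tss_window" in raw:
            raw["tss_window"] = tuple(raw["tss_window"])
        return cls(**raw)


def characterize(config: RunConfig) -> dict:
    """Run the full single-condition analysis; returns the result bundle.

    Missing optional inputs (repeats, CX report, expression) skip their
    sections with an explicit notice in the report, never silently.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    results: dict = {}

    def say(msg: str) -> None:
        log.append(msg)

    genome = _stage("load_genome", lambda: gio.load_genome(config.genome))
    genes = _stage("load_annotation", lambda: gio.load_annotation(config.annotation, genome))
    repeats = (
        _stage("load_repeats", lambda: gio.load_bed(config.repeats))
        if config.repeats
        else None
    )
    raw_sites = _stage(
        "load_modification_calls", lambda: gio.load_modification_calls(config.sites, genome)
    )
    policy = sc.FilterPolicy(config.min_coverage, config.min_mqv, config.mqv_absent)
    say(f"site filter: coverage >= {policy.min_coverage}, mQv > {policy.min_mqv}, "
        f"mQv-absent -> {policy.mqv_absent}")
    sites, removed = _stage("filter_sites", lambda: sc.filter_sites(raw_sites, policy))
    say(f"sites: {len(raw_sites)} loaded, {len(sites)} retained, removed {removed}")
    gio.write_modification_calls(sites, out / "sites_filtered.tsv")

    symmetry = _stage("classify_symmetry", lambda: sc.classify_symmetry(sites, genome))
    symmetry.pairs.to_csv(out / "symmetry_pairs.tsv", sep="\t", index=False, float_format="%.6g")
    results["n_sites"] = len(sites)
    results["fraction_symmetric"] = symmetry.fraction_symmetric
    results["fraction_apt"] = symmetry.fraction_apt

    motif = _stage("summarize_contexts", lambda: sc.summarize_contexts(sites, genome))
    motif.pfm.to_csv(out / "motif_pfm.tsv", sep="\t", float_format="%.6g")
    results["consensus"] = motif.consensus
    results["motif_fraction_apt"] = motif.fraction_apt

    results["global_level_pct"] = _stage("global_level", lambda: sc.global_level(sites, genome))

    track = _stage("build_motif_track", lambda: md.build_motif_track(genome, sites, config.motif))
    if track.n_methylated == 0:
        say("MAC scan skipped: no methylated motif occurrences")
        scan, macs = None, []
    else:
        scan = _stage(
            "scan_distances",
            lambda: md.scan_distances(track, range(1, config.d_max + 1), config.min_methylated),
        )
        macs = md.cluster_at_distance(track, scan.d_star, config.min_methylated)
        scan.table.to_csv(out / "distance_scan.tsv", sep="\t", index=False, float_format="%.6g")
        results["d_star"] = scan.d_star
    mac_frame = md.macs_to_frame(macs)
    gio.write_bed(mac_frame, out / "macs.bed", extra=["n_methylated", "strand"])
    mac_frame.to_csv(out / "macs.tsv", sep="\t", index=False, float_format="%.6g")
    results["n_macs"] = len(macs)
    in_cluster = 0
    if macs:
        spans = {}
        for m in macs:
            spans.setdefault(m.contig, []).append((m.start, m.end))
        for contig, sub in sites.groupby("contig", sort=False):
            pos = sub["position"].to_numpy()
            for s, e in spans.get(contig, []):
                in_cluster += int(((pos >= s) & (pos < e)).sum())
    results["in_cluster_fraction"] = in_cluster / len(sites) if len(sites) else float("nan")

    partition = _stage(
        "build_partition",
        lambda: gc_.build_partition(genome, genes, repeats, config.promoter_len),
    )
    enr = _stage("enrichment", lambda: gc_.enrichment(sites, partition, genome, "A"))
    enr.to_csv(out / "enrichment_6ma.tsv", sep="\t", index=False, float_format="%.6g")
    results["enrichment_6ma"] = enr

    profile = _stage(
        "metagene_profile",
        lambda: gc_.metagene_profile(
            sites, genes, config.gene_body_len, config.gene_flank_len,
            config.n_body_bins, config.n_flank_bins,
        ),
    )
    profile.to_frame().to_csv(out / "metagene_6ma.tsv", sep="\t", index=False, float_format="%.6g")
    results["metagene"] = profile

    counts = _stage(
        "tss_window_counts",
        lambda: gc_.tss_window_counts(sites, macs, genes, config.tss_window),
    )
    counts.to_csv(out / "tss_window_counts.tsv", sep="\t", index=False)
    results["tss_window_counts"] = counts

    if config.cx_report:
        cx = _stage("load_cx_report", lambda: gio.load_cx_report(config.cx_report, genome))
        levels = cm.weighted_level(cx)
        results["weighted_5mc"] = {k: v.level for k, v in levels.items()}
        rows = [
            (k, v.n_sites, v.n_meth_reads, v.n_total_reads, v.level) for k, v in levels.items()
        ]
        if repeats is not None:
            rep_levels = cm.weighted_level(cx, subset=repeats)
            results["weighted_5mc_repeats"] = {k: v.level for k, v in rep_levels.items()}
            rows += [
                (f"repeats_{k}", v.n_sites, v.n_meth_reads, v.n_total_reads, v.level)
                for k, v in rep_levels.items()
            ]
        pd.DataFrame(
            rows, columns=["context", "n_sites", "n_meth_reads", "n_total_reads", "level"]
        ).to_csv(out / "weighted_5mc.tsv", sep="\t", index=False, float_format="%.6g")
        meth_c = cm.filter_methylated_cytosines(
            cx, cm.CytosineFilterPolicy(config.c_min_coverage, config.c_min_ratio)
        )
        results["n_methylated_cytosines"] = len(meth_c)
        if repeats is not None and len(repeats):
            te_elements = [
                (r.contig, r.start, r.end, "+") for r in repeats.itertuples(index=False)
            ]
            metaplot = cm.element_metaplot(
                cx, te_elements, config.te_body_len, config.te_flank_len
            )
            frames = []
            for ctx, prof in metaplot.items():
                f = prof.to_frame()
                f["context"] = ctx
                frames.append(f)
            pd.concat(frames).to_csv(
                out / "metaplot_5mc_repeats.tsv", sep="\t", index=False, float_format="%.6g"
            )
            results["metaplot_5mc_repeats"] = metaplot
    else:
        say("NOTICE: no CX report given; 5mC sections skipped")

    if config.expression:
        expression = _stage("load_expression", lambda: gio.load_expression(config.expression))
        strata = ei.stratify_expression(expression, config.n_top)
        assoc = ei.methylation_by_stratum(strata, counts)
        assoc.to_csv(out / "stratum_association.tsv", sep="\t", index=False, float_format="%.6g")
        results["stratum_association"] = assoc
        results["strata"] = strata
    else:
        say("NOTICE: no expression table given; expression sections skipped")

    config.to_yaml(out / "config.yaml")
    _write_report(out / "report.txt", results, log)
    results["log"] = log
    return results


def _stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def _write_report(path: Path, results: dict, log: list[str]) -> None:
    lines = ["macscan characterization report", "=" * 33, ""]
    lines += log + [""]
    scalars = {
        k: v
        for k, v in results.items()
        if isinstance(v, (int, float, str)) or v is None
    }
    for k, v in sorted(scalars.items()):
        if isinstance(v, float):
            lines.append(f"{k}: {v:.6g}")
        else:
            lines.append(f"{k}: {v}")
    for key in ("weighted_5mc", "weighted_5mc_repeats"):
        if key in results:
            lines.append(
                f"{key}: "
                + json.dumps({k: (round(v, 6) if v == v else None) for k, v in results[key].items()})
            )
    Path(path).write_text("\n".join(lines) + "\n")


def compare(config_a: RunConfig, config_b: RunConfig, deg_table: str | Path, outdir: str | Path) -> dict:
    """Two-condition comparison: matched ratio shifts and MAC gain/loss.

    Both runs must target the same genome and annotation (contig names and
    lengths are checked).  The DEG table supplies gene direction labels (or
    log2fc + p at 0.05) defining the up/down sets for the Welch comparison.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = gio.load_genome(config_a.genome)
    genome_b = gio.load_genome(config_b.genome)
    if genome.lengths != genome_b.lengths:
        raise ValueError("genome mismatch between conditions (contig names/lengths differ)")
    genes = gio.load_annotation(config_a.annotation, genome)
    sites = {}
    macs = {}
    for label, cfg in (("a", config_a), ("b", config_b)):
        raw = gio.load_modification_calls(cfg.sites, genome)
        filt, _ = sc.filter_sites(
            raw, sc.FilterPolicy(cfg.min_coverage, cfg.min_mqv, cfg.mqv_absent)
        )
        sites[label] = filt
        track = md.build_motif_track(genome, filt, cfg.motif)
        if track.n_methylated:
            scan = md.scan_distances(track, range(1, cfg.d_max + 1), cfg.min_methylated)
            macs[label] = md.cluster_at_distance(track, scan.d_star, cfg.min_methylated)
        else:
            macs[label] = []

    gain_loss = ei.mac_gain_loss(macs["a"], macs["b"], genes, config_a.tss_window)
    deg = gio.load_expression(deg_table)
    direction = deg.set_index("gene_id")["direction"]
    if direction.isna().all():
        sig = deg["pvalue"] < 0.05
        direction = pd.Series(
            np.select(
                [sig & (deg["log2fc"] > 0), sig & (deg["log2fc"] < 0)],
                ["up", "down"],
                default="not-DE",
            ),
            index=deg["gene_id"],
        )
    gene_by_id = {g.gene_id: g for g in genes}
    gene_sets = {
        label: [gene_by_id[g] for g in direction[direction == label].index if g in gene_by_id]
        for label in ("up", "down")
    }
    shifts = ei.ratio_shift_test(sites["a"], sites["b"], gene_sets, config_a.tss_window)

    gain_loss = gain_loss.merge(
        direction.rename("direction"), left_on="gene_id", right_index=True, how="left"
    )
    gain_loss.to_csv(out / "mac_gain_loss.tsv", sep="\t", index=False)
    rows = []
    for name, d in shifts["per_set"].items():
        rows.append({"set": name, **d})
    pd.DataFrame(rows).to_csv(out / "ratio_shift_sets.tsv", sep="\t", index=False, float_format="%.6g")
    welch = shifts["welch"]
    (out / "welch.txt").write_text(
        "no test (insufficient matched sites)\n"
        if welch is None
        else f"t={welch.t:.6g}\tdf={welch.df:.6g}\tp={welch.pvalue:.6g}\tn1={welch.n1}\tn2={welch.n2}\n"
    )
    return {"gain_loss": gain_loss, "shifts": shifts, "macs": macs, "sites": sites}
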