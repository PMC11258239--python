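"""Shared fixtures: small hand genomes and session-scoped synthetic datasets."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from macscan import synthetic_data as syn
from macscan.genome_io import GenomeIndex
from macscan.pipeline import RunConfig, characterize


def make_sites(rows: list[tuple], coverage: int = 20, n_mod: int | None = None,
               mqv: float = 40.0) -> pd.DataFrame:
    """Site table from (contig, position, strand[, coverage, n_mod]) tuples."""
    out = []
    for r in rows:
        contig, position, strand = r[:3]
        cov = r[3] if len(r) > 3 else coverage
        nm = r[4] if len(r) > 4 else (n_mod if n_mod is not None else cov)
        out.append((contig, position, strand, cov, nm, mqv, nm / cov))
    return pd.DataFrame(
        out, columns=["contig", "position", "strand", "coverage", "n_mod", "mqv", "ratio"]
    )


def make_cytosines(rows: list[tuple]) -> pd.DataFrame:
    """Cytosine table from (contig, position, strand, context, n_meth, n_unmeth)."""
    return pd.DataFrame(
        rows, columns=["contig", "position", "strand", "context", "n_meth", "n_unmeth"]
    )


@pytest.fixture
def toy_genome() -> GenomeIndex:
    return GenomeIndex({"c1": "AATT"})


def _simulate_and_run(tmp_path_factory, label: str, regime) -> dict:
    root = tmp_path_factory.mktemp(label)
    paths = syn.simulate_dataset(root / "data", regime)
    config = RunConfig(
        genome=str(paths["genome"]),
        annotation=str(paths["annotation"]),
        sites=str(paths["sites"]),
        outdir=str(root / "run"),
        repeats=str(paths["repeats"]),
        cx_report=str(paths["cx_report"]),
        expression=str(paths["expression"]),
    )
    results = characterize(config)
    truth = json.loads(paths["truth_6ma"].read_text())
    clusters = pd.read_csv(
        paths["truth_6ma"].with_suffix(".clusters.tsv"), sep="\t"
    )
    truth_sites = pd.read_csv(paths["truth_6ma"].with_suffix(".sites.tsv"), sep="\t")
    element_levels = pd.read_csv(
        paths["truth_5mc"].with_suffix(".element_levels.tsv"), sep="\t"
    )
    return {
        "paths": paths,
        "config": config,
        "results": results,
        "truth": truth,
        "clusters": clusters,
        "truth_sites": truth_sites,
        "element_levels": element_levels,
    }


@pytest.fixture(scope="session")
def sym_bundle(tmp_path_factory) -> dict:
    """500 kb symmetric/clustered regime, simulated and fully characterized."""
    return _simulate_and_run(tmp_path_factory, "sym", syn.phycomyces_like(1))


@pytest.fixture(scope="session")
def asym_bundle(tmp_path_factory) -> dict:
    """500 kb asymmetric/scattered regime, simulated and fully characterized."""
    return _simulate_and_run(tmp_path_factory, "asym", syn.mucor_like(1))
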