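"""Readers and writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally; conversions to and from
the 1-based inclusive conventions of GFF3 and the tabular site formats
happen only here, at the I/O boundary.

In-memory containers
--------------------
* genome: :class:`GenomeIndex` (uppercase sequences over ``{A,C,G,T,N}``).
* gene models: list of :class:`GeneModel`.
* 6mA sites: a :class:`pandas.DataFrame` with columns
  ``contig, position, strand, coverage, n_mod, mqv, ratio``
  (``position`` 0-based, ``mqv`` NaN when the caller has no quality score).
* cytosines: a DataFrame with columns
  ``contig, position, strand, context, n_meth, n_unmeth``.
* expression: a DataFrame with columns
  ``gene_id, abundance, log2fc, pvalue, direction``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SITE_COLUMNS = ["contig", "position", "strand", "coverage", "n_mod", "mqv", "ratio"]
CX_COLUMNS = ["contig", "position", "strand", "context", "n_meth", "n_unmeth"]
EXPRESSION_COLUMNS = ["gene_id", "abundance", "log2fc", "pvalue", "direction"]

SITES_HEADER = "#macscan-sites v1"


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeIndex:
    """Uppercase genome with per-contig lengths and base counts.

    ``mask`` optionally records soft-masked (lowercase in the input FASTA)
    positions; it plays no role in the analysis but is preserved so masking
    information is not silently discarded.
    """

    sequences: dict[str, str]
    mask: dict[str, np.ndarray] = field(default_factory=dict)
    lengths: dict[str, int] = field(init=False)
    base_counts: dict[str, dict[str, int]] = field(init=False)
    _arrays: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lengths = {name: len(s) for name, s in self.sequences.items()}
        self.base_counts = {
            name: {b: s.count(b) for b in "ACGTN"}
            for name, s in self.sequences.items()
        }
        self._arrays = {}

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences)

    def seq(self, contig: str) -> str:
        return self.sequences[contig]

    def array(self, contig: str) -> np.ndarray:
        """Sequence as a ``uint8`` byte array (cached), for vectorized checks."""
        if contig not in self._arrays:
            self._arrays[contig] = np.frombuffer(
                self.sequences[contig].encode("ascii"), dtype=np.uint8
            )
        return self._arrays[contig]

    def base_at(self, contig: str, position: int, strand: str = "+") -> str:
        base = self.sequences[contig][position]
        return base if strand == "+" else base.translate(_COMPLEMENT)

    @property
    def total_adenines(self) -> int:
        """Adenines on both strands: plus-strand A plus plus-strand T."""
        return sum(c["A"] + c["T"] for c in self.base_counts.values())

    def reverse_complement(self) -> "GenomeIndex":
        """Mirror image genome (used by strand-involution checks)."""
        return GenomeIndex({name: revcomp(s) for name, s in self.sequences.items()})


@dataclass
class GeneModel:
    """One gene with strand-aware TSS/TTS and ordered exon intervals."""

    gene_id: str
    contig: str
    strand: str
    start: int  # 0-based half-open span
    end: int
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        """5'-most transcribed base on the gene's strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        exons = tuple(sorted(self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = exons


def load_genome(path: str | Path) -> GenomeIndex:
    """Read a FASTA file into a :class:`GenomeIndex`.

    Lowercase (soft-masked) stretches are uppercased; their positions are
    kept in ``mask``.  Duplicate record names and characters outside
    ``ACGTN`` are hard errors.
    """
    sequences: dict[str, str] = {}
    mask: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate contig name: {name}")
        raw = str(record.seq)
        upper = raw.upper()
        arr = np.frombuffer(upper.encode("ascii"), dtype=np.uint8)
        valid = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
        if not valid.all():
            pos = int(np.flatnonzero(~valid)[0])
            raise ValueError(
                f"contig {name}: invalid character {upper[pos]!r} at position {pos}"
            )
        lowercase = np.frombuffer(raw.encode("ascii"), dtype=np.uint8) >= ord("a")
        if lowercase.any():
            mask[name] = lowercase
        sequences[name] = upper
    if not sequences:
        raise ValueError(f"no records in FASTA file {path}")
    return GenomeIndex(sequences, mask)


def write_genome(genome: GenomeIndex, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def load_annotation(path: str | Path, genome: GenomeIndex) -> list[GeneModel]:
    """Read gene/mRNA/exon features from a GFF3 file.

    GFF3 is 1-based inclusive; internal coordinates are 0-based half-open.
    Genes without exons are skipped with a warning; features beyond contig
    bounds or on unknown contigs raise.
    """
    genes: dict[str, dict] = {}
    id_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _, ftype, start, end, _, strand, _, attrs = fields
            start0, end0 = int(start) - 1, int(end)
            attributes = _parse_gff_attributes(attrs)
            if ftype == "gene":
                gid = attributes.get("ID", f"gene_{lineno}")
                if contig not in genome.sequences:
                    raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
                if end0 > genome.lengths[contig]:
                    raise ValueError(
                        f"{path}:{lineno}: gene {gid} beyond contig {contig} length"
                    )
                genes[gid] = {
                    "contig": contig,
                    "strand": strand,
                    "start": start0,
                    "end": end0,
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                }
                id_to_gene[gid] = gid
            elif ftype in ("mRNA", "transcript"):
                parent = attributes.get("Parent")
                tid = attributes.get("ID")
                if parent in id_to_gene and tid:
                    id_to_gene[tid] = id_to_gene[parent]
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attributes.get("Parent", "")
                gid = id_to_gene.get(parent)
                if gid is None:
                    raise ValueError(
                        f"{path}:{lineno}: {ftype} with unknown parent {parent!r}"
                    )
                if contig not in genome.sequences:
                    raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
                if end0 > genome.lengths[contig]:
                    raise ValueError(f"{path}:{lineno}: feature beyond contig bounds")
                key = {"exon": "exons", "five_prime_UTR": "utr5", "three_prime_UTR": "utr3"}
                genes[gid][key[ftype]].append((start0, end0))
    models = []
    for gid, g in genes.items():
        if not g["exons"]:
            warnings.warn(f"gene {gid} has no exons; skipped")
            continue
        models.append(
            GeneModel(
                gene_id=gid,
                contig=g["contig"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=tuple(sorted(g["exons"])),
                utr5=tuple(sorted(g["utr5"])),
                utr3=tuple(sorted(g["utr3"])),
            )
        )
    return models


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_annotation(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (gene/mRNA/exon, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tmacscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\tmacscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\tmacscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={tid}.exon{i};Parent={tid}\n"
                )
            for s, e in g.utr5:
                fh.write(
                    f"{g.contig}\tmacscan\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n"
                )
            for s, e in g.utr3:
                fh.write(
                    f"{g.contig}\tmacscan\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={tid}\n"
                )


# ---------------------------------------------------------------------------
# 6mA modification calls


def _round_half_even(x: np.ndarray) -> np.ndarray:
    # numpy.rint rounds half to even, matching the documented rule
    return np.rint(x).astype(np.int64)


def _validate_sites(df: pd.DataFrame, genome: GenomeIndex, source: str) -> pd.DataFrame:
    """Drop rows whose reference base is not A on the stated strand.

    A rejection rate above 1% aborts: it almost always means the input used
    a different coordinate convention.
    """
    keep = np.zeros(len(df), dtype=bool)
    for contig, idx in df.groupby("contig", sort=False).groups.items():
        if contig not in genome.sequences:
            raise ValueError(f"{source}: unknown contig {contig!r}")
        arr = genome.array(contig)
        sub = df.loc[idx]
        pos = sub["position"].to_numpy()
        if (pos < 0).any() or (pos >= genome.lengths[contig]).any():
            raise ValueError(f"{source}: position outside contig {contig}")
        plus = sub["strand"].to_numpy() == "+"
        base = arr[pos]
        ok = np.where(plus, base == ord("A"), base == ord("T"))
        keep[df.index.get_indexer(idx)] = ok
    n_rejected = int((~keep).sum())
    if len(df) and n_rejected / len(df) > 0.01:
        raise ValueError(
            f"{source}: {n_rejected}/{len(df)} rows do not sit on an adenine; "
            "likely a coordinate-convention mismatch"
        )
    if n_rejected:
        warnings.warn(f"{source}: rejected {n_rejected} non-adenine rows")
    out = df[keep].reset_index(drop=True)
    out["ratio"] = out["n_mod"] / out["coverage"]
    return out[SITE_COLUMNS]


def load_modification_calls(path: str | Path, genome: GenomeIndex) -> pd.DataFrame:
    """Read per-site 6mA calls from the canonical TSV or a modification GFF.

    The canonical table starts with ``#macscan-sites v1`` and carries
    1-based positions; a fractional ``n_mod`` column (``frac_mod``) is
    converted to read counts by round-half-even.  Files whose first
    non-comment line has nine tab-separated columns are parsed as the
    modification-GFF dialect (score column = mQv, ``coverage=``/``frac=``
    attributes).
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or len(head.rstrip("\n").split("\t")) == 9:
        df = _read_modification_gff(path)
    else:
        df = _read_site_table(path)
    return _validate_sites(df, genome, str(path))


def _read_site_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str})
    required = {"contig", "position", "strand", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "n_mod" in df.columns:
        n_mod = df["n_mod"].to_numpy(dtype=np.int64)
    elif "frac_mod" in df.columns:
        n_mod = _round_half_even(df["frac_mod"].to_numpy() * df["coverage"].to_numpy())
    else:
        raise ValueError(f"{path}: need an n_mod or frac_mod column")
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "position": df["position"].astype(np.int64) - 1,
            "strand": df["strand"],
            "coverage": df["coverage"].astype(np.int64),
            "n_mod": n_mod,
            "mqv": df["mqv"].astype(float) if "mqv" in df.columns else np.nan,
        }
    )
    _check_counts(out, path)
    return out


def _read_modification_gff(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF row")
            contig, _, _, start, _, score, strand, _, attrs = fields
            attributes = _parse_gff_attributes(attrs)
            cov = attributes.get("coverage", attributes.get("cov"))
            if cov is None:
                raise ValueError(f"{path}:{lineno}: no coverage attribute")
            cov = int(cov)
            if "n_mod" in attributes:
                n_mod = int(attributes["n_mod"])
            elif "frac" in attributes:
                n_mod = int(np.rint(float(attributes["frac"]) * cov))
            else:
                raise ValueError(f"{path}:{lineno}: no frac or n_mod attribute")
            mqv = float(score) if score not in (".", "") else np.nan
            rows.append((contig, int(start) - 1, strand, cov, n_mod, mqv))
    df = pd.DataFrame(rows, columns=["contig", "position", "strand", "coverage", "n_mod", "mqv"])
    _check_counts(df, path)
    return df


def _check_counts(df: pd.DataFrame, source) -> None:
    bad = (df["n_mod"] < 0) | (df["n_mod"] > df["coverage"]) | (df["coverage"] < 1)
    if bad.any():
        raise ValueError(f"{source}: {int(bad.sum())} rows with impossible read counts")


def write_modification_calls(sites: pd.DataFrame, path: str | Path) -> None:
    """Write sites to the canonical versioned TSV (1-based positions)."""
    out = sites[["contig", "position", "strand", "coverage", "n_mod", "mqv"]].copy()
    out["position"] = out["position"] + 1
    buf = io.StringIO()
    buf.write(SITES_HEADER + "\n")
    out.to_csv(buf, sep="\t", index=False, float_format="%.4f")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Bisulfite CX report


def load_cx_report(path: str | Path, genome: GenomeIndex) -> pd.DataFrame:
    """Read a CX-report-style table of per-cytosine bisulfite counts.

    Columns (no header): contig, 1-based position, strand, methylated count,
    unmethylated count, context, [trinucleotide].  The context label is
    re-derived from the genome; a mismatch rate above 1% is a hard error.
    """
    from macscan.cytosine_methylation import assign_context_vector

    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if raw.shape[1] not in (6, 7):
        raise ValueError(f"{path}: expected 6 or 7 CX-report columns, found {raw.shape[1]}")
    df = raw.iloc[:, :6].copy()
    df.columns = ["contig", "position", "strand", "n_meth", "n_unmeth", "context"]
    df["position"] = df["position"].astype(np.int64) - 1
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    derived = np.empty(len(df), dtype=object)
    for contig, idx in df.groupby("contig", sort=False).groups.items():
        if contig not in genome.sequences:
            raise ValueError(f"{path}: unknown contig {contig!r}")
        sub = df.loc[idx]
        derived[df.index.get_indexer(idx)] = assign_context_vector(
            genome, contig, sub["position"].to_numpy(), sub["strand"].to_numpy()
        )
    df["derived_context"] = derived
    usable = df["derived_context"] != "truncated"
    mismatch = usable & (df["context"] != df["derived_context"])
    if len(df) and mismatch.sum() / len(df) > 0.01:
        raise ValueError(
            f"{path}: {int(mismatch.sum())}/{len(df)} context labels disagree with "
            "the genome; wrong genome or coordinate convention?"
        )
    if mismatch.any():
        warnings.warn(f"{path}: {int(mismatch.sum())} context mismatches (file label kept out)")
    out = df[usable].reset_index(drop=True)
    out = out[["contig", "position", "strand", "derived_context", "n_meth", "n_unmeth"]]
    out.columns = CX_COLUMNS
    return out


def write_cx_report(cytosines: pd.DataFrame, path: str | Path) -> None:
    out = cytosines[["contig", "position", "strand", "n_meth", "n_unmeth", "context"]].copy()
    out["position"] = out["position"] + 1
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Expression tables


def load_expression(path: str | Path) -> pd.DataFrame:
    """Read a per-gene expression table (gene_id, abundance[, log2fc, pvalue, direction])."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "abundance" not in df.columns:
        raise ValueError(f"{path}: need gene_id and abundance columns")
    if (df["abundance"] < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    for col in ("log2fc", "pvalue"):
        if col not in df.columns:
            df[col] = np.nan
    if "direction" not in df.columns:
        df["direction"] = pd.NA
    return df[EXPRESSION_COLUMNS]


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# BED intervals (repeats, MACs)


def load_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into contig/start/end[/name]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            rows.append((fields[0], int(fields[1]), int(fields[2]), name))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["contig", "start", "end"]
    for c in ["name"] + (extra or []):
        if c in intervals.columns:
            cols.append(c)
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)
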