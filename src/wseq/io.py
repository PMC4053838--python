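"""Readers and writers for the pipeline's plain-text formats.

FASTA for sequences (wrapped at 60 columns, uppercased on read), TSV for
counts / designs / annotations / results / catalogs / layouts, JSON for
manifests and tallies, YAML for configuration.  Intervals are 0-based
half-open in files produced for machines and 1-based inclusive in
human-readable report columns (marked in the header names).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional
import warnings

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CountExperiment, Fragment

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fragments",
    "write_fragments",
    "write_experiment",
    "read_experiment",
    "write_results",
    "WCatalogEntry",
    "load_w_catalog",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercase sequence) pairs from a FASTA file."""
    with open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fragments(path) -> list[Fragment]:
    """Fragments from FASTA; source/chrom parsed from the description."""
    out = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            meta = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            out.append(
                Fragment(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    source=meta.get("source", "de-novo"),
                    chrom=meta.get("chrom", "Un_random"),
                )
            )
    return out


def write_fragments(path, fragments: Iterable[Fragment], width: int = 60) -> None:
    recs = [
        SeqRecord(
            Seq(f.sequence), id=f.id,
            description=f"source={f.source} chrom={f.chrom}",
        )
        for f in fragments
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def write_experiment(experiment: CountExperiment, out_dir) -> dict:
    """Write counts/design/annotation TSVs; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "annotation": out / "annotation.tsv",
    }
    experiment.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
    design = experiment.design.copy()
    design["library_size"] = experiment.library_sizes
    design.rename_axis("sample").to_csv(paths["design"], sep="\t")
    if experiment.annotation is not None:
        experiment.annotation.rename_axis("gene_id").to_csv(
            paths["annotation"], sep="\t"
        )
    return {k: str(v) for k, v in paths.items()}


def read_experiment(
    counts_path, design_path, annotation_path=None
) -> CountExperiment:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    design = pd.read_csv(design_path, sep="\t", index_col="sample")
    lib = None
    if "library_size" in design.columns:
        lib = design.pop("library_size").astype(float)
    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t", index_col="gene_id")
    return CountExperiment(
        counts=counts, design=design, library_sizes=lib, annotation=annotation
    )


def write_results(results: dict, path) -> pd.DataFrame:
    """Long-format TSV of all test tables (one row per gene per test)."""
    frames = []
    for name, res in results.items():
        t = res.table.copy()
        t.insert(0, "test", res.test)
        frames.append(t.rename_axis("gene_id").reset_index())
    long = pd.concat(frames, ignore_index=True)
    long.to_csv(path, sep="\t", index=False)
    return long


# ---------------------------------------------------------------------------
# the W-gene catalog
# ---------------------------------------------------------------------------


@dataclass
class WCatalogEntry:
    """One W-chromosome gene of the embryonic catalog."""

    gene: str
    description: str
    location: str
    fpkm_blastoderm_female: Optional[float]
    fpkm_gonad_female: Optional[float]
    dna_identity_pct: Optional[float]
    protein_identity_pct: Optional[float]
    dnds: Optional[float]
    is_small_rna: bool = False
    is_novel: bool = False
    lacks_z_gametologue: bool = False


def _opt_float(value, line_no: int, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(
            f"w catalog line {line_no}: column {column!r} has non-numeric "
            f"value {value!r}"
        ) from None


def load_w_catalog(path=None) -> list[WCatalogEntry]:
    """Parse and validate the W-gene catalog TSV (packaged copy by default).

    Validates: unique gene symbols, small-RNA entries carry no dN/dS, and
    exactly one protein-coding entry lacks a Z gametologue (the FAF case) —
    unless the catalog is empty, which yields an empty list with a warning.
    """
    if path is None:
        path = resources.files("wseq.data") / "w_catalog.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "gene", "description", "location", "fpkm_blastoderm_female",
        "fpkm_gonad_female", "dna_identity_pct", "protein_identity_pct",
        "dnds", "is_small_rna", "is_novel", "lacks_z_gametologue",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"w catalog lacks columns {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        if not row["gene"]:
            raise ValueError(f"w catalog line {line_no}: empty gene symbol")
        flags = {}
        for col in ("is_small_rna", "is_novel", "lacks_z_gametologue"):
            if row[col] not in ("0", "1"):
                raise ValueError(
                    f"w catalog line {line_no}: column {col!r} must be 0/1, "
                    f"got {row[col]!r}"
                )
            flags[col] = row[col] == "1"
        entry = WCatalogEntry(
            gene=row["gene"],
            description=row["description"],
            location=row["location"],
            fpkm_blastoderm_female=_opt_float(
                row["fpkm_blastoderm_female"], line_no, "fpkm_blastoderm_female"
            ),
            fpkm_gonad_female=_opt_float(
                row["fpkm_gonad_female"], line_no, "fpkm_gonad_female"
            ),
            dna_identity_pct=_opt_float(
                row["dna_identity_pct"], line_no, "dna_identity_pct"
            ),
            protein_identity_pct=_opt_float(
                row["protein_identity_pct"], line_no, "protein_identity_pct"
            ),
            dnds=_opt_float(row["dnds"], line_no, "dnds"),
            **flags,
        )
        if entry.is_small_rna and entry.dnds is not None:
            raise ValueError(
                f"w catalog line {line_no}: small-RNA entry has a dN/dS value"
            )
        entries.append(entry)

    if not entries:
        warnings.warn("w catalog is empty")
        return entries
    symbols = [e.gene for e in entries]
    if len(set(symbols)) != len(symbols):
        dup = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"w catalog has duplicate gene symbols: {dup}")
    n_orphan = sum(e.lacks_z_gametologue for e in entries)
    if n_orphan != 1:
        raise ValueError(
            f"w catalog must flag exactly one gene without a Z gametologue "
            f"(found {n_orphan})"
        )
    return entries
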