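"""Shared containers for the ZW expression / W-transcriptome pipeline.

The pipeline revolves around three kinds of objects:

* a :class:`CountExperiment` — a genes × samples matrix of RNA-seq fragment
  counts with a factorial design (tissue × sex × replicate) and per-sample
  library sizes, plus a gene annotation giving each gene's chromosome class
  and exonic length;
* transcript :class:`Fragment` s — pieces of a transcript recovered from
  different evidence sources (curated annotation, genome-guided assembly,
  de-novo assembly), possibly mislocated on unplaced pseudo-chromosomes;
* plain string sequences (DNA, uppercase ACGTN) for scaffolding and
  divergence analysis.

Genomic and transcript intervals are 0-based half-open everywhere in memory;
human-readable reports convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: chromosome classes of the chicken-style ZW genome model
CHROM_CLASSES = ("autosome", "Z", "W", "W_random", "Un_random")
#: classes treated as carrying W-linked material
W_CLASSES = ("W", "W_random")

TISSUES = ("blastoderm", "gonad")
SEXES = ("F", "M")

#: evidence sources for transcript fragments, in decreasing curation priority
FRAGMENT_SOURCES = ("annotation", "genome-guided", "de-novo")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse-complement an uppercase ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> str:
    """Validate and uppercase a DNA string; reject non-ACGTN characters."""
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-ACGTN characters: {sorted(bad)}")
    return seq


@dataclass
class GeneRecord:
    """One annotated gene: id, chromosome class, exonic length in bp."""

    gene_id: str
    chrom_class: str
    length: int
    gametologue: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"unknown chromosome class {self.chrom_class!r}")
        if self.length <= 0:
            raise ValueError("gene length must be positive")


@dataclass
class Fragment:
    """A transcript piece from one evidence source.

    ``chrom`` is the pseudo-chromosome the fragment was *claimed* to lie on
    (W_random / Un_random / autosome) — frequently wrong for W material,
    which is the problem the scaffolder solves.
    """

    id: str
    sequence: str
    source: str = "de-novo"
    chrom: str = "Un_random"

    def __post_init__(self) -> None:
        self.sequence = check_dna(self.sequence, f"fragment {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CountExperiment:
    """Counts + factorial design + annotation for one RNA-seq experiment.

    Parameters
    ----------
    counts
        Integer counts, genes (rows, indexed by gene id) × samples (columns).
    design
        One row per sample (index matches count columns) with columns
        ``tissue`` (blastoderm/gonad), ``sex`` (F/M) and ``replicate``.
    library_sizes
        Per-sample positive totals; defaults to column sums of ``counts``.
    annotation
        Per-gene table (indexed like ``counts``) with columns
        ``chrom_class`` and ``length``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    library_sizes: pd.Series = None  # type: ignore[assignment]
    annotation: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            if set(self.counts.columns) != set(self.design.index):
                raise ValueError("count columns and design rows disagree")
            self.design = self.design.loc[self.counts.columns]
        for col in ("tissue", "sex"):
            if col not in self.design.columns:
                raise ValueError(f"design lacks required column {col!r}")
            if self.design[col].isna().any():
                raise ValueError(f"design column {col!r} has missing values")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        if (self.library_sizes <= 0).any() or self.library_sizes.isna().any():
            raise ValueError("library sizes must be positive")
        if self.annotation is not None:
            missing = self.counts.index.difference(self.annotation.index)
            if len(missing):
                raise ValueError(
                    f"{len(missing)} genes lack annotation (e.g. {missing[0]!r})"
                )

    # -- convenience ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples(self, tissue: str | None = None, sex: str | None = None) -> list[str]:
        """Sample names matching the given tissue and/or sex."""
        mask = pd.Series(True, index=self.design.index)
        if tissue is not None:
            mask &= self.design["tissue"] == tissue
        if sex is not None:
            mask &= self.design["sex"] == sex
        return list(self.design.index[mask])

    def subset_genes(self, gene_ids) -> "CountExperiment":
        ann = None if self.annotation is None else self.annotation.loc[gene_ids]
        return CountExperiment(
            counts=self.counts.loc[gene_ids],
            design=self.design.copy(),
            library_sizes=self.library_sizes.copy(),
            annotation=ann,
        )


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated experiment.

    ``genes`` is indexed by gene id with columns:
    ``base_mean`` (expected count in a reference female sample),
    ``is_dimorphic_blastoderm``, ``is_dimorphic_gonad``, ``sex_of_bias``
    (F/M/none), ``fc_blastoderm``, ``fc_gonad`` (true male:female mean
    ratios), ``is_tissue_de``, ``tissue_fc`` (gonad:blastoderm ratio),
    ``dispersion`` and ``is_mhm`` (female-only Z locus member).
    """

    genes: pd.DataFrame
    fragments: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
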