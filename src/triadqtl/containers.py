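"""In-memory containers shared by all pipeline stages.

The pipeline's currency is a trio of tabular objects: a dosage matrix with
its marker map and pedigree metadata (:class:`GenotypeMatrix`), a TPM
expression matrix with transcript coordinates (:class:`ExpressionMatrix`),
and a per-sample trait table (:class:`TraitTable`). All three wrap pandas
objects so that downstream stages can rely on labelled alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns required in a SNP map.
MAP_COLUMNS = ["snp", "chrom", "pos"]

#: Columns required in a transcript annotation table (1-based inclusive coords).
ANNOTATION_COLUMNS = ["transcript", "gene", "chrom", "start", "end", "strand"]


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (0/1/2, NaN = missing) plus map and sample metadata.

    Attributes
    ----------
    dosages : DataFrame, samples x SNPs
        Count of the alternate allele; NaN encodes a missing genotype.
    snp_map : DataFrame with columns ``snp, chrom, pos`` (1-based bp).
    pedigree : DataFrame indexed by sample with columns ``sire, dam,
        generation`` (``0`` for unknown parents; generation in {0, 1, 2}).
    sex : Series indexed by sample; 1 = male, 2 = female (PED convention).
    batch : Series indexed by sample; slaughter/processing batch label.
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame
    pedigree: pd.DataFrame = field(default_factory=pd.DataFrame)
    sex: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    batch: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise ValueError(f"snp_map lacks columns {missing}")
        self.snp_map = self.snp_map.set_index("snp", drop=False) if (
            self.snp_map.index.name != "snp"
        ) else self.snp_map
        if not self.snp_map.index.equals(pd.Index(self.dosages.columns)):
            self.snp_map = self.snp_map.loc[self.dosages.columns]

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def snps(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        """Return a view restricted to the given samples and/or SNPs."""
        d = self.dosages
        if samples is not None:
            d = d.loc[samples]
        if snps is not None:
            d = d[snps]
        return GenotypeMatrix(
            dosages=d,
            snp_map=self.snp_map.loc[d.columns],
            pedigree=self.pedigree,
            sex=self.sex.reindex(d.index),
            batch=self.batch.reindex(d.index),
        )

    def f2_samples(self) -> pd.Index:
        """Samples of the final (F2) generation, per the pedigree."""
        if self.pedigree.empty or "generation" not in self.pedigree.columns:
            return self.samples
        gen2 = self.pedigree.index[self.pedigree["generation"] == 2]
        return self.samples.intersection(gen2)

    def chrom_lengths(self) -> dict:
        """Per-chromosome extent (bp) inferred from the marker map."""
        return self.snp_map.groupby("chrom")["pos"].max().to_dict()


@dataclass
class ExpressionMatrix:
    """Samples x transcripts TPM values plus transcript coordinates.

    ``annotation`` uses 1-based inclusive genomic coordinates internally;
    conversion to/from BED (0-based half-open) happens at the file boundary.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.annotation.empty:
            missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotation.columns]
            if missing:
                raise ValueError(f"annotation lacks columns {missing}")
            if self.annotation.index.name != "transcript":
                self.annotation = self.annotation.set_index("transcript", drop=False)

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def transcripts(self) -> pd.Index:
        return self.values.columns

    def log_values(self) -> pd.DataFrame:
        """Natural-log TPM with a pseudocount of 1, the scan-ready scale."""
        return np.log1p(self.values)


@dataclass
class TraitTable:
    """Per-sample measured and derived meat-quality trait values."""

    values: pd.DataFrame

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def traits(self) -> pd.Index:
        return self.values.columns

    def __getitem__(self, trait: str) -> pd.Series:
        return self.values[trait]
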