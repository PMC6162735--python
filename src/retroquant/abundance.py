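"""Reads-per-million repeat-family abundance.

The abundance of a family in a genotype is the total number of reads mapped
to any contig of that family, per million reads used for mapping.  The
denominator is the post-trim input read count, not the mapped count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .readmap import AssignmentTable


class IntegrityError(ValueError):
    """Assignment refers to a contig absent from the library map."""


def count_family_abundance(assignments: AssignmentTable,
                           library_map: Mapping[str, str],
                           n_input_reads: int | None = None,
                           family_order: list[str] | None = None) -> pd.Series:
    """Per-family mapped reads per million input reads.

    Families present in ``library_map`` (or ``family_order``) but receiving
    no reads appear with value 0.
    """
    if n_input_reads is None:
        n_input_reads = assignments.n_input_reads
    if n_input_reads < assignments.n_mapped:
        raise IntegrityError("n_input_reads below the mapped read count")
    contig_counts = assignments.target_counts()
    missing = [c for c in contig_counts.index[contig_counts > 0]
               if c not in library_map]
    if missing:
        raise IntegrityError(f"mapped contigs not in library map: {missing[:5]}")
    if family_order is None:
        family_order = list(dict.fromkeys(library_map.values()))
    fam_counts = pd.Series(0.0, index=pd.Index(family_order, name="family_id"))
    for contig, cnt in contig_counts.items():
        fam = library_map.get(contig)
        if fam in fam_counts.index:
            fam_counts[fam] += cnt
    scale = 1e6 / n_input_reads if n_input_reads > 0 else 0.0
    return fam_counts * scale


@dataclass
class AbundanceMatrix:
    """Genotypes x families matrix of reads-per-million, with group labels."""

    values: pd.DataFrame           # index genotypes, columns family_ids
    groups: pd.Series              # genotype -> 'wild' | 'cultivated'
    n_input_reads: pd.Series       # genotype -> reads used for mapping

    def __post_init__(self):
        v = self.values
        if (v.values < 0).any() or (v.values > 1e6 + 1e-6).any():
            raise ValueError("abundances must lie in [0, 1e6] per million")
        if not v.index.equals(self.groups.index):
            self.groups = self.groups.reindex(v.index)
        if self.groups.isna().any():
            raise ValueError("every genotype needs a group label")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_means(self) -> pd.DataFrame:
        return self.values.groupby(self.groups).mean()

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.insert(1, "n_input_reads", self.n_input_reads)
        out.index.name = "genotype"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="genotype")
        groups = df.pop("group")
        n_reads = df.pop("n_input_reads")
        return cls(values=df, groups=groups, n_input_reads=n_reads)


def build_abundance_matrix(vectors: Mapping[str, pd.Series],
                           group_labels: Mapping[str, str],
                           n_input_reads: Mapping[str, int] | None = None
                           ) -> AbundanceMatrix:
    """Assemble per-genotype abundance vectors into one matrix.

    Column order follows the first genotype's family order (the library
    order).  Duplicated genotypes are an error.
    """
    names = list(vectors)
    if len(set(names)) != len(names):
        raise ValueError("duplicated genotype ids")
    per_group = pd.Series(group_labels).value_counts()
    if (per_group < 2).any() or len(per_group) < 2:
        raise ValueError("need >= 2 genotypes in each of two groups")
    values = pd.DataFrame({g: vectors[g] for g in names}).T
    values.index.name = "genotype"
    groups = pd.Series({g: group_labels[g] for g in names}, name="group")
    if n_input_reads is None:
        n_input_reads = {g: 0 for g in names}
    nreads = pd.Series({g: int(n_input_reads[g]) for g in names},
                       name="n_input_reads")
    return AbundanceMatrix(values=values, groups=groups, n_input_reads=nreads)
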