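"""Gene-RE pairs: read pairs bridging a repeat family and a gene.

A read pair in which one mate maps to a repeat-library contig and the other
to a transcriptome gene ("gene-RE pair") is evidence of a repeat insertion
within fragment range of that gene.  Per-genotype pair counts are normalised
per million read pairs; groups are compared per family by univariate
PERMANOVA, and the pathway spectra of the pooled per-group gene lists are
compared per pathway the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import IntegrityError
from .famstats import euclidean_distance_matrix, permanova
from .readmap import PairAssignmentTable

PAIR_COLUMNS = ["genotype", "family_id", "gene_id", "read_id"]


def extract_gene_re_pairs(pair_table: PairAssignmentTable,
                          library_map: Mapping[str, str],
                          gene_ids: Sequence[str],
                          genotype: str = "",
                          family_subset: Sequence[str] | None = None
                          ) -> pd.DataFrame:
    """Select pairs with exactly one repeat mate and one gene mate.

    Repeat-repeat and gene-gene pairs are discarded; mate order is
    irrelevant.  A mapped target belonging to neither the repeat library nor
    the gene set is an integrity error.  ``family_subset`` optionally
    restricts the repeat mate to the given families (the pipeline passes the
    significant subset).
    """
    names = pair_table.mate1.ref_names
    gene_set = set(gene_ids)
    kind = np.zeros(len(names) + 1, dtype=np.int8)  # 1 repeat, 2 gene
    fam_of = np.array([""] * (len(names) + 1), dtype=object)
    for i, n in enumerate(names):
        if n in library_map:
            kind[i] = 1
            fam_of[i] = library_map[n]
        elif n in gene_set:
            kind[i] = 2
        else:
            kind[i] = -1
    t1 = pair_table.mate1.target_idx
    t2 = pair_table.mate2.target_idx
    both = pair_table.both_mapped
    k1, k2 = kind[t1], kind[t2]
    bad = both & ((k1 == -1) | (k2 == -1))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        name = names[t1[i]] if kind[t1[i]] == -1 else names[t2[i]]
        raise IntegrityError(
            f"target {name!r} in neither repeat library nor gene set")
    sel = both & (((k1 == 1) & (k2 == 2)) | ((k1 == 2) & (k2 == 1)))
    idx = np.flatnonzero(sel)
    repeat_t = np.where(k1[idx] == 1, t1[idx], t2[idx])
    gene_t = np.where(k1[idx] == 1, t2[idx], t1[idx])
    read_ids = (np.array(pair_table.read_ids, dtype=object)[idx]
                if pair_table.read_ids is not None
                else np.array([f"pair{i}" for i in idx], dtype=object))
    out = pd.DataFrame({
        "genotype": genotype,
        "family_id": fam_of[repeat_t],
        "gene_id": np.array(names, dtype=object)[gene_t],
        "read_id": read_ids,
    })
    if family_subset is not None:
        out = out[out["family_id"].isin(set(family_subset))]
    return out.reset_index(drop=True)


@dataclass
class PairRateMatrix:
    """Genotypes x families matrix of gene-RE pairs per million read pairs."""

    values: pd.DataFrame
    groups: pd.Series
    n_read_pairs: pd.Series

    def group_means(self) -> pd.DataFrame:
        return self.values.groupby(self.groups).mean()

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.insert(1, "n_read_pairs", self.n_read_pairs)
        out.index.name = "genotype"
        out.to_csv(path, sep="\t", float_format="%.6f")


def pair_rates(pairs: pd.DataFrame,
               n_read_pairs: Mapping[str, int],
               group_labels: Mapping[str, str],
               family_order: Sequence[str]) -> PairRateMatrix:
    """Per-genotype, per-family gene-RE pairs per million read pairs."""
    genotypes = list(n_read_pairs)
    counts = (pairs.groupby(["genotype", "family_id"]).size()
              .unstack(fill_value=0)
              .reindex(index=genotypes, columns=list(family_order),
                       fill_value=0))
    for g in genotypes:
        n_pairs_g = int((pairs["genotype"] == g).sum())
        if n_read_pairs[g] < n_pairs_g:
            raise IntegrityError(f"{g}: more gene-RE pairs than read pairs")
    denom = pd.Series({g: float(n_read_pairs[g]) for g in genotypes})
    rates = counts.div(denom, axis=0) * 1e6
    groups = pd.Series({g: group_labels[g] for g in genotypes}, name="group")
    return PairRateMatrix(values=rates, groups=groups,
                          n_read_pairs=pd.Series(n_read_pairs))


def _stars(p: float, alphas: tuple[float, float] = (0.05, 0.001)) -> str:
    hi, lo = max(alphas), min(alphas)
    if p < lo:
        return "***"
    if p < hi:
        return "*"
    return ""


def compare_pair_rates(matrix: PairRateMatrix,
                       alphas: tuple[float, float] = (0.05, 0.001),
                       n_permutations: int = 999,
                       seed: int = 0,
                       metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-family PERMANOVA of gene-RE pair rates between groups.

    Star coding at the two thresholds (default * p < 0.05, *** p < 0.001);
    group and superfamily means are reported alongside.
    """
    groups = matrix.groups.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for fam in matrix.values.columns:
        x = matrix.values[fam].to_numpy(dtype=float)
        D = euclidean_distance_matrix(x)
        res = permanova(D, groups, n_permutations=n_permutations,
                        seed=int(rng.integers(0, 2**31 - 1)))
        rows.append((fam,
                     float(x[groups == "cultivated"].mean()),
                     float(x[groups == "wild"].mean()),
                     res.pseudo_F, res.p_value, _stars(res.p_value, alphas)))
    out = pd.DataFrame(rows, columns=["family_id", "mean_cultivated",
                                      "mean_wild", "pseudo_F", "p_value",
                                      "stars"])
    if metadata is not None:
        out = metadata[["family_id", "lineage", "superfamily"]].merge(
            out, on="family_id", how="right")
    return out


def superfamily_means(comparison: pd.DataFrame) -> pd.DataFrame:
    """Mean pair rates per superfamily (the Gypsy-vs-Copia roll-up)."""
    if "superfamily" not in comparison.columns:
        raise ValueError("comparison lacks superfamily metadata")
    return (comparison.groupby("superfamily")
            [["mean_cultivated", "mean_wild"]].mean().reset_index())


def pool_gene_lists(pairs: pd.DataFrame,
                    group_labels: Mapping[str, str]) -> dict[str, pd.Series]:
    """Per-group gene lists with multiplicity (pairs pooled over genotypes)."""
    out: dict[str, pd.Series] = {}
    glab = pairs["genotype"].map(dict(group_labels))
    for group in sorted(set(group_labels.values())):
        sel = pairs[glab == group]
        out[group] = sel.groupby("gene_id").size().sort_index()
    return out


def pathway_spectrum(gene_lists: Mapping[str, pd.Series],
                     annotation: pd.DataFrame,
                     pairs: pd.DataFrame | None = None,
                     group_labels: Mapping[str, str] | None = None,
                     alphas: tuple[float, float] = (0.05, 0.001),
                     n_permutations: int = 999,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway term spectrum of the pooled per-group gene lists.

    Each pooled gene occurrence contributes one count per pathway annotation
    of that gene (term-level counting); genes without annotation are tallied
    under 'unannotated' and excluded from the percentages.  When per-genotype
    pairs and group labels are supplied, each pathway is additionally
    compared between groups by univariate PERMANOVA over per-genotype term
    counts, star-coded like the pair-rate comparison.

    Returns (spectrum, comparison).
    """
    if annotation.empty:
        warnings.warn("empty pathway annotation: all genes unannotated, "
                      "group comparison skipped")
        rows = [(g, "unannotated", int(lst.sum()), np.nan)
                for g, lst in gene_lists.items()]
        return (pd.DataFrame(rows, columns=["group", "pathway", "count",
                                            "percent"]),
                pd.DataFrame(columns=["pathway", "mean_cultivated",
                                      "mean_wild", "pseudo_F", "p_value",
                                      "stars"]))
    ann = annotation.groupby("gene_id")["pathway"].apply(list)
    spec_rows: list[tuple] = []
    for group, lst in gene_lists.items():
        counts: dict[str, int] = {}
        for gene, mult in lst.items():
            pws = ann.get(gene, [])
            if not pws:
                counts["unannotated"] = counts.get("unannotated", 0) + int(mult)
            for p in pws:
                counts[p] = counts.get(p, 0) + int(mult)
        total = sum(c for p, c in counts.items() if p != "unannotated")
        for p, c in sorted(counts.items()):
            pct = 100.0 * c / total if (total and p != "unannotated") else np.nan
            spec_rows.append((group, p, c, pct))
    spectrum = pd.DataFrame(spec_rows,
                            columns=["group", "pathway", "count", "percent"])

    comparison = pd.DataFrame(columns=["pathway", "mean_cultivated",
                                       "mean_wild", "pseudo_F", "p_value",
                                       "stars"])
    if pairs is not None and group_labels is not None and len(pairs):
        expanded = pairs.merge(annotation, on="gene_id", how="inner")
        genotypes = list(group_labels)
        counts = (expanded.groupby(["genotype", "pathway"]).size()
                  .unstack(fill_value=0)
                  .reindex(index=genotypes, fill_value=0))
        groups = np.array([group_labels[g] for g in genotypes])
        rng = np.random.default_rng(seed)
        rows = []
        for pw in counts.columns:
            x = counts[pw].to_numpy(dtype=float)
            res = permanova(euclidean_distance_matrix(x), groups,
                            n_permutations=n_permutations,
                            seed=int(rng.integers(0, 2**31 - 1)))
            rows.append((pw,
                         float(x[groups == "cultivated"].mean()),
                         float(x[groups == "wild"].mean()),
                         res.pseudo_F, res.p_value,
                         _stars(res.p_value, alphas)))
        comparison = pd.DataFrame(rows, columns=comparison.columns)
    return spectrum, comparison
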