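"""Gene-RE pair extraction, rates, pooling and pathway spectra."""

import numpy as np
import pandas as pd
import pytest

from retroquant.abundance import IntegrityError
from retroquant.proximity import (PairRateMatrix, compare_pair_rates,
                                  extract_gene_re_pairs, pair_rates,
                                  pathway_spectrum, pool_gene_lists)
from retroquant.readmap import AssignmentTable, PairAssignmentTable

REFS = ["c1", "c2", "geneA", "geneB"]
LIBMAP = {"c1": "F1", "c2": "F2"}
GENES = ["geneA", "geneB"]


def _pair_table(assignments):
    """assignments: list of (target1 | None, target2 | None)."""
    def table(col):
        idx = np.array([REFS.index(a[col]) if a[col] is not None else -1
                        for a in assignments], dtype=np.int64)
        return AssignmentTable(
            target_idx=idx, strand=np.ones(len(idx), dtype=np.int8),
            identity=np.ones(len(idx), dtype=np.float32),
            ref_names=REFS, n_input_reads=len(idx))
    return PairAssignmentTable(mate1=table(0), mate2=table(1))


class TestExtraction:
    def test_definition_and_discards(self):
        pt = _pair_table([("geneA", "geneB"),   # gene-gene: discarded
                          ("c1", "c2"),          # repeat-repeat: discarded
                          ("c1", "geneA"),       # kept
                          ("geneB", "c2"),       # kept (order irrelevant)
                          (None, "geneA")])      # not in pair
        pairs = extract_gene_re_pairs(pt, LIBMAP, GENES, genotype="g1")
        assert len(pairs) == 2
        assert set(zip(pairs.family_id, pairs.gene_id)) == \
            {("F1", "geneA"), ("F2", "geneB")}

    def test_mate_swap_symmetry(self):
        a = [("c1", "geneA"), ("geneB", "c2")]
        swapped = [(y, x) for x, y in a]
        p1 = extract_gene_re_pairs(_pair_table(a), LIBMAP, GENES)
        p2 = extract_gene_re_pairs(_pair_table(swapped), LIBMAP, GENES)
        cols = ["family_id", "gene_id"]
        assert p1[cols].equals(p2[cols])

    def test_unknown_target_integrity_error(self):
        pt = _pair_table([("c1", "geneA")])
        with pytest.raises(IntegrityError):
            extract_gene_re_pairs(pt, {}, GENES)

    def test_family_subset_filter(self):
        pt = _pair_table([("c1", "geneA"), ("c2", "geneA")])
        pairs = extract_gene_re_pairs(pt, LIBMAP, GENES,
                                      family_subset=["F1"])
        assert set(pairs.family_id) == {"F1"}


class TestRates:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["genotype", "family_id",
                                           "gene_id", "read_id"])

    def test_zero_pairs(self):
        m = pair_rates(self._pairs([]), {"g1": 1000, "g2": 1000},
                       {"g1": "wild", "g2": "cultivated"}, ["F1"])
        assert (m.values.values == 0).all()

    def test_per_million_arithmetic(self):
        rows = [("g1", "F1", "geneA", f"r{i}") for i in range(10)]
        m = pair_rates(self._pairs(rows), {"g1": 2_000_000, "g2": 2_000_000},
                       {"g1": "wild", "g2": "cultivated"}, ["F1"])
        assert m.values.loc["g1", "F1"] == pytest.approx(5.0)

    def test_identical_groups_not_significant(self, rng):
        vals = pd.DataFrame({"F1": np.tile([3.0, 4.0], 3)},
                            index=[f"g{i}" for i in range(6)])
        m = PairRateMatrix(
            values=vals,
            groups=pd.Series(["wild", "wild", "wild", "cultivated",
                              "cultivated", "cultivated"], index=vals.index),
            n_read_pairs=pd.Series(1000, index=vals.index))
        res = compare_pair_rates(m, n_permutations=999, seed=0)
        assert res["p_value"].iloc[0] > 0.05
        assert res["stars"].iloc[0] == ""


class TestPooling:
    def _pairs(self):
        rows = [("w1", "F1", "geneA", "r1"),
                ("w2", "F1", "geneA", "r2"),
                ("w1", "F2", "geneB", "r3"),
                ("c1", "F1", "geneB", "r4")]
        return pd.DataFrame(rows, columns=["genotype", "family_id",
                                           "gene_id", "read_id"])

    GROUPS = {"w1": "wild", "w2": "wild", "c1": "cultivated"}

    def test_multiplicity_and_conservation(self):
        lists = pool_gene_lists(self._pairs(), self.GROUPS)
        assert lists["wild"]["geneA"] == 2
        assert lists["wild"].sum() + lists["cultivated"].sum() == 4
        assert list(lists["cultivated"].index) == ["geneB"]


class TestPathways:
    ANNOT = pd.DataFrame({
        "gene_id": ["geneA", "geneB", "geneB"],
        "pathway": ["Oxidative phosphorylation", "Sulfur metabolism",
                    "Ribosome"],
    })

    def test_single_gene_full_percentage(self):
        lists = {"wild": pd.Series({"geneA": 3}),
                 "cultivated": pd.Series(dtype=int)}
        spec, _ = pathway_spectrum(lists, self.ANNOT)
        w = spec[spec.group == "wild"]
        assert w["percent"].iloc[0] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        lists = {"wild": pd.Series({"geneA": 2, "geneB": 1})}
        spec, _ = pathway_spectrum(lists, self.ANNOT)
        w = spec[(spec.group == "wild") & (spec.pathway != "unannotated")]
        assert w["percent"].sum() == pytest.approx(100.0)

    def test_term_level_counting(self):
        lists = {"wild": pd.Series({"geneB": 2})}
        spec, _ = pathway_spectrum(lists, self.ANNOT)
        w = spec[spec.group == "wild"].set_index("pathway")["count"]
        assert w["Sulfur metabolism"] == 2 and w["Ribosome"] == 2

    def test_empty_annotation_warns(self):
        lists = {"wild": pd.Series({"geneA": 1})}
        with pytest.warns(UserWarning):
            spec, comp = pathway_spectrum(
                lists, pd.DataFrame(columns=["gene_id", "pathway"]))
        assert comp.empty

    def test_planted_enrichment_detected(self, rng):
        """Wild gene-RE genes enriched 3x for one pathway come out
        significant with wild > cultivated."""
        genes = [f"gene{i}" for i in range(40)]
        annot = pd.DataFrame({
            "gene_id": genes,
            "pathway": ["Sulfur metabolism" if i < 20 else "Ribosome"
                        for i in range(40)],
        })
        rows = []
        genotypes = {f"w{i}": "wild" for i in range(4)}
        genotypes.update({f"c{i}": "cultivated" for i in range(4)})
        r = 0
        for g, grp in genotypes.items():
            p_target = 0.75 if grp == "wild" else 0.25
            for _ in range(30):
                if rng.random() < p_target:
                    gene = genes[int(rng.integers(0, 20))]
                else:
                    gene = genes[int(rng.integers(20, 40))]
                rows.append((g, "F1", gene, f"r{r}"))
                r += 1
        pairs = pd.DataFrame(rows, columns=["genotype", "family_id",
                                            "gene_id", "read_id"])
        lists = pool_gene_lists(pairs, genotypes)
        spec, comp = pathway_spectrum(lists, annot, pairs=pairs,
                                      group_labels=genotypes,
                                      n_permutations=999, seed=0)
        row = comp[comp.pathway == "Sulfur metabolism"].iloc[0]
        assert row["p_value"] < 0.05
        assert row["mean_wild"] > row["mean_cultivated"]


class TestEndToEndRecovery:
    def test_zero_adjacency_zero_pairs(self, tiny_cohort):
        """A cohort variant with no gene-adjacent insertions yields no
        gene-RE pairs from true (non-chimeric) fragments."""
        import dataclasses
        from retroquant.readmap import MappingParams, map_pairs
        from retroquant.synthcohort import (build_genotype, simulate_cohort)
        cfg = dataclasses.replace(tiny_cohort.config,
                                  gene_adjacent_fraction=0.0, seed=77)
        cohort = simulate_cohort(cfg)
        gid = cohort.genotypes[0][0]
        r1, r2 = cohort.reads(gid, seed=5, n_pairs=5000)
        combined = dict(cohort.library.contigs)
        combined.update(cohort.gene_set.genes)
        pt = map_pairs(r1, r2, combined, MappingParams(seed=1))
        pairs = extract_gene_re_pairs(pt, cohort.library.contig_to_family,
                                      list(cohort.gene_set.genes),
                                      genotype=gid)
        assert len(pairs) == 0

    def test_pairs_track_adjacent_insertions(self, tiny_cohort):
        """Families with planted gene-adjacent copies generate gene-RE
        pairs; per-family pair counts correlate with the planted counts."""
        from retroquant.readmap import MappingParams, map_pairs
        from scipy.stats import spearmanr
        cohort = tiny_cohort
        combined = dict(cohort.library.contigs)
        combined.update(cohort.gene_set.genes)
        all_pairs = []
        for gid, _ in cohort.genotypes[:3]:
            r1, r2 = cohort.reads(gid, seed=50, n_pairs=20000)
            pt = map_pairs(r1, r2, combined, MappingParams(seed=2))
            all_pairs.append(extract_gene_re_pairs(
                pt, cohort.library.contig_to_family,
                list(cohort.gene_set.genes), genotype=gid))
        pairs = pd.concat(all_pairs)
        assert len(pairs) > 0
        counts = pairs.groupby("family_id").size()
        adj = cohort.true_adjacent_counts().iloc[:3].sum()
        both = pd.concat([counts, adj], axis=1).fillna(0)
        rho = spearmanr(both.iloc[:, 0], both.iloc[:, 1])[0]
        assert rho > 0.5
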