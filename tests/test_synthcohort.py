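"""Generator correctness: determinism, planted structure, read statistics."""

import dataclasses

import edlib
import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from retroquant import seqio
from retroquant.synthcohort import (CohortConfig, CohortSizingError,
                                    ConfigurationError, RepeatFamilySpec,
                                    build_genotype, generate_gene_set,
                                    generate_re_library,
                                    reference_family_specs, simulate_cohort,
                                    simulate_reads)
from .conftest import small_specs


class TestLibrary:
    def test_identity_bookkeeping(self):
        specs = [RepeatFamilySpec("A", "Chromovirus", consensus_length=1000,
                                  n_contigs=1),
                 RepeatFamilySpec("B", "Angela", consensus_length=1000,
                                  n_contigs=1)]
        lib = generate_re_library(specs, seed=0)
        assert len(lib.contigs) == 2
        assert lib.contig_to_family == {"A_c1": "A", "B_c1": "B"}

    def test_determinism(self, tmp_path):
        specs = small_specs(3)
        paths = []
        for run in (1, 2):
            lib = generate_re_library(specs, seed=7)
            p = tmp_path / f"lib{run}.fasta"
            lib.write(p, tmp_path / f"map{run}.tsv")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_reference_hierarchy_split(self):
        """The 22-family default hierarchy is 18 Gypsy / 4 Copia."""
        lib = generate_re_library(reference_family_specs(), seed=0)
        counts = lib.metadata["superfamily"].value_counts()
        assert counts["Gypsy"] == 18
        assert counts["Copia"] == 4
        lineages = lib.metadata.groupby("lineage")["superfamily"].nunique()
        assert (lineages == 1).all()  # lineage -> superfamily is a function

    def test_duplicate_family_id_rejected(self):
        specs = [RepeatFamilySpec("A", "Athila"),
                 RepeatFamilySpec("A", "Angela")]
        with pytest.raises(ConfigurationError):
            generate_re_library(specs, seed=0)

    def test_contig_divergence_and_family_separation(self):
        lib = generate_re_library(small_specs(4, consensus_length=800), seed=3)
        # contigs stay close to their own consensus ...
        for cid, seq in lib.contigs.items():
            fam = lib.contig_to_family[cid]
            d = edlib.align(seq, lib.consensus[fam], task="distance")["editDistance"]
            assert d / len(seq) <= 0.05 + 0.01
        # ... while 90-nt windows of one family stay far from other families
        rng = np.random.default_rng(0)
        fams = list(lib.consensus)
        for _ in range(20):
            fa, fb = rng.choice(fams, 2, replace=False)
            s = int(rng.integers(0, len(lib.consensus[fa]) - 90))
            win = lib.consensus[fa][s:s + 90]
            d = edlib.align(win, lib.consensus[fb], mode="HW",
                            task="distance")["editDistance"]
            assert 1 - d / 90 < 0.70


class TestGeneSet:
    def test_single_gene_single_pathway(self):
        gs = generate_gene_set(1, ["Ribosome"], seed=0,
                               unannotated_fraction=0.0)
        assert len(gs.genes) == 1
        assert len(gs.annotation) >= 1

    def test_pathway_labels_verbatim(self):
        labels = ["Oxidative phosphorylation", "Sulfur metabolism",
                  "Cysteine and methionine metabolism"]
        gs = generate_gene_set(60, labels, seed=1, unannotated_fraction=0.0)
        assert set(gs.annotation["pathway"]) <= set(labels)
        assert set(gs.annotation["pathway"]) == set(labels)

    def test_determinism(self):
        a = generate_gene_set(10, ["P1"], seed=5)
        b = generate_gene_set(10, ["P1"], seed=5)
        assert a.genes == b.genes
        assert a.annotation.equals(b.annotation)


class TestGenotype:
    def _cfg(self, **kw):
        base = dict(n_wild=2, n_cultivated=2, families=small_specs(3),
                    base_copy_number=20, n_genes=40,
                    background_length=60_000, coverage=100, seed=1)
        base.update(kw)
        return CohortConfig(**base)

    def test_null_fold_change_equal_expectation(self):
        """fold_change 1 leaves group copy-number expectations equal."""
        cfg = self._cfg(base_copy_number=50)
        lib = generate_re_library(cfg.families, 1)
        gs = generate_gene_set(cfg.n_genes, cfg.pathway_labels, 2)
        counts = {"wild": [], "cultivated": []}
        for i in range(6):
            for grp in counts:
                _, truth, _ = build_genotype(cfg, lib, gs, grp, f"g{i}", 100 + i * 2
                                             + (0 if grp == "wild" else 1))
                counts[grp].append(len(truth))
        mw, mc = np.mean(counts["wild"]), np.mean(counts["cultivated"])
        # each mean is over 6 Poisson(150) draws; 3 SE band
        se = np.sqrt(150 / 6) * np.sqrt(2) * 3
        assert abs(mw - mc) < se * 3

    def test_poisson_copy_number(self):
        """Cultivated copies with fold 2 land in the Poisson 99% interval."""
        cfg = self._cfg(families=small_specs(1), base_copy_number=100,
                        fold_change=2.0, n_genes=150,
                        background_length=50_000)
        lib = generate_re_library(cfg.families, 1)
        gs = generate_gene_set(cfg.n_genes, cfg.pathway_labels, 2)
        lo, hi = poisson.ppf([0.005, 0.995], 200)
        inside = 0
        for i in range(10):
            _, truth, _ = build_genotype(cfg, lib, gs, "cultivated",
                                         f"g{i}", 500 + i)
            inside += lo <= len(truth) <= hi
        assert inside >= 9

    def test_zero_adjacency(self):
        cfg = self._cfg(gene_adjacent_fraction=0.0)
        lib = generate_re_library(cfg.families, 1)
        gs = generate_gene_set(cfg.n_genes, cfg.pathway_labels, 2)
        _, truth, _ = build_genotype(cfg, lib, gs, "wild", "w1", 9)
        assert not truth["gene_adjacent"].any()

    def test_adjacent_insertions_near_named_gene(self, tiny_cohort):
        truth = tiny_cohort.truth
        genes = tiny_cohort.gene_positions.set_index(["genotype", "gene_id"])
        limit = tiny_cohort.config.adjacent_distance
        adj = truth[truth.gene_adjacent]
        assert len(adj) > 0
        for _, row in adj.iterrows():
            g = genes.loc[(row.genotype, row.gene_id)]
            dist = max(g.start - row.end, row.start - g.end, 0)
            assert dist <= limit

    def test_insertions_do_not_overlap_genes(self, tiny_cohort):
        for gid, _ in tiny_cohort.genotypes:
            ins = tiny_cohort.truth.query("genotype == @gid")
            gen = tiny_cohort.gene_positions.query("genotype == @gid")
            starts = gen["start"].to_numpy()
            ends = gen["end"].to_numpy()
            for s, e in zip(ins["start"], ins["end"]):
                assert not ((s < ends) & (e > starts)).any()

    def test_planted_bases_conserved(self, tiny_cohort):
        """Total planted repeat bases equals the truth-row span sum and each
        recorded interval decodes near its family consensus."""
        cohort = tiny_cohort
        truth = cohort.truth
        spans = (truth["end"] - truth["start"]).sum()
        cons_len = {s.family_id: s.consensus_length
                    for s in cohort.config.families}
        assert spans == sum(cons_len[f] for f in truth["family_id"])
        rng = np.random.default_rng(0)
        sample = truth.sample(10, random_state=1)
        for _, row in sample.iterrows():
            g = cohort.genomes[row.genotype]
            codes = g[row.start:row.end]
            if row.strand == "-":
                codes = seqio.revcomp_codes(codes)
            d = edlib.align(seqio.decode(codes),
                            cohort.library.consensus[row.family_id],
                            task="distance")["editDistance"]
            assert d / len(codes) <= cohort.config.copy_divergence * 2 + 0.01

    def test_sizing_error(self):
        cfg = self._cfg(base_copy_number=200, gene_adjacent_fraction=1.0,
                        n_genes=5)
        lib = generate_re_library(cfg.families, 1)
        gs = generate_gene_set(cfg.n_genes, cfg.pathway_labels, 2)
        with pytest.raises(CohortSizingError):
            build_genotype(cfg, lib, gs, "wild", "w1", 3)


class TestReads:
    def test_error_free_reads_are_substrings(self, rng):
        genome = seqio.decode(rng.integers(0, 4, 5000).astype(np.uint8))
        r1, r2 = simulate_reads(genome, 20, 50, 200, 20, 0.0, seed=3)
        rc = seqio.revcomp(genome)
        for a, b in zip(r1, r2):
            assert a in genome or a in rc
            assert b in genome or b in rc

    def test_fixed_insert_outer_distance(self, rng):
        genome = seqio.decode(rng.integers(0, 4, 5000).astype(np.uint8))
        r1, r2 = simulate_reads(genome, 30, 40, 250, 0.0, 0.0, seed=4)
        for a, b in zip(r1, r2):
            s = genome.find(a)
            e = genome.find(seqio.revcomp(b)) + 40
            assert e - s == 250

    def test_error_rate_calibration(self):
        """Observed substitution fraction matches the configured rate."""
        genome = "A" * 20000  # errors are exactly the non-A / non-T bases
        r1, r2 = simulate_reads(genome, 10000, 90, 300, 30, 0.01, seed=8)
        n1 = sum(90 - r.count("A") for r in r1)
        n2 = sum(90 - r.count("T") for r in r2)
        frac = (n1 + n2) / (2 * 10000 * 90)
        assert 0.008 <= frac <= 0.012

    def test_empty_and_determinism(self):
        genome = "ACGT" * 2000
        assert simulate_reads(genome, 0, 50, 200, 10, 0.0, 1) == ([], [])
        a = simulate_reads(genome, 50, 50, 200, 10, 0.01, 9)
        b = simulate_reads(genome, 50, 50, 200, 10, 0.01, 9)
        assert a == b


class TestCohort:
    def test_group_effect_recovery(self):
        """Mean cultivated/wild copy ratio converges to fold_change."""
        cfg = CohortConfig(n_wild=4, n_cultivated=4,
                           families=small_specs(2), base_copy_number=150,
                           fold_change={"FAM01": 2.0, "FAM02": 1.0},
                           n_genes=100, coverage=100,
                           background_length=50_000, seed=11)
        cohort = simulate_cohort(cfg)
        cn = cohort.true_copy_numbers()
        groups = dict(cohort.genotypes)
        cult = cn.loc[[g for g in cn.index if groups[g] == "cultivated"]]
        wild = cn.loc[[g for g in cn.index if groups[g] == "wild"]]
        ratio = cult["FAM01"].mean() / wild["FAM01"].mean()
        assert 1.7 < ratio < 2.3
        ratio_null = cult["FAM02"].mean() / wild["FAM02"].mean()
        assert 0.85 < ratio_null < 1.15

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = CohortConfig(families=small_specs(2),
                           fold_change={"FAM01": 1.5, "FAM02": 1.0})
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = CohortConfig.from_yaml(p)
        assert back.family_ids == cfg.family_ids
        assert back.resolved("fold_change") == cfg.resolved("fold_change")

    def test_invalid_configs(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_wild=1)
        with pytest.raises(ConfigurationError):
            CohortConfig(error_rate=0.5)
        with pytest.raises(ConfigurationError):
            CohortConfig(read_length=400, insert_mu=300)
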