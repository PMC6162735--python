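"""End-to-end orchestration: simulate -> map -> abundance -> famstats ->
landscape -> proximity, from one configuration and one master seed.

The master seed fans out to named per-stage streams (SHA-256 of
``"<master>:<stage>"``), so every stage is independently reproducible and a
rerun with the same master seed is byte-identical.  All intermediate
artifacts are plain text (FASTA/FASTQ/TSV/bedGraph/YAML) so any stage can be
rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import abundance as ab
from . import famstats, landscape, proximity, seqio
from .readmap import MappingParams, ReferenceIndex, map_pairs, map_readset
from .synthcohort import (CohortConfig, Cohort, GeneSet, RepeatLibrary,
                          simulate_cohort)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mapping: MappingParams = field(default_factory=MappingParams)
    alpha: float = 0.01
    n_permutations: int = 999
    pair_alphas: tuple[float, float] = (0.05, 0.001)
    window_size: int = 50_000        # synthetic scale; 3 Mbp on real genomes
    seed: int = 0
    write_reads: bool = False
    write_genomes: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in d:
            import tempfile
            # round-trip through CohortConfig's own loader
            cc = d["cohort"]
            from .synthcohort import RepeatFamilySpec
            fams = cc.pop("families", None)
            if fams is not None:
                cc["families"] = [RepeatFamilySpec(**f) for f in fams]
            if "adjacency_gap" in cc:
                cc["adjacency_gap"] = tuple(cc["adjacency_gap"])
            kwargs["cohort"] = CohortConfig(**cc)
        if "mapping" in d:
            kwargs["mapping"] = MappingParams(**d["mapping"])
        for k in ("alpha", "n_permutations", "window_size", "seed",
                  "write_reads", "write_genomes"):
            if k in d:
                kwargs[k] = d[k]
        if "pair_alphas" in d:
            kwargs["pair_alphas"] = tuple(d["pair_alphas"])
        return cls(**kwargs)


def demo_cohort_config(seed: int = 0) -> CohortConfig:
    """The default demonstration cohort: 8 cultivated vs 7 wild genotypes,
    the 22-family Gypsy/Copia hierarchy, with planted group effects.

    Eight families (seven Chromovirus, one TAR/Tork) are more abundant in
    cultivated genotypes and fourteen in wild ones, and the Gypsy families
    sit nearer genes in wild genotypes, mirroring the structure the pipeline
    is meant to detect.
    """
    higher_cult = ["CL5", "CL18", "CL25", "CL32", "CL35", "CL47", "CL57",
                   "CL255"]
    higher_wild = ["CL64", "CL88", "CL94", "CL96", "CL102", "CL138", "CL193",
                   "CL232", "CL29", "CL43", "CL87", "CL48", "CL115", "CL100"]
    fold = {f: 1.8 for f in higher_cult}
    fold.update({f: 0.55 for f in higher_wild})
    gypsy = higher_cult[:7] + higher_wild[:11]
    adj_wild = {f: (0.25 if f in gypsy else 0.10) for f in fold}
    adj_cult = {f: (0.12 if f in gypsy else 0.10) for f in fold}
    return CohortConfig(base_copy_number=60, fold_change=fold,
                        gene_adjacent_fraction=adj_wild,
                        gene_adjacent_fraction_cultivated=adj_cult,
                        coverage=20000, seed=seed)


@dataclass
class RunResult:
    abundance: ab.AbundanceMatrix
    classification: pd.DataFrame
    lineage_summary: pd.DataFrame
    pca_scores: pd.DataFrame | None
    pair_rates: proximity.PairRateMatrix | None
    pair_comparison: pd.DataFrame | None
    pathway_spectrum: pd.DataFrame | None
    pathway_comparison: pd.DataFrame | None
    windows: pd.DataFrame | None
    recovery: pd.DataFrame | None
    outdir: Path


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _analyse(matrix: ab.AbundanceMatrix,
             library: RepeatLibrary,
             gene_set: GeneSet | None,
             pair_inputs,  # callable genotype -> (reads1, reads2) or None
             n_read_pairs: dict[str, int] | None,
             config: RunConfig,
             outdir: Path,
             cohort: Cohort | None = None) -> RunResult:
    """Analysis half shared by synthetic and real modes."""
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(outdir / "abundance_matrix.tsv")

    classification = famstats.classify_families(
        matrix, alpha=config.alpha, n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "famstats"), metadata=library.metadata)
    _write_tsv(classification, outdir / "family_classification.tsv")
    lin = famstats.lineage_summary(classification)
    _write_tsv(lin, outdir / "lineage_summary.tsv")

    sig_fams = list(classification.loc[classification.significant, "family_id"])
    pca_scores = None
    pca_cols = sig_fams if len(sig_fams) >= 2 else matrix.family_ids
    sub = matrix.values[pca_cols]
    if sub.shape[1] >= 1 and sub.to_numpy().std() > 0:
        res = famstats.pca(sub)
        pca_scores = res.scores
        pca_out = res.scores.copy()
        pca_out.insert(0, "group", matrix.groups.values)
        pca_out.index.name = "genotype"
        pca_out.to_csv(outdir / "pca_scores.tsv", sep="\t",
                       float_format="%.6g")
        pd.DataFrame({"component": res.scores.columns,
                      "variance_explained_pct":
                          np.round(res.variance_explained, 6)}) \
            .to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)

    rates = comparison = spectrum = pw_comp = None
    if pair_inputs is not None and gene_set is not None and sig_fams:
        sig_contigs = {c: s for c, s in library.contigs.items()
                       if library.contig_to_family[c] in set(sig_fams)}
        combined = dict(sig_contigs)
        combined.update(gene_set.genes)
        index = ReferenceIndex(combined, k=config.mapping.kmer_seed_length)
        all_pairs = []
        for gid in matrix.genotypes:
            reads1, reads2 = pair_inputs(gid)
            params = dataclasses.replace(
                config.mapping, seed=stage_seed(config.seed, f"pairs:{gid}"))
            pt = map_pairs(reads1, reads2, index, params)
            all_pairs.append(proximity.extract_gene_re_pairs(
                pt, library.contig_to_family, list(gene_set.genes),
                genotype=gid, family_subset=sig_fams))
        pairs = pd.concat(all_pairs, ignore_index=True)
        _write_tsv(pairs, outdir / "gene_re_pairs.tsv")
        group_labels = matrix.groups.to_dict()
        rates = proximity.pair_rates(pairs, n_read_pairs, group_labels,
                                     sig_fams)
        rates.to_tsv(outdir / "pair_rate_matrix.tsv")
        comparison = proximity.compare_pair_rates(
            rates, alphas=config.pair_alphas,
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "pair-permanova"),
            metadata=library.metadata)
        _write_tsv(comparison, outdir / "pair_rate_comparison.tsv")
        gene_lists = proximity.pool_gene_lists(pairs, group_labels)
        for group, lst in gene_lists.items():
            with open(outdir / f"gene_list_{group}.txt", "w") as fh:
                for gene, mult in lst.items():
                    fh.write(f"{gene}\t{mult}\n")
        spectrum, pw_comp = proximity.pathway_spectrum(
            gene_lists, gene_set.annotation, pairs=pairs,
            group_labels=group_labels, alphas=config.pair_alphas,
            n_permutations=config.n_permutations,
            seed=stage_seed(config.seed, "pathway-permanova"))
        _write_tsv(spectrum, outdir / "pathway_spectrum.tsv")
        _write_tsv(pw_comp, outdir / "pathway_comparison.tsv")

    windows = None
    if cohort is not None and sig_fams:
        ref_seed = stage_seed(config.seed, "reference-genome")
        from .synthcohort import build_genotype
        genome, _, _ = build_genotype(cohort.config, library,
                                      cohort.gene_set, "wild",
                                      "reference", ref_seed)
        genome_str = seqio.decode(genome)
        queries: dict[str, dict[str, str]] = {}
        for sf in ("Gypsy", "Copia"):
            fams = set(classification.loc[
                classification.significant
                & (classification.superfamily == sf), "family_id"])
            contigs = {c: s for c, s in library.contigs.items()
                       if library.contig_to_family[c] in fams}
            if contigs:
                queries[sf] = contigs
        if queries:
            hits = landscape.scan_repeats({"chr1": genome_str}, queries)
            windows = landscape.window_counts(
                hits, {"chr1": len(genome_str)},
                window_size=config.window_size)
            _write_tsv(windows, outdir / "landscape_windows.tsv")
            for cls in windows["cls"].unique():
                if cls != "none":
                    landscape.write_bedgraph(
                        windows, outdir / f"landscape_{cls}.bedgraph", cls)

    recovery = None
    if cohort is not None:
        rec_rows = []
        true_cn = cohort.true_copy_numbers()
        est = matrix.values.reindex(index=true_cn.index,
                                    columns=true_cn.columns)
        rho_ab = spearmanr(true_cn.values.ravel(), est.values.ravel())[0]
        rec_rows.append(("abundance_vs_true_copies_spearman", float(rho_ab)))
        if rates is not None:
            adj = cohort.true_adjacent_counts()[sig_fams].sum(axis=0)
            pr = rates.values.sum(axis=0)
            if len(sig_fams) >= 3:
                rho_px = spearmanr(adj.values, pr.values)[0]
                rec_rows.append(("pair_rate_vs_true_adjacent_spearman",
                                 float(rho_px)))
        recovery = pd.DataFrame(rec_rows, columns=["quantity", "value"])
        _write_tsv(recovery, outdir / "recovery.tsv")

    _write_report(outdir, matrix, classification, lin, comparison,
                  spectrum, pw_comp, recovery, config)
    return RunResult(abundance=matrix, classification=classification,
                     lineage_summary=lin, pca_scores=pca_scores,
                     pair_rates=rates, pair_comparison=comparison,
                     pathway_spectrum=spectrum, pathway_comparison=pw_comp,
                     windows=windows, recovery=recovery, outdir=outdir)


def _write_report(outdir, matrix, classification, lin, comparison,
                  spectrum, pw_comp, recovery, config) -> None:
    n_sig = int(classification["significant"].sum())
    lines = ["# retroquant run report", ""]
    lines += [f"- genotypes: {len(matrix.genotypes)} "
              f"({(matrix.groups == 'cultivated').sum()} cultivated, "
              f"{(matrix.groups == 'wild').sum()} wild)",
              f"- families tested: {len(matrix.family_ids)}",
              f"- significant at p <= {config.alpha}: {n_sig} "
              f"of {len(matrix.family_ids)}",
              f"- master seed: {config.seed}", ""]
    lines += ["## Family classification", "",
              classification.to_markdown(index=False), ""]
    lines += ["## Lineage summary", "", lin.to_markdown(index=False), ""]
    if comparison is not None:
        lines += ["## Gene-RE pair rates (per million read pairs)", "",
                  comparison.to_markdown(index=False), ""]
    if spectrum is not None:
        lines += ["## Pathway spectrum (pooled per group)", "",
                  spectrum.to_markdown(index=False), ""]
    if pw_comp is not None and len(pw_comp):
        lines += ["## Pathway comparison", "",
                  pw_comp.to_markdown(index=False), ""]
    if recovery is not None:
        lines += ["## Truth recovery", "", recovery.to_markdown(index=False),
                  ""]
    (Path(outdir) / "report.md").write_text("\n".join(lines))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


def run_synthetic(config: RunConfig, outdir) -> RunResult:
    """Simulate a cohort and run the full analysis on it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=stage_seed(config.seed, "cohort"))
        cohort = simulate_cohort(cohort_cfg)
        cohort.library.write(outdir / "library.fasta",
                             outdir / "library_map.tsv")
        cohort.gene_set.write(outdir / "genes.fasta",
                              outdir / "gene_annotation.tsv")
        _write_tsv(cohort.truth, outdir / "truth.tsv")
        cohort_cfg.to_yaml(outdir / "cohort_config.yaml")
        if config.write_genomes:
            seqio.write_fasta(outdir / "genomes.fasta",
                              ((g, cohort.genome_str(g))
                               for g, _ in cohort.genotypes))

        stage = "readmap/abundance"
        lib_index = ReferenceIndex(cohort.library.contigs,
                                   k=config.mapping.kmer_seed_length)
        vectors: dict[str, pd.Series] = {}
        n_inputs: dict[str, int] = {}
        read_cache: dict[str, tuple[list[str], list[str]]] = {}
        for gid, _ in cohort.genotypes:
            r1, r2 = cohort.reads(gid, stage_seed(config.seed, f"reads:{gid}"))
            read_cache[gid] = (r1, r2)
            if config.write_reads:
                seqio.write_fastq(outdir / f"{gid}_1.fastq",
                                  ((f"{gid}:{i}/1", s)
                                   for i, s in enumerate(r1)))
                seqio.write_fastq(outdir / f"{gid}_2.fastq",
                                  ((f"{gid}:{i}/2", s)
                                   for i, s in enumerate(r2)))
            params = dataclasses.replace(
                config.mapping, seed=stage_seed(config.seed, f"map:{gid}"))
            table = map_readset(r1 + r2, lib_index, params,
                                truncate_to=cohort_cfg.read_length)
            vectors[gid] = ab.count_family_abundance(
                table, cohort.library.contig_to_family,
                family_order=cohort_cfg.family_ids)
            n_inputs[gid] = table.n_input_reads
        matrix = ab.build_abundance_matrix(vectors,
                                           dict(cohort.genotypes), n_inputs)

        stage = "analysis"
        n_read_pairs = {gid: cohort_cfg.coverage
                        for gid, _ in cohort.genotypes}
        return _analyse(matrix, cohort.library, cohort.gene_set,
                        lambda gid: read_cache[gid], n_read_pairs,
                        config, outdir, cohort=cohort)
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


@dataclass
class RealInputs:
    """User-supplied inputs for real-data mode."""

    samples: list[tuple[str, str, str, str]]  # (genotype, group, fq1, fq2)
    library_fasta: str
    library_map: str
    genes_fasta: str | None = None
    annotation_tsv: str | None = None


def run_real(config: RunConfig, inputs: RealInputs, outdir) -> RunResult:
    """Run the analysis half on user-supplied FASTQ and references."""
    outdir = Path(outdir)
    stage = "inputs"
    try:
        library = RepeatLibrary.from_files(inputs.library_fasta,
                                           inputs.library_map)
        gene_set = None
        if inputs.genes_fasta:
            if inputs.annotation_tsv:
                gene_set = GeneSet.from_files(inputs.genes_fasta,
                                              inputs.annotation_tsv)
            else:
                warnings.warn("no pathway annotation supplied; pathway "
                              "comparison will be skipped")
                gene_set = GeneSet(
                    genes=seqio.read_fasta(inputs.genes_fasta),
                    annotation=pd.DataFrame(columns=["gene_id", "pathway"]))

        stage = "readmap/abundance"
        lib_index = ReferenceIndex(library.contigs,
                                   k=config.mapping.kmer_seed_length)
        vectors: dict[str, pd.Series] = {}
        n_inputs: dict[str, int] = {}
        groups: dict[str, str] = {}
        n_read_pairs: dict[str, int] = {}
        fq_of: dict[str, tuple[str, str]] = {}
        for gid, group, fq1, fq2 in inputs.samples:
            if gid in groups:
                raise ValueError(f"duplicated genotype {gid}")
            groups[gid] = group
            fq_of[gid] = (fq1, fq2)
            reads = ([s for _, s in seqio.read_fastq(fq1)]
                     + [s for _, s in seqio.read_fastq(fq2)])
            params = dataclasses.replace(
                config.mapping, seed=stage_seed(config.seed, f"map:{gid}"))
            table = map_readset(reads, lib_index, params, truncate_to=90)
            vectors[gid] = ab.count_family_abundance(
                table, library.contig_to_family,
                family_order=library.family_ids)
            n_inputs[gid] = table.n_input_reads
            n_read_pairs[gid] = len(reads) // 2
        matrix = ab.build_abundance_matrix(vectors, groups, n_inputs)

        stage = "analysis"
        pair_inputs = None
        if gene_set is not None:
            pair_inputs = lambda gid: fq_of[gid]  # noqa: E731
        return _analyse(matrix, library, gene_set, pair_inputs,
                        n_read_pairs, config, outdir, cohort=None)
    except Exception as exc:  # noqa: BLE001
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
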