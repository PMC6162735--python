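"""Synthetic cohort generator.

Builds the ingredients of a two-group (wild vs. cultivated) repeat-abundance
study entirely in silico: a library of LTR-retrotransposon-like families
organised as family -> lineage -> superfamily, a gene set with pathway
annotation, per-genotype genomes in which repeat copies are planted with
group-specific copy numbers and a controlled fraction of copies adjacent to
genes, and paired-end reads from those genomes.  Every generated insertion is
recorded in a ground-truth table so downstream estimates (abundance,
gene-proximity rates) can be validated by parameter recovery.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import seqio
from .seqio import decode, encode, revcomp_codes

# Lineage -> superfamily is a function: each lineage belongs to exactly one
# superfamily (Gypsy or Copia).
LINEAGE_TO_SUPERFAMILY: dict[str, str] = {
    "Chromovirus": "Gypsy",
    "Athila": "Gypsy",
    "Ogre/Tat": "Gypsy",
    "AleII": "Copia",
    "AleI": "Copia",
    "Angela": "Copia",
    "Bianca": "Copia",
    "Ivana/Oryco": "Copia",
    "Maximus/SIRE": "Copia",
    "TAR/Tork": "Copia",
}

# The 22 differentially abundant families of the sunflower study, with their
# lineage assignment (15 Gypsy-Chromovirus, 3 Gypsy-Athila, 4 Copia).
_REFERENCE_FAMILIES: list[tuple[str, str]] = [
    ("CL5", "Chromovirus"), ("CL18", "Chromovirus"), ("CL25", "Chromovirus"),
    ("CL32", "Chromovirus"), ("CL35", "Chromovirus"), ("CL47", "Chromovirus"),
    ("CL57", "Chromovirus"), ("CL64", "Chromovirus"), ("CL88", "Chromovirus"),
    ("CL94", "Chromovirus"), ("CL96", "Chromovirus"), ("CL102", "Chromovirus"),
    ("CL138", "Chromovirus"), ("CL193", "Chromovirus"), ("CL232", "Chromovirus"),
    ("CL29", "Athila"), ("CL43", "Athila"), ("CL87", "Athila"),
    ("CL48", "AleII"), ("CL115", "Maximus/SIRE"),
    ("CL100", "Angela"), ("CL255", "TAR/Tork"),
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class CohortSizingError(ValueError):
    """The requested insertions do not fit the genome layout."""


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One repeat family: id, lineage/superfamily, consensus size, contigs."""

    family_id: str
    lineage: str
    superfamily: str | None = None
    consensus_length: int = 1000
    n_contigs: int = 3

    def __post_init__(self):
        if self.consensus_length < 300:
            raise ConfigurationError(
                f"{self.family_id}: consensus_length must be >= 300")
        if self.n_contigs < 1:
            raise ConfigurationError(f"{self.family_id}: n_contigs must be >= 1")
        expected = LINEAGE_TO_SUPERFAMILY.get(self.lineage)
        if self.superfamily is None:
            if expected is None:
                raise ConfigurationError(f"unknown lineage {self.lineage!r}")
            object.__setattr__(self, "superfamily", expected)
        elif expected is not None and self.superfamily != expected:
            raise ConfigurationError(
                f"lineage {self.lineage} belongs to {expected}, "
                f"not {self.superfamily}")


def reference_family_specs(consensus_length: int = 1000,
                           n_contigs: int = 3) -> list[RepeatFamilySpec]:
    """The 22-family hierarchy (18 Gypsy / 4 Copia) used as default cohort."""
    return [RepeatFamilySpec(fid, lin, consensus_length=consensus_length,
                             n_contigs=n_contigs)
            for fid, lin in _REFERENCE_FAMILIES]


@dataclass
class RepeatLibrary:
    """Repeat-family reference library: contigs plus the contig->family map."""

    contigs: dict[str, str]
    contig_to_family: dict[str, str]
    metadata: pd.DataFrame  # family_id, lineage, superfamily (one row/family)
    consensus: dict[str, str] = field(default_factory=dict)

    @property
    def family_ids(self) -> list[str]:
        return list(self.metadata["family_id"])

    def lineage_of(self, family_id: str) -> str:
        row = self.metadata.loc[self.metadata.family_id == family_id]
        return str(row["lineage"].iloc[0])

    def write(self, fasta_path, map_path) -> None:
        seqio.write_fasta(fasta_path, self.contigs.items())
        table = pd.DataFrame({
            "contig_id": list(self.contigs),
            "family_id": [self.contig_to_family[c] for c in self.contigs],
        }).merge(self.metadata, on="family_id", how="left")
        table.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta_path, map_path) -> "RepeatLibrary":
        contigs = seqio.read_fasta(fasta_path)
        table = pd.read_csv(map_path, sep="\t")
        missing = set(contigs) - set(table["contig_id"])
        if missing:
            raise ConfigurationError(
                f"contigs absent from map table: {sorted(missing)[:5]}")
        c2f = dict(zip(table["contig_id"], table["family_id"]))
        meta = (table[["family_id", "lineage", "superfamily"]]
                .drop_duplicates("family_id").reset_index(drop=True))
        return cls(contigs=contigs, contig_to_family=c2f, metadata=meta)


@dataclass
class GeneSet:
    """Gene sequences standing in for a transcriptome, with pathway labels."""

    genes: dict[str, str]
    annotation: pd.DataFrame  # columns: gene_id, pathway (0..k rows per gene)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def pathways_of(self, gene_id: str) -> list[str]:
        sel = self.annotation.loc[self.annotation.gene_id == gene_id, "pathway"]
        return [p for p in sel if isinstance(p, str)]

    def write(self, fasta_path, annot_path) -> None:
        seqio.write_fasta(fasta_path, self.genes.items())
        self.annotation.to_csv(annot_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta_path, annot_path) -> "GeneSet":
        return cls(genes=seqio.read_fasta(fasta_path),
                   annotation=pd.read_csv(annot_path, sep="\t"))


def _random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability `rate` (never to itself)."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    out[mask] = (out[mask] + shift) % 4
    return out


def generate_re_library(specs: Sequence[RepeatFamilySpec],
                        seed: int,
                        contig_divergence: float = 0.03) -> RepeatLibrary:
    """Generate a repeat library: per family, one random consensus and
    ``n_contigs`` variants of it at <= 5% substitution divergence.

    Distinct families have unrelated random consensuses, so inter-family
    identity is at background level.
    """
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate family_id in specs")
    if not 0 <= contig_divergence <= 0.05:
        raise ConfigurationError("contig_divergence must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    c2f: dict[str, str] = {}
    consensus: dict[str, str] = {}
    for spec in specs:
        cons = _random_codes(rng, spec.consensus_length)
        consensus[spec.family_id] = decode(cons)
        for j in range(spec.n_contigs):
            cid = f"{spec.family_id}_c{j + 1}"
            rate = rng.uniform(0.0, contig_divergence)
            contigs[cid] = decode(_mutate(cons, rate, rng))
            c2f[cid] = spec.family_id
    meta = pd.DataFrame({
        "family_id": ids,
        "lineage": [s.lineage for s in specs],
        "superfamily": [s.superfamily for s in specs],
    })
    return RepeatLibrary(contigs=contigs, contig_to_family=c2f,
                         metadata=meta, consensus=consensus)


def generate_gene_set(n_genes: int,
                      pathway_labels: Sequence[str],
                      seed: int,
                      length_range: tuple[int, int] = (1000, 3000),
                      max_pathways_per_gene: int = 2,
                      unannotated_fraction: float = 0.1) -> GeneSet:
    """Random gene sequences, each carrying 0..k pathway labels."""
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: dict[str, str] = {}
    rows: list[tuple[str, str]] = []
    labels = list(pathway_labels)
    for i in range(n_genes):
        gid = f"gene{i + 1:05d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        genes[gid] = decode(_random_codes(rng, length))
        if labels and rng.random() >= unannotated_fraction:
            k = int(rng.integers(1, max_pathways_per_gene + 1))
            k = min(k, len(labels))
            for p in rng.choice(labels, size=k, replace=False):
                rows.append((gid, str(p)))
    annot = pd.DataFrame(rows, columns=["gene_id", "pathway"])
    return GeneSet(genes=genes, annotation=annot)


def _per_family(value, family_ids: list[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {f: float(value.get(f, value.get("default", 1.0)))
               for f in family_ids}
        return out
    return {f: float(value) for f in family_ids}


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the real study design: 8 cultivated and 7 wild genotypes,
    90-nt reads for abundance, and the 22-family Gypsy/Copia hierarchy.
    """

    n_wild: int = 7
    n_cultivated: int = 8
    families: list[RepeatFamilySpec] = field(default_factory=reference_family_specs)
    base_copy_number: float | Mapping[str, float] = 100
    fold_change: float | Mapping[str, float] = 1.0  # cultivated / wild
    gene_adjacent_fraction: float | Mapping[str, float] = 0.1
    gene_adjacent_fraction_cultivated: float | Mapping[str, float] | None = None
    n_genes: int = 200
    pathway_labels: list[str] = field(default_factory=lambda: [
        "Oxidative phosphorylation", "Sulfur metabolism",
        "Cysteine and methionine metabolism", "Glycolysis / Gluconeogenesis",
        "Starch and sucrose metabolism", "Purine metabolism",
        "Plant hormone signal transduction", "Ribosome",
    ])
    read_length: int = 90
    insert_mu: float = 300.0
    insert_sigma: float = 30.0
    error_rate: float = 0.005
    coverage: int = 20000  # read pairs per genotype
    copy_divergence: float = 0.02
    background_length: int = 500_000
    adjacency_gap: tuple[int, int] = (10, 150)
    adjacent_distance: float | None = None  # default 2 * insert_mu
    adjacent_pathway_weights: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_wild < 2 or self.n_cultivated < 2:
            raise ConfigurationError("need >= 2 genotypes per group")
        if not 0 <= self.error_rate < 0.1:
            raise ConfigurationError("error_rate must be in [0, 0.1)")
        if self.insert_mu <= self.read_length:
            raise ConfigurationError("insert_mu must exceed read_length")
        if self.adjacent_distance is None:
            self.adjacent_distance = 2.0 * self.insert_mu

    @property
    def family_ids(self) -> list[str]:
        return [s.family_id for s in self.families]

    def resolved(self, name: str, group: str = "wild") -> dict[str, float]:
        """Per-family value of a scalar-or-mapping config field."""
        if name == "gene_adjacent_fraction" and group == "cultivated" \
                and self.gene_adjacent_fraction_cultivated is not None:
            value = self.gene_adjacent_fraction_cultivated
        else:
            value = getattr(self, name)
        return _per_family(value, self.family_ids, name)

    def genotype_labels(self) -> list[tuple[str, str]]:
        wild = [(f"wild{i + 1:02d}", "wild") for i in range(self.n_wild)]
        cult = [(f"cult{i + 1:02d}", "cultivated")
                for i in range(self.n_cultivated)]
        return cult + wild

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["families"] = [dataclasses.asdict(s) for s in self.families]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        fams = d.pop("families", None)
        cfg_kwargs = {k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}}
        if fams is not None:
            cfg_kwargs["families"] = [RepeatFamilySpec(**f) for f in fams]
        if "adjacency_gap" in cfg_kwargs:
            cfg_kwargs["adjacency_gap"] = tuple(cfg_kwargs["adjacency_gap"])
        return cls(**cfg_kwargs)


TRUTH_COLUMNS = ["genotype", "family_id", "chrom", "start", "end", "strand",
                 "gene_adjacent", "gene_id"]


def build_genotype(config: CohortConfig,
                   library: RepeatLibrary,
                   gene_set: GeneSet,
                   group: str,
                   genotype_id: str,
                   seed: int) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Assemble one genotype genome.

    The genome is a single chromosome of random background in which one copy
    of every gene and a Poisson-distributed number of copies of every repeat
    family are planted.  A per-family, per-group fraction of repeat copies is
    placed immediately next to a gene (gap drawn from ``adjacency_gap``), the
    rest at least one spacer away from any gene.  Copies are substitution
    mutated at ``copy_divergence`` and inserted on a random strand.

    Returns (genome codes, insertion truth table, gene position table).
    """
    if group not in ("wild", "cultivated"):
        raise ConfigurationError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    base = config.resolved("base_copy_number")
    fold = config.resolved("fold_change")
    adj_frac = config.resolved("gene_adjacent_fraction", group)
    cons = {f: encode(library.consensus[f]) for f in config.family_ids}

    # draw copy numbers and how many of each family are gene-adjacent
    n_copies: dict[str, int] = {}
    n_adj: dict[str, int] = {}
    for f in config.family_ids:
        lam = base[f] * (fold[f] if group == "cultivated" else 1.0)
        n = int(rng.poisson(lam))
        n_copies[f] = n
        n_adj[f] = int(rng.binomial(n, min(1.0, max(0.0, adj_frac[f]))))

    gene_ids = gene_set.gene_ids
    total_adj = sum(n_adj.values())
    if total_adj > 2 * len(gene_ids):
        raise CohortSizingError(
            f"{total_adj} gene-adjacent insertions requested but only "
            f"{2 * len(gene_ids)} gene flanks available; increase n_genes")

    # choose gene flanks for adjacent copies, optionally biased by pathway
    slots = [(g, side) for g in gene_ids for side in ("L", "R")]
    weights = np.ones(len(slots))
    if config.adjacent_pathway_weights:
        wmap = config.adjacent_pathway_weights.get(group, {})
        if wmap:
            gene_w = {}
            for g in gene_ids:
                ws = [wmap.get(p, 1.0) for p in gene_set.pathways_of(g)]
                gene_w[g] = max(ws) if ws else 1.0
            weights = np.array([gene_w[g] for g, _ in slots])
    # weighted sampling without replacement (Efraimidis-Spirakis keys)
    keys = rng.random(len(slots)) ** (1.0 / weights)
    chosen = [slots[i] for i in np.argsort(-keys)[:total_adj]]
    adj_fams = [f for f in config.family_ids for _ in range(n_adj[f])]
    rng.shuffle(adj_fams)
    flank_of: dict[tuple[str, str], str] = dict(zip(chosen, adj_fams))

    # blocks: every gene (with its attached repeats) and each standalone copy
    def repeat_copy(f: str) -> tuple[np.ndarray, str]:
        seq = _mutate(cons[f], config.copy_divergence, rng)
        if rng.random() < 0.5:
            return revcomp_codes(seq), "-"
        return seq, "+"

    blocks: list[list[tuple[str, ...]]] = []  # list of block part descriptors
    for g in gene_ids:
        block: list[tuple[str, ...]] = []
        if (g, "L") in flank_of:
            block.append(("repeat", flank_of[(g, "L")], g))
            block.append(("gap", ""))
        block.append(("gene", g))
        if (g, "R") in flank_of:
            block.append(("gap", ""))
            block.append(("repeat", flank_of[(g, "R")], g))
        blocks.append(block)
    for f in config.family_ids:
        for _ in range(n_copies[f] - n_adj[f]):
            blocks.append([("repeat", f, "")])
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    # spacers sized so total background ~ background_length, never shorter
    # than the maximal fragment span (no read pair bridges two blocks)
    min_spacer = int(config.insert_mu + 6 * config.insert_sigma + 100)
    n_spacers = len(blocks) + 1
    mean_spacer = max(min_spacer, config.background_length // max(1, n_spacers))
    gap_lo, gap_hi = config.adjacency_gap

    parts: list[np.ndarray] = []
    pos = 0
    truth_rows: list[tuple] = []
    gene_rows: list[tuple] = []

    def add(arr: np.ndarray) -> tuple[int, int]:
        nonlocal pos
        parts.append(arr)
        start = pos
        pos += len(arr)
        return start, pos

    def add_spacer() -> None:
        length = int(rng.integers(int(0.8 * mean_spacer),
                                  int(1.2 * mean_spacer) + 1))
        add(_random_codes(rng, length))

    add_spacer()
    for block in blocks:
        for part in block:
            if part[0] == "gap":
                add(_random_codes(rng, int(rng.integers(gap_lo, gap_hi + 1))))
            elif part[0] == "gene":
                s, e = add(encode(gene_set.genes[part[1]]))
                gene_rows.append((genotype_id, part[1], "chr1", s, e))
            else:  # repeat
                _, fam, near_gene = part
                seq, strand = repeat_copy(fam)
                s, e = add(seq)
                truth_rows.append((genotype_id, fam, "chr1", s, e, strand,
                                   bool(near_gene), near_gene or None))
        add_spacer()

    genome = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    gene_pos = pd.DataFrame(
        gene_rows, columns=["genotype", "gene_id", "chrom", "start", "end"])
    return genome, truth, gene_pos


def simulate_reads(genome: np.ndarray | str,
                   n_pairs: int,
                   read_length: int,
                   insert_mu: float,
                   insert_sigma: float,
                   error_rate: float,
                   seed: int) -> tuple[list[str], list[str]]:
    """Simulate paired-end reads from one genome.

    Fragment starts are uniform; insert (outer) lengths are Gaussian,
    truncated below at ``read_length``.  Mate 1 is the 5' end of the forward
    strand; mate 2 is the reverse complement of the 3' end.  Substitution
    errors are applied per base at ``error_rate``.
    """
    if isinstance(genome, str):
        genome = encode(genome)
    if n_pairs <= 0:
        return [], []
    glen = len(genome)
    if glen <= insert_mu + 6 * insert_sigma:
        raise CohortSizingError("genome too short for the insert distribution")
    rng = np.random.default_rng(seed)
    ins = np.rint(rng.normal(insert_mu, insert_sigma, n_pairs)).astype(np.int64)
    ins = np.clip(ins, read_length, glen)
    starts = (rng.random(n_pairs) * (glen - ins + 1)).astype(np.int64)
    offs = np.arange(read_length, dtype=np.int64)
    m1 = genome[starts[:, None] + offs]
    m2 = genome[(starts + ins - read_length)[:, None] + offs]
    m2 = seqio._COMPLEMENT[m2[:, ::-1]]
    for m in (m1, m2):
        if error_rate > 0:
            mask = rng.random(m.shape) < error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            m[mask] = (m[mask] + shift) % 4
    a1 = seqio.BASES[m1].tobytes()
    a2 = seqio.BASES[m2].tobytes()
    L = read_length
    reads1 = [a1[i * L:(i + 1) * L].decode() for i in range(n_pairs)]
    reads2 = [a2[i * L:(i + 1) * L].decode() for i in range(n_pairs)]
    return reads1, reads2


@dataclass
class Cohort:
    """A fully generated synthetic cohort with ground truth."""

    config: CohortConfig
    library: RepeatLibrary
    gene_set: GeneSet
    genotypes: list[tuple[str, str]]  # (genotype_id, group)
    genomes: dict[str, np.ndarray]
    truth: pd.DataFrame
    gene_positions: pd.DataFrame

    def genome_str(self, genotype_id: str) -> str:
        return decode(self.genomes[genotype_id])

    def reads(self, genotype_id: str, seed: int,
              n_pairs: int | None = None,
              read_length: int | None = None) -> tuple[list[str], list[str]]:
        cfg = self.config
        return simulate_reads(
            self.genomes[genotype_id],
            cfg.coverage if n_pairs is None else n_pairs,
            cfg.read_length if read_length is None else read_length,
            cfg.insert_mu, cfg.insert_sigma, cfg.error_rate, seed)

    def true_copy_numbers(self) -> pd.DataFrame:
        """Genotypes x families table of planted copy counts."""
        counts = (self.truth.groupby(["genotype", "family_id"])
                  .size().unstack(fill_value=0))
        fams = self.config.family_ids
        counts = counts.reindex(index=[g for g, _ in self.genotypes],
                                columns=fams, fill_value=0)
        return counts

    def true_adjacent_counts(self) -> pd.DataFrame:
        adj = self.truth[self.truth.gene_adjacent]
        counts = (adj.groupby(["genotype", "family_id"])
                  .size().unstack(fill_value=0))
        counts = counts.reindex(index=[g for g, _ in self.genotypes],
                                columns=self.config.family_ids, fill_value=0)
        return counts


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate library, genes and all genotype genomes for one cohort."""
    rng = np.random.default_rng(config.seed)
    lib_seed, gene_seed = (int(s) for s in
                           rng.integers(0, 2**31 - 1, size=2))
    library = generate_re_library(config.families, lib_seed)
    gene_set = generate_gene_set(config.n_genes, config.pathway_labels,
                                 gene_seed)
    genotypes = config.genotype_labels()
    genomes: dict[str, np.ndarray] = {}
    truths: list[pd.DataFrame] = []
    gene_pos: list[pd.DataFrame] = []
    for gid, group in genotypes:
        gseed = int(rng.integers(0, 2**31 - 1))
        genome, truth, gpos = build_genotype(config, library, gene_set,
                                             group, gid, gseed)
        genomes[gid] = genome
        truths.append(truth)
        gene_pos.append(gpos)
    return Cohort(config=config, library=library, gene_set=gene_set,
                  genotypes=genotypes, genomes=genomes,
                  truth=pd.concat(truths, ignore_index=True),
                  gene_positions=pd.concat(gene_pos, ignore_index=True))


def sample_abundance_model(n_families: int,
                           n_wild: int,
                           n_cultivated: int,
                           base_copy_number: float,
                           fold_change: float | np.ndarray,
                           reads_per_genotype: int,
                           consensus_length: int,
                           background_length: int,
                           seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Sample per-family abundances from the cohort's statistical skeleton
    without sequence-level simulation.

    Per genotype, family copy numbers are Poisson around the group mean; the
    number of mapped reads per family is binomial with success probability
    equal to the family's share of the genome; abundances are reads per
    million.  This is the sampling layer the full generator realises with
    actual sequences, and is what large calibration runs (e.g. null type-I
    error over thousands of families) use.

    Returns (genotypes x families abundance DataFrame, group Series).
    """
    rng = np.random.default_rng(seed)
    fold = np.broadcast_to(np.asarray(fold_change, dtype=float),
                           (n_families,)).copy()
    genotypes = ([f"cult{i+1:02d}" for i in range(n_cultivated)]
                 + [f"wild{i+1:02d}" for i in range(n_wild)])
    groups = pd.Series(["cultivated"] * n_cultivated + ["wild"] * n_wild,
                       index=genotypes, name="group")
    lam = np.where(groups.values[:, None] == "cultivated",
                   base_copy_number * fold[None, :],
                   base_copy_number)
    copies = rng.poisson(lam)
    repeat_bases = copies * consensus_length
    genome = repeat_bases.sum(axis=1, keepdims=True) + background_length
    p = repeat_bases / genome
    counts = rng.binomial(reads_per_genotype, p)
    rpm = counts * 1e6 / reads_per_genotype
    fam_ids = [f"F{i+1:04d}" for i in range(n_families)]
    return pd.DataFrame(rpm, index=genotypes, columns=fam_ids), groups
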