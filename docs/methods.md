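# Methods

## Abundance model

A repeat family's genomic abundance is estimated as mapped reads per
million reads used for mapping (rpm): reads of one genotype are mapped as
single ends against all contigs of a family library, and the family value
is the total count over its contigs, scaled by 10⁶ / (number of post-trim
input reads). The denominator is the *input* read count, not the mapped
count, so rpm is a read-share measure: in expectation

    rpm_f ≈ 10⁶ · (copies_f · L_f) / G,

with `L_f` the family's element length and `G` the genome size. Two
consequences shape both use and validation:

- rpm is **compositional**: it tracks copy number only while the family's
  bases are a small fraction of `G`. In multi-gigabase plant genomes this
  holds by orders of magnitude; in synthetic genomes it holds only if the
  random background dominates the genome, which is how the validation
  cohorts are sized (see below).
- reads are truncated to a fixed 90 nt before single-end mapping (shorter
  reads are dropped), so rpm is comparable across genotypes with different
  read-length distributions. Paired (proximity) mapping uses full-length
  reads.

## Mapping contract

Reads are mapped with unit edit costs (mismatch = insertion = deletion = 1)
and accepted at identity ≥ 0.9 over ≥ 0.9 of the read. The mapper aligns
the **full read** semi-globally (free end-gaps on the reference, no soft
clipping) and defines

    identity = 1 − editDistance / readLength.

Every edit — including what a clipping aligner would trim — counts against
the read, so the length-fraction condition is absorbed into the identity
rule and the reported aligned fraction is 1 by construction. This
interpretation is path-independent (the optimal edit distance is unique
even when alignments are not), which makes accept/reject decisions well
defined and lets a brute-force dynamic-programming scan
(`retroquant.refalign`) serve as an exact oracle. Thresholds are compared
with ≥, so a 90-nt read with exactly 9 isolated substitutions (identity
81/90 = 0.9) is accepted and one with 10 is not.

Candidate references are found by exact k-mer seeding on both strands and
each candidate is verified with a banded unit-cost alignment (edlib, edit
budget e_max = ⌊L·(1 − 0.9)⌋). Seeding recovers *every* acceptable hit when
k ≤ ⌊L/(e_max + 1)⌋ (pigeonhole: some k-window of the read must be
edit-free) — k = 9 for 90-nt reads at 0.9 identity. The default k = 13
trades that guarantee for speed; it can miss a borderline hit only when
errors are spaced almost periodically (probability ≈ 10⁻³ at the worst
admissible error count, lower elsewhere). Validation of mapper exactness
therefore runs at k = 9, where agreement with the brute-force oracle is
guaranteed by construction, on instances small enough for the denser seed.

Reads matching several references equally well (equal edit distance) are
assigned uniformly at random from a dedicated seeded stream, so duplicated
or shared contigs within a family do not bias family-level counts.

## PERMANOVA

Group differences are tested per family by one-way PERMANOVA on the
Euclidean distance matrix of per-genotype values:

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij
    pseudo-F  = (SS_among/(a−1)) / (SS_within/(N−a)).

For univariate data this equals the classical one-way ANOVA F (verified to
1e-9 in tests). The permutation p-value uses the +1 correction,
p = (#{F_perm ≥ F_obs}+1)/(B+1), and never reports 0; when the number of
distinct label arrangements does not exceed the requested B the test
enumerates them all and reports the exact proportion (identity included).
Degenerate inputs are flagged: all-zero distances give p = 1; zero
within-group spread with non-zero among-group spread reports F = +∞ with p
still taken from permutations.

Two discreteness effects matter in small designs: with two groups each
arrangement appears twice (label swap), so the exact p-value floor for a
balanced 5+5 design is 2/252 ≈ 0.008 and a 3+3 design can never reach
p ≤ 0.01; and a sampled p can only resolve multiples of 1/(B+1). The
default B = 999 follows the convention of the community's permutation
software. Per-family tests are marginal — no multiple-testing correction
enters the headline classification (p ≤ 0.01 per family) — but a
Benjamini–Hochberg column is emitted alongside. Direction is the sign of
the group-mean difference. The star coding of the proximity comparison
(* p < 0.05, *** p < 0.001) needs B ≥ 1999 (or exhaustive mode) before
the three-star level is reachable.

PCA is a centred SVD; variance explained is reported in percent over all
components and each component's largest-magnitude loading is made positive.
The PCA is computed on the genotypes × significant-families matrix (one
plot), our reading of the per-family ordination views such studies print.

## Landscape scanning

Family sequences are located along a genome by the same seed-and-verify
machinery with a divergence ceiling instead of the read contract: a query
masks an interval when it aligns with ≤ 20% divergence over ≥ 100 bp.
Overlapping hits of one class (pooled Gypsy set, pooled Copia set, a
centromeric probe) are unioned, so window counts are coverage, never a
double-counting sum. Windows tile each chromosome; the real-genome default
is 3 Mbp, synthetic runs use ~50 kb so that a multi-window landscape fits
in a megabase-scale genome. Both per-family and per-class granularities are
available (hits carry `query_id` and `cls`).

## Gene-RE pairs

A gene-RE pair is a read pair with one mate mapped to a repeat contig and
the other to a transcriptome gene, after mapping both mates against the
combined reference; pairs with an unmapped mate, repeat-repeat and
gene-gene pairs are discarded. Rates are pairs per million read **pairs**
(if compared against per-million-*reads* figures, multiply by 2).
Per-genotype, per-family rates are compared between groups by the same
univariate PERMANOVA; pathway spectra are computed on the pooled per-group
gene lists (pooling suppresses per-genotype sampling noise at low
coverage), with term-level counting — a gene with two pathway annotations
contributes one count to each; unannotated genes are tallied separately and
excluded from percentages. The per-pathway significance test uses
per-genotype pathway counts as the unit of replication, the only reading
under which a permutation test is computable alongside pooled reporting.
The pipeline restricts pairs to the significant-family subset, mirroring
the intended use (families that already show differential abundance). No
PCR-duplicate removal is performed; the simulator generates none, and on
real data this is a documented caveat.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
sequence biology:

- **library**: per family one i.i.d.-uniform random consensus
  (default 1 kb, ≥ 300 nt) and n_contigs variants at ≤ 5% substitution
  divergence; distinct families are unrelated sequences, so inter-family
  identity sits at background (~25%) and 90-nt windows never cross the 0.7
  similarity mark.
- **genomes**: one chromosome per genotype — uniform random background,
  one planted copy of every gene (1–3 kb random sequences with 0–2 pathway
  labels), and per-family Poisson(base_copy_number · fold_change^[group])
  repeat copies, each substitution-mutated at 2% and inserted on a random
  strand. A per-family, per-group fraction of copies is placed next to a
  gene (gap uniform in 10–150 nt, well inside bridging-pair range); the
  rest sit at least one spacer from anything. Spacers are never shorter
  than insert_mu + 6·insert_sigma + 100, so no read pair bridges two
  unrelated blocks and zero gene-adjacency implies zero gene-RE pairs from
  true fragments. Insertions never overlap genes; every insertion is
  recorded in the truth table (0-based half-open coordinates).
  The ground-truth "adjacent" flag corresponds to a distance ≤ 2·insert_mu,
  the maximal span a bridging pair can detect.
- **reads**: uniform fragment starts, Gaussian insert length (default
  300 ± 30, truncated below at the read length), mate 1 from the 5′ forward
  end, mate 2 reverse-complemented from the 3′ end, substitution-only
  errors (default 0.5%, typical of modern short-read data), constant Q40
  qualities. Default read length 90 nt, group sizes 8 cultivated + 7 wild,
  and the default 22-family hierarchy (15 Gypsy-Chromovirus, 3
  Gypsy-Athila, one each of Copia AleII, Maximus/SIRE, Angela, TAR/Tork)
  mirror the study design this package is built around.
- Every generator is a pure function of (config, seed); the pipeline fans a
  master seed out to named per-stage streams via SHA-256, so reruns are
  byte-identical.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: LTR structural features (LTR/PBS/PPT),
GC- or context-dependent mappability bias, indel sequencing errors, quality
variation, PCR duplicates, library-size imbalance between genotypes, and
real within-group abundance dispersion (the Poisson choice creates
within-group variance of plausible magnitude; real dispersion is unknown
and configurable).

`sample_abundance_model` exposes the generator's sampling skeleton without
sequences (Poisson copies → binomial read counts → rpm); large calibration
runs (e.g. the 1,000-family null for type-I error) use it directly.

## Validation conditions and problem sizes

Simulation-based checks run at sizes chosen to keep the full suite within
desk-scale minutes while preserving each check's statistical meaning:
the null calibration uses 1,000 families at 8 + 7 genotypes with 999
permutations; the power check uses 20 families (5 planted at fold 2.0),
base copy number 200 and 2·10⁵ read pairs per genotype; the proximity
recovery uses 20 families with adjacency fractions spread over 0.02–0.40 at
10⁵ pairs per genotype. Because rpm is compositional (above), cohorts that
vary copy numbers keep the background large enough that planted changes
perturb genome size by under ~3% — the synthetic counterpart of a real
genome where a family's CNV is a vanishing fraction of total DNA. Without
this, desk-scale genomes show spurious opposite-direction shifts in every
null family; that is a property of the rpm measure, not of the test.

## Known limitations

- The mapper is exhaustive only over seed-sharing references; at the
  default k = 13 a borderline hit with near-periodic errors can be missed
  (quantified above). Use k ≤ ⌊L/(e_max+1)⌋ where exactness matters.
- rpm compares relative, not absolute, copy numbers; no genome-size or
  hybridisation calibration is attempted.
- The landscape scanner verifies full-query alignments at seed clusters; it
  reports decayed copies only down to the divergence ceiling and ≥ 100 bp,
  and is not a substitute for a full repeat annotation pipeline.
- Proximity is mapping-based: it counts bridging pairs, it does not resolve
  genomic distance or orientation of insertions.
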