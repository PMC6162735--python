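"""Short-read mapping under an identity / length-fraction contract.

One internal mapper serves both the single-end (abundance) and the paired
(gene-proximity) modes of the pipeline.  A read is mapped iff it aligns to a
reference with unit edit costs (mismatch = insertion = deletion = 1) at
identity >= ``min_identity`` over >= ``min_length_fraction`` of its length.
The whole read is always aligned semi-globally (free ends on the reference,
no soft clipping), so every edit counts against the read and identity is
defined path-independently as ``1 - edit_distance / read_length``; the
aligned fraction is 1 by construction.

Candidate references are found by exact k-mer seeding on both strands and
each candidate is verified with a banded unit-cost alignment (edlib).  The
seeding is exhaustive: every reference sharing at least one seed with the
read is verified.  Seeding is guaranteed to recover every hit within the
edit budget when ``kmer_seed_length <= floor(L / (e_max + 1))`` (pigeonhole,
e_max = floor(L * (1 - min_identity))); the default k = 13 trades that
guarantee for speed and misses hits only when errors are spaced almost
periodically.

Reads matching several references equally well are assigned uniformly at
random among the tied best hits, from the module's seeded RNG stream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from . import seqio
from .seqio import encode

_SENTINEL = np.uint64(2**63)  # k-mer containing a non-ACGT base


class PairingError(ValueError):
    """Mate files out of sync."""


@dataclass
class MappingParams:
    """Mapping thresholds and seeding parameters.

    Unit edit costs are part of the contract; identity and length fraction
    default to 0.9.
    """

    min_identity: float = 0.9
    min_length_fraction: float = 0.9
    mismatch_cost: int = 1
    deletion_cost: int = 1
    insertion_cost: int = 1
    kmer_seed_length: int = 13
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_length_fraction <= 1:
            raise ValueError("min_length_fraction must be in (0, 1]")
        if (self.mismatch_cost, self.deletion_cost, self.insertion_cost) != (1, 1, 1):
            raise ValueError("only unit edit costs are supported")

    def max_edits(self, read_length: int) -> int:
        return int(read_length * (1 - self.min_identity) + 1e-9)


@dataclass
class Hit:
    target_id: str
    strand: str  # '+' or '-'
    distance: int
    identity: float
    aligned_fraction: float
    score: int  # matches - edits


@dataclass
class ReadAssignment:
    read_id: str | None
    target_id: str | None  # None = unmapped
    strand: str | None
    alignment_identity: float
    aligned_fraction: float

    @property
    def mapped(self) -> bool:
        return self.target_id is not None


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """2-bit k-mer codes for one encoded sequence (row) or a batch (matrix).

    Windows containing a non-ACGT base get the sentinel code.
    """
    n = arr.shape[-1] - k + 1
    if n <= 0:
        return np.empty(arr.shape[:-1] + (0,), dtype=np.uint64)
    # accumulate in the narrowest dtype that holds 4^k, convert once at the end
    work = np.uint32 if 2 * k <= 31 else np.uint64
    a = arr.astype(work)
    codes = a[..., :n].copy()
    four = work(4)
    for j in range(1, k):
        codes *= four
        codes += a[..., j:j + n]
    codes = codes.astype(np.uint64)
    if (arr >= 4).any():
        bad = (arr >= 4).astype(np.int32)
        w = np.cumsum(bad, axis=-1)
        lead = np.zeros(arr.shape[:-1] + (1,), dtype=np.int32)
        w = np.concatenate([lead, w], axis=-1)
        window_bad = (w[..., k:] - w[..., :-k]) > 0
        codes[window_bad] = _SENTINEL
    return codes


class ReferenceIndex:
    """Exact k-mer index over a reference collection (forward strands)."""

    def __init__(self, references: Mapping[str, str], k: int = 13):
        self.k = int(k)
        self.names: list[str] = list(references)
        self.seqs: list[str] = [references[n].upper() for n in self.names]
        codes_list = []
        ref_list = []
        for i, s in enumerate(self.seqs):
            c = kmer_codes(encode(s), self.k)
            c = np.unique(c[c != _SENTINEL])
            codes_list.append(c)
            ref_list.append(np.full(len(c), i, dtype=np.int64))
        if codes_list and sum(len(c) for c in codes_list):
            codes = np.concatenate(codes_list)
            refs = np.concatenate(ref_list)
            order = np.argsort(codes, kind="stable")
            codes, refs = codes[order], refs[order]
            self._ucodes, starts = np.unique(codes, return_index=True)
            self._starts = starts
            self._ends = np.append(starts[1:], len(codes))
            self._refs = refs
        else:
            self._ucodes = np.empty(0, dtype=np.uint64)
            self._starts = np.empty(0, dtype=np.int64)
            self._ends = np.empty(0, dtype=np.int64)
            self._refs = np.empty(0, dtype=np.int64)
        # direct membership table: turns the common case (k-mer absent from
        # the library) into one gather instead of a binary search
        self._lut: np.ndarray | None = None
        if self.k <= 14 and len(self._ucodes):
            self._lut = np.zeros(4 ** self.k, dtype=bool)
            self._lut[self._ucodes] = True

    def __len__(self) -> int:
        return len(self.names)

    def candidates(self, codes: np.ndarray,
                   read_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unique (read, reference) pairs sharing at least one k-mer.

        `codes` is flat; `read_idx` gives the read index of each code.
        """
        if len(self._ucodes) == 0 or len(codes) == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e
        if self._lut is not None:
            inb = codes < self._lut.size
            inb[inb] = self._lut[codes[inb]]
            codes = codes[inb]
            read_idx = read_idx[inb]
            if len(codes) == 0:
                e = np.empty(0, dtype=np.int64)
                return e, e
        pos = np.searchsorted(self._ucodes, codes)
        pos[pos >= len(self._ucodes)] = 0
        match = self._ucodes[pos] == codes
        match &= codes != _SENTINEL
        pos = pos[match]
        reads = read_idx[match]
        starts, ends = self._starts[pos], self._ends[pos]
        lens = ends - starts
        total = int(lens.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e
        # grouped-arange expansion of the CSR slices
        rep_starts = np.repeat(starts, lens)
        base = np.repeat(np.cumsum(lens) - lens, lens)
        idx = rep_starts + (np.arange(total) - base)
        pair_refs = self._refs[idx]
        pair_reads = np.repeat(reads, lens)
        key = pair_reads * np.int64(len(self.names)) + pair_refs
        ukey = np.unique(key)
        return ukey // len(self.names), ukey % len(self.names)


def _as_index(references, k: int) -> ReferenceIndex:
    if isinstance(references, ReferenceIndex):
        return references
    return ReferenceIndex(references, k=k)


def _align_distance(query: str, target: str, e_max: int) -> int:
    res = edlib.align(query, target, mode="HW", task="distance", k=e_max)
    return int(res["editDistance"])


def find_hits(read: str, references, params: MappingParams) -> list[Hit]:
    """All accepted hits of one read against a reference collection."""
    index = _as_index(references, params.kmer_seed_length)
    L = len(read)
    if L < params.kmer_seed_length or len(index) == 0:
        return []
    e_max = params.max_edits(L)
    arr = encode(read)
    rc = seqio.revcomp_codes(arr)
    hits: list[Hit] = []
    for strand, codes_src, qstr in (
            ("+", arr, read), ("-", rc, seqio.decode(rc))):
        codes = kmer_codes(codes_src, params.kmer_seed_length)
        reads, refs = index.candidates(codes, np.zeros(len(codes), dtype=np.int64))
        for r in refs:
            d = _align_distance(qstr, index.seqs[int(r)], e_max)
            if d >= 0:
                hits.append(Hit(target_id=index.names[int(r)], strand=strand,
                                distance=d, identity=1 - d / L,
                                aligned_fraction=1.0, score=L - 2 * d))
    return hits


def assign_read(hits: Sequence[Hit], rng: np.random.Generator,
                read_id: str | None = None) -> ReadAssignment:
    """Pick one assignment: best score, ties resolved uniformly at random."""
    if not hits:
        return ReadAssignment(read_id, None, None, 0.0, 0.0)
    best = max(h.score for h in hits)
    tied = [h for h in hits if h.score == best]
    h = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
    return ReadAssignment(read_id, h.target_id, h.strand,
                          h.identity, h.aligned_fraction)


@dataclass
class AssignmentTable:
    """Per-read assignments, stored columnar for scale."""

    target_idx: np.ndarray  # int64; -1 = unmapped
    strand: np.ndarray      # int8; +1 / -1 / 0
    identity: np.ndarray    # float32; nan when unmapped
    ref_names: list[str]
    n_input_reads: int
    read_ids: list[str] | None = None
    n_dropped_short: int = 0

    def __len__(self) -> int:
        return len(self.target_idx)

    @property
    def n_mapped(self) -> int:
        return int((self.target_idx >= 0).sum())

    def target_counts(self) -> pd.Series:
        """Mapped reads per reference."""
        mapped = self.target_idx[self.target_idx >= 0]
        counts = np.bincount(mapped, minlength=len(self.ref_names))
        return pd.Series(counts, index=pd.Index(self.ref_names, name="target_id"))

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self)
        ids = self.read_ids if self.read_ids is not None \
            else [f"read{i}" for i in range(n)]
        names = np.array(self.ref_names + ["UNMAPPED"], dtype=object)
        strands = np.array(["-", "?", "+"], dtype=object)
        return pd.DataFrame({
            "read_id": ids,
            "target_id": names[self.target_idx],
            "strand": strands[self.strand.astype(np.int64) + 1],
            "identity": np.round(self.identity.astype(float), 6),
        })

    def to_tsv(self, path, library_map: Mapping[str, str] | None = None) -> None:
        df = self.to_dataframe()
        if library_map is not None:
            df["family_id"] = [library_map.get(t, "")
                               for t in df["target_id"]]
        df.to_csv(path, sep="\t", index=False)


def _parse_reads(reads) -> tuple[list[str] | None, list[str]]:
    """Accept a FASTQ path, an iterable of sequences, or (id, seq) pairs."""
    if isinstance(reads, (str, os.PathLike)):
        ids, seqs = [], []
        for rid, seq in seqio.read_fastq(reads):
            ids.append(rid)
            seqs.append(seq)
        return ids, seqs
    reads = list(reads)
    if reads and isinstance(reads[0], tuple):
        return [r[0] for r in reads], [r[1] for r in reads]
    return None, [str(r).upper() for r in reads]


def _map_sequences(seqs: list[str], index: ReferenceIndex,
                   params: MappingParams, rng: np.random.Generator,
                   chunk: int = 200_000
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a list of sequences; returns (target_idx, strand, identity)."""
    n = len(seqs)
    target = np.full(n, -1, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int8)
    ident = np.full(n, np.nan, dtype=np.float32)
    if n == 0 or len(index) == 0:
        return target, strand, ident
    k = params.kmer_seed_length
    # group reads by length so each group is a dense matrix
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    for L in np.unique(lengths):
        if L < k:
            continue
        gidx = np.flatnonzero(lengths == L)
        e_max = params.max_edits(int(L))
        for lo in range(0, len(gidx), chunk):
            sub = gidx[lo:lo + chunk]
            block = b"".join(seqs[i].encode() for i in sub)
            arr = seqio._ENCODE[np.frombuffer(block, dtype=np.uint8)
                                .reshape(len(sub), L)]
            rc = seqio._COMPLEMENT[arr[:, ::-1]]
            local = np.arange(len(sub), dtype=np.int64)
            cand_r: list[np.ndarray] = []
            cand_f: list[np.ndarray] = []
            cand_s: list[np.ndarray] = []
            for sgn, mat in ((1, arr), (-1, rc)):
                codes = kmer_codes(mat, k)
                flat = codes.ravel()
                ridx = np.repeat(local, codes.shape[1])
                r, f = index.candidates(flat, ridx)
                cand_r.append(r)
                cand_f.append(f)
                cand_s.append(np.full(len(r), sgn, dtype=np.int8))
            cr = np.concatenate(cand_r)
            cf = np.concatenate(cand_f)
            cs = np.concatenate(cand_s)
            if len(cr) == 0:
                continue
            rc_str: dict[int, str] = {}
            dist = np.empty(len(cr), dtype=np.int64)
            refseqs = index.seqs
            for i in range(len(cr)):
                ri = int(cr[i])
                if cs[i] > 0:
                    q = seqs[sub[ri]]
                else:
                    q = rc_str.get(ri)
                    if q is None:
                        q = seqio.decode(rc[ri])
                        rc_str[ri] = q
                dist[i] = _align_distance(q, refseqs[int(cf[i])], e_max)
            ok = dist >= 0
            if not ok.any():
                continue
            cr, cf, cs, dist = cr[ok], cf[ok], cs[ok], dist[ok]
            # best edit distance per read; ties broken uniformly at random
            tie = rng.random(len(cr))
            order = np.lexsort((tie, dist, cr))
            first = np.ones(len(order), dtype=bool)
            sorted_r = cr[order]
            first[1:] = sorted_r[1:] != sorted_r[:-1]
            pick = order[first]
            winners = sub[cr[pick]]
            target[winners] = cf[pick]
            strand[winners] = cs[pick]
            ident[winners] = 1.0 - dist[pick] / float(L)
    return target, strand, ident


def map_readset(reads, references, params: MappingParams | None = None,
                truncate_to: int | None = None) -> AssignmentTable:
    """Map a read set as single ends.

    ``reads`` may be a FASTQ path, a list of sequences, or (id, seq) pairs.
    With ``truncate_to`` set, reads are cut to that length and shorter reads
    are dropped (the abundance pipeline's fixed-length contract; the dropped
    count is recorded).  ``n_input_reads`` is the number of reads used for
    mapping, i.e. after truncation/dropping.
    """
    params = params or MappingParams()
    ids, seqs = _parse_reads(reads)
    dropped = 0
    if truncate_to is not None:
        keep = [i for i, s in enumerate(seqs) if len(s) >= truncate_to]
        dropped = len(seqs) - len(keep)
        seqs = [seqs[i][:truncate_to] for i in keep]
        if ids is not None:
            ids = [ids[i] for i in keep]
    index = _as_index(references, params.kmer_seed_length)
    rng = np.random.default_rng(params.seed)
    target, strand, ident = _map_sequences(seqs, index, params, rng)
    return AssignmentTable(target_idx=target, strand=strand, identity=ident,
                           ref_names=list(index.names),
                           n_input_reads=len(seqs), read_ids=ids,
                           n_dropped_short=dropped)


@dataclass
class PairAssignmentTable:
    """Joint assignment of mate 1 and mate 2 against one combined reference."""

    mate1: AssignmentTable
    mate2: AssignmentTable
    read_ids: list[str] | None = None

    def __post_init__(self):
        if len(self.mate1) != len(self.mate2):
            raise PairingError("mate files differ in read count")

    def __len__(self) -> int:
        return len(self.mate1)

    @property
    def n_pairs(self) -> int:
        return len(self.mate1)

    @property
    def both_mapped(self) -> np.ndarray:
        return (self.mate1.target_idx >= 0) & (self.mate2.target_idx >= 0)

    def to_dataframe(self) -> pd.DataFrame:
        names = np.array(self.mate1.ref_names + ["UNMAPPED"], dtype=object)
        n = len(self)
        ids = self.read_ids if self.read_ids is not None \
            else [f"pair{i}" for i in range(n)]
        return pd.DataFrame({
            "read_id": ids,
            "target1": names[self.mate1.target_idx],
            "target2": names[self.mate2.target_idx],
            "in_pair": self.both_mapped,
        })


def map_pairs(reads1, reads2, references,
              params: MappingParams | None = None) -> PairAssignmentTable:
    """Map mates of a paired read set (full length, no truncation).

    Pairs with either mate unmapped are flagged ``in_pair=False`` and are
    excluded from downstream gene-RE analysis.
    """
    params = params or MappingParams()
    ids1, seqs1 = _parse_reads(reads1)
    ids2, seqs2 = _parse_reads(reads2)
    if len(seqs1) != len(seqs2):
        raise PairingError(
            f"mate counts differ: {len(seqs1)} vs {len(seqs2)}")
    if ids1 is not None and ids2 is not None:
        base1 = [i.removesuffix("/1") for i in ids1]
        base2 = [i.removesuffix("/2") for i in ids2]
        if base1 != base2:
            bad = next(i for i, (a, b) in enumerate(zip(base1, base2))
                       if a != b)
            raise PairingError(
                f"mate ids out of sync at record {bad}: "
                f"{ids1[bad]!r} vs {ids2[bad]!r}")
    index = _as_index(references, params.kmer_seed_length)
    rng = np.random.default_rng(params.seed)
    t1 = AssignmentTable(*_map_sequences(seqs1, index, params, rng),
                         ref_names=list(index.names),
                         n_input_reads=len(seqs1), read_ids=ids1)
    t2 = AssignmentTable(*_map_sequences(seqs2, index, params, rng),
                         ref_names=list(index.names),
                         n_input_reads=len(seqs2), read_ids=ids2)
    base_ids = None
    if ids1 is not None:
        base_ids = [i.removesuffix("/1") for i in ids1]
    return PairAssignmentTable(mate1=t1, mate2=t2, read_ids=base_ids)
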