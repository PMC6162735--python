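"""Repeat landscape: locate family sequences along a genome assembly and
count masked bases in fixed windows.

The scanner plays the role of a masking tool bound to a divergence ceiling:
a query sequence masks a genome interval when it aligns there (unit edit
costs, either strand) with divergence <= ``max_divergence`` over at least
``min_hit_length`` bases.  Candidate loci come from exact k-mer seeding;
each seed cluster is verified with a semi-global alignment.  Hits of the
same query class (e.g. the pooled Gypsy set, the pooled Copia set, or a
centromeric probe) are unioned before counting, so ``masked_bases`` is a
coverage measure, never a double-counting sum.

The real-genome window default is 3 Mbp; synthetic-scale runs typically use
tens of kilobases.
"""

from __future__ import annotations

from typing import Mapping

import edlib
import numpy as np
import pandas as pd

from .seqio import decode, encode, revcomp_codes
from .readmap import kmer_codes, _SENTINEL

INTERVAL_COLUMNS = ["chrom", "start", "end", "cls", "query_id", "divergence"]


class WindowIntegrityError(ValueError):
    """Interval outside chromosome bounds."""


class _GenomeKmerIndex:
    """Sorted k-mer -> position lookup for one chromosome."""

    def __init__(self, codes_arr: np.ndarray, k: int):
        self.k = k
        codes = kmer_codes(codes_arr, k)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.positions = order.astype(np.int64)

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query_offset, genome_position) for every exact k-mer match."""
        lo = np.searchsorted(self.sorted_codes, query_codes, side="left")
        hi = np.searchsorted(self.sorted_codes, query_codes, side="right")
        lens = hi - lo
        valid = (lens > 0) & (query_codes != _SENTINEL)
        lo, lens = lo[valid], lens[valid]
        offsets = np.flatnonzero(valid)
        total = int(lens.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e
        rep_lo = np.repeat(lo, lens)
        base = np.repeat(np.cumsum(lens) - lens, lens)
        pos = self.positions[rep_lo + np.arange(total) - base]
        return np.repeat(offsets, lens), pos


def scan_repeats(genome: Mapping[str, str],
                 queries: Mapping[str, Mapping[str, str]],
                 max_divergence: float = 0.20,
                 min_hit_length: int = 100,
                 k: int = 13) -> pd.DataFrame:
    """Scan a genome for copies of query sequences.

    ``queries`` maps a class label (e.g. 'Gypsy', 'Copia', 'centromere') to
    its {query_id: sequence} set.  Returns accepted hits as a DataFrame with
    columns chrom, start, end (0-based half-open), cls, query_id, divergence.
    """
    rows: list[tuple] = []
    for chrom, seq in genome.items():
        gcodes = encode(seq)
        glen = len(gcodes)
        if glen < k:
            continue
        index = _GenomeKmerIndex(gcodes, k)
        for cls, qset in queries.items():
            for qid, qseq in qset.items():
                for strand in ("+", "-"):
                    q = qseq if strand == "+" else decode(
                        revcomp_codes(encode(qseq)))
                    qlen = len(q)
                    if qlen < max(k, min_hit_length):
                        continue
                    qcodes = kmer_codes(encode(q), k)
                    offs, pos = index.lookup(qcodes)
                    if len(pos) == 0:
                        continue
                    starts = np.unique(pos - offs)
                    # cluster candidate copy starts; distinct copies are
                    # separated by much more than half a query length
                    gap = np.diff(starts)
                    breaks = np.flatnonzero(gap > 0.5 * qlen)
                    clusters = np.split(starts, breaks + 1)
                    e_max = int(max_divergence * qlen + 1e-9)
                    pad = int(0.25 * qlen) + 50
                    for cl in clusters:
                        w0 = max(0, int(cl[0]) - pad)
                        w1 = min(glen, int(cl[-1]) + qlen + pad)
                        res = edlib.align(q, seq[w0:w1], mode="HW",
                                          task="locations", k=e_max)
                        d = res["editDistance"]
                        if d < 0:
                            continue
                        s, e = res["locations"][0]
                        if e + 1 - s < min_hit_length:
                            continue
                        rows.append((chrom, w0 + s, w0 + e + 1, cls, qid,
                                     round(d / qlen, 6)))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def merge_intervals(intervals: pd.DataFrame,
                    by: tuple[str, ...] = ("chrom", "cls")) -> pd.DataFrame:
    """Union of overlapping intervals within each group."""
    out_rows: list[tuple] = []
    if intervals.empty:
        return pd.DataFrame(columns=["chrom", "cls", "start", "end"])
    for key, grp in intervals.groupby(list(by)):
        grp = grp.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out_rows.append((*key, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out_rows.append((*key, cur_s, cur_e))
    return pd.DataFrame(out_rows, columns=[*by, "start", "end"])


def window_counts(intervals: pd.DataFrame,
                  chrom_lengths: Mapping[str, int],
                  window_size: int = 3_000_000) -> pd.DataFrame:
    """Masked bases per fixed-size window, per class.

    Windows tile each chromosome (the last window may be short); an interval
    spanning a boundary contributes its bases to both windows, conserving
    the total.  Intervals beyond a chromosome end raise an integrity error.
    """
    merged = merge_intervals(intervals)
    for _, row in merged.iterrows():
        length = chrom_lengths.get(row["chrom"])
        if length is None or row["end"] > length or row["start"] < 0:
            raise WindowIntegrityError(
                f"interval {row['chrom']}:{row['start']}-{row['end']} "
                f"outside chromosome bounds")
    classes = sorted(merged["cls"].unique()) if not merged.empty else []
    rows: list[tuple] = []
    for chrom, length in chrom_lengths.items():
        edges = list(range(0, length, window_size)) or [0]
        for w0 in edges:
            w1 = min(w0 + window_size, length)
            for cls in classes:
                sel = merged[(merged["chrom"] == chrom) & (merged["cls"] == cls)]
                ov = np.minimum(sel["end"], w1) - np.maximum(sel["start"], w0)
                masked = int(ov[ov > 0].sum()) if len(sel) else 0
                rows.append((chrom, w0, w1, cls, masked))
            if not classes:
                rows.append((chrom, w0, w1, "none", 0))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end",
                                       "cls", "masked_bases"])


def write_bedgraph(track: pd.DataFrame, path, cls: str) -> None:
    """One bedGraph per class: chrom, start, end, masked_bases."""
    sel = track[track["cls"] == cls]
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{cls}_masked_bases"\n')
        for _, r in sel.iterrows():
            fh.write(f"{r['chrom']}\t{r['window_start']}\t{r['window_end']}"
                     f"\t{r['masked_bases']}\n")
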