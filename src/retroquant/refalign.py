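"""Reference (brute-force) semi-global aligner.

Full dynamic-programming scan over every reference position and both
strands, with unit edit costs and free ends on the reference.  It shares no
code with the seeded mapper in :mod:`retroquant.readmap` and exists as an
independent check of its accept/reject decisions and best-target choices on
small instances.  Complexity is O(|read| * |reference|) per strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .seqio import encode, revcomp_codes


def semiglobal_distance(query: np.ndarray, target: np.ndarray) -> int:
    """Minimal unit-cost edit distance of the full query against any
    substring of the target (free target ends)."""
    m, n = len(query), len(target)
    if n == 0:
        return m
    col = np.arange(n + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int64)  # row 0: free start in target
    for i in range(m):
        sub = (target != query[i]).astype(np.int64)
        raw = np.empty(n + 1, dtype=np.int64)
        raw[0] = prev[0] + 1
        raw[1:] = np.minimum(prev[:-1] + sub, prev[1:] + 1)
        # horizontal relaxation: dp[j] = min_{j' <= j} raw[j'] + (j - j')
        prev = np.minimum.accumulate(raw - col) + col
    return int(prev.min())


@dataclass
class BruteForceHit:
    target_id: str
    strand: str
    distance: int
    identity: float


def best_hits_bruteforce(read: str, references: Mapping[str, str],
                         min_identity: float = 0.9
                         ) -> tuple[list[BruteForceHit], bool]:
    """Exhaustive scan: best accepted hit(s) of a read over all references
    and strands.

    Returns (tied best hits at the minimal edit distance, accepted flag).
    The accept rule matches the mapper contract: identity
    ``1 - d/len(read) >= min_identity``.
    """
    L = len(read)
    e_max = int(L * (1 - min_identity) + 1e-9)
    q_fw = encode(read)
    q_rc = revcomp_codes(q_fw)
    results: list[BruteForceHit] = []
    for name, seq in references.items():
        t = encode(seq)
        for strand, q in (("+", q_fw), ("-", q_rc)):
            d = semiglobal_distance(q, t)
            results.append(BruteForceHit(name, strand, d, 1 - d / L))
    best = min(r.distance for r in results) if results else L
    accepted = best <= e_max
    tied = [r for r in results if r.distance == best] if accepted else []
    return tied, accepted
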