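"""Per-family group comparison: PERMANOVA, PCA, and classification.

PERMANOVA follows Anderson's formulation on a Euclidean distance matrix:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within
    pseudo-F  = (SS_among / (a-1)) / (SS_within / (N-a))

The null distribution permutes group labels.  When the number of distinct
label arrangements does not exceed the requested permutation count, the test
enumerates them all and reports the exact proportion (identity included);
otherwise it samples and applies the +1 correction, so the p-value can never
be 0.  For univariate data with Euclidean distances the pseudo-F coincides
with the classical one-way ANOVA F.

Per-family testing is marginal, with no multiple-testing correction for the
headline classification (a Benjamini-Hochberg column is emitted alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import false_discovery_control

from .abundance import AbundanceMatrix


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)


def euclidean_distance_matrix(values, ids: list[str] | None = None
                              ) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample vectors.

    ``values`` is samples x features; a 1-D array is treated as univariate
    samples.  A DataFrame contributes its index as sample ids.
    """
    if isinstance(values, pd.DataFrame):
        ids = ids or list(values.index.astype(str))
        values = values.to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if ids is None:
        ids = [f"s{i}" for i in range(len(values))]
    d = squareform(pdist(values, metric="euclidean"))
    return DistanceMatrix(values=d, ids=list(ids))


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int
    ss_among: float
    ss_within: float
    exhaustive: bool = False
    degenerate: bool = False


def _ss_within_batch(D2: np.ndarray, label_rows: np.ndarray,
                     group_codes: np.ndarray,
                     group_sizes: np.ndarray) -> np.ndarray:
    """SS_within for each row of label assignments (vectorised)."""
    out = np.zeros(label_rows.shape[0])
    for g, n_g in zip(group_codes, group_sizes):
        Z = (label_rows == g).astype(float)
        out += ((Z @ D2) * Z).sum(axis=1) / (2.0 * n_g)
    return out


def _distinct_assignments(codes: np.ndarray) -> np.ndarray:
    """All distinct rearrangements of a label multiset (as code rows)."""
    n = len(codes)
    uniq, counts = np.unique(codes, return_counts=True)
    rows: list[np.ndarray] = []

    def rec(positions: tuple[int, ...], remaining: list[tuple[int, int]],
            current: np.ndarray) -> None:
        if not remaining:
            rows.append(current.copy())
            return
        g, c = remaining[0]
        for chosen in combinations(positions, c):
            current[list(chosen)] = g
            rest = tuple(p for p in positions if p not in set(chosen))
            rec(rest, remaining[1:], current)

    rec(tuple(range(n)), list(zip(uniq.tolist(), counts.tolist())),
        np.empty(n, dtype=np.int64))
    return np.array(rows)


def n_distinct_assignments(groups) -> int:
    _, counts = np.unique(np.asarray(groups), return_counts=True)
    total = comb(int(counts.sum()), int(counts[0]))
    left = int(counts.sum()) - int(counts[0])
    for c in counts[1:]:
        total *= comb(left, int(c))
        left -= int(c)
    return total


def permanova(D: DistanceMatrix | np.ndarray, groups,
              n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with permutation p-value."""
    dvals = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    labels = np.asarray(groups)
    N = len(labels)
    if dvals.shape != (N, N):
        raise ValueError("groups length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    sizes = np.bincount(codes)
    if a < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    D2 = dvals ** 2
    iu = np.triu_indices(N, k=1)
    ss_total = D2[iu].sum() / N
    gcodes = np.arange(a)

    def pseudo_f(ss_within: np.ndarray) -> np.ndarray:
        ss_among = ss_total - ss_within
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_among / (a - 1)) / (ss_within / (N - a))
        f = np.where((ss_within <= 1e-12) & (ss_among > 1e-12), np.inf, f)
        f = np.where((ss_within <= 1e-12) & (ss_among <= 1e-12), 0.0, f)
        return f

    sw_obs = _ss_within_batch(D2, codes[None, :], gcodes, sizes)[0]
    f_obs = float(pseudo_f(np.array([sw_obs]))[0])
    ss_among = ss_total - sw_obs

    if ss_total <= 1e-12:  # all distances zero
        return PermanovaResult(pseudo_F=0.0, p_value=1.0,
                               n_permutations=0, seed=seed,
                               ss_among=0.0, ss_within=0.0, degenerate=True)

    n_total = n_distinct_assignments(labels)
    if n_total <= n_permutations:
        rows = _distinct_assignments(codes)
        sw = _ss_within_batch(D2, rows, gcodes, sizes)
        f_perm = pseudo_f(sw)
        p = float(np.mean(f_perm >= f_obs - 1e-12))
        return PermanovaResult(pseudo_F=f_obs, p_value=p,
                               n_permutations=n_total, seed=seed,
                               ss_among=float(ss_among),
                               ss_within=float(sw_obs), exhaustive=True)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(codes, (n_permutations, 1)), axis=1)
    sw = _ss_within_batch(D2, perms, gcodes, sizes)
    f_perm = pseudo_f(sw)
    n_ge = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (n_ge + 1) / (n_permutations + 1)
    return PermanovaResult(pseudo_F=f_obs, p_value=float(p),
                           n_permutations=n_permutations, seed=seed,
                           ss_among=float(ss_among), ss_within=float(sw_obs))


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # features x components
    variance_explained: np.ndarray  # percent, sums to 100 over components
    degenerate: bool = False


def pca(matrix) -> PCAResult:
    """Centered SVD principal component analysis.

    Sign convention: the largest-magnitude loading of each component is
    positive.  ``variance_explained`` is in percent and sums to 100 unless
    the matrix is constant (then all zero and ``degenerate`` is set).
    """
    if isinstance(matrix, pd.DataFrame):
        sample_ids = list(matrix.index.astype(str))
        feature_ids = list(matrix.columns.astype(str))
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    degenerate = total <= 1e-30
    var = np.zeros_like(s) if degenerate else (s ** 2) / total * 100.0
    scores = U * s
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=sample_ids, columns=comps),
        loadings=pd.DataFrame(loadings, index=feature_ids, columns=comps),
        variance_explained=var, degenerate=degenerate)


def classify_families(matrix: AbundanceMatrix,
                      alpha: float = 0.01,
                      n_permutations: int = 999,
                      seed: int = 0,
                      metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-family univariate PERMANOVA between groups, with direction.

    Returns one row per family: group means, pseudo-F, permutation p,
    significance at ``alpha`` (p <= alpha), direction of the mean difference,
    and a BH-adjusted p column (informational; the headline classification is
    the marginal one).
    """
    groups = matrix.groups.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for fam in matrix.family_ids:
        x = matrix.values[fam].to_numpy(dtype=float)
        D = euclidean_distance_matrix(x, ids=matrix.genotypes)
        fam_seed = int(rng.integers(0, 2**31 - 1))
        res = permanova(D, groups, n_permutations=n_permutations,
                        seed=fam_seed)
        mw = float(x[groups == "wild"].mean())
        mc = float(x[groups == "cultivated"].mean())
        sig = bool(res.p_value <= alpha) and not res.degenerate
        if mc > mw:
            direction = "higher-in-cultivated"
        elif mw > mc:
            direction = "higher-in-wild"
        else:
            direction = "none"
        rows.append((fam, mw, mc, res.pseudo_F, res.p_value, sig, direction))
    out = pd.DataFrame(rows, columns=[
        "family_id", "mean_wild", "mean_cultivated", "pseudo_F", "p_value",
        "significant", "direction"])
    out["p_bh"] = false_discovery_control(out["p_value"], method="bh")
    if metadata is not None:
        out = metadata[["family_id", "lineage", "superfamily"]].merge(
            out, on="family_id", how="right")
    return out


def lineage_summary(classification: pd.DataFrame) -> pd.DataFrame:
    """Counts of significant families per lineage/superfamily with the
    direction split (the lineage-level view of the classification)."""
    if "lineage" not in classification.columns:
        raise ValueError("classification lacks lineage metadata")
    grp = classification.groupby(["superfamily", "lineage"])
    out = grp.agg(
        n_families=("family_id", "size"),
        n_significant=("significant", "sum"),
        n_higher_cultivated=("direction", lambda d: int(
            ((d == "higher-in-cultivated")
             & classification.loc[d.index, "significant"]).sum())),
        n_higher_wild=("direction", lambda d: int(
            ((d == "higher-in-wild")
             & classification.loc[d.index, "significant"]).sum())),
    ).reset_index()
    out["pct_significant"] = 100.0 * out["n_significant"] / out["n_families"]
    return out
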