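"""Alpha and beta diversity: Shannon index, richness, Bray-Curtis,
non-metric multidimensional scaling, ANOSIM and PERMANOVA.

Bray-Curtis matrices are held in :class:`skbio.DistanceMatrix` (symmetric,
zero diagonal, hollow by construction).  ANOSIM and PERMANOVA are
permutation tests computed here so that every permutation stream is driven
by an explicit seed:

* ANOSIM follows Clarke (1993): dissimilarities are ranked with mid-ranks,
  and R = (mean between-group rank - mean within-group rank) / (M/2) with
  M = n(n-1)/2; the one-sided p-value counts permuted R >= observed.
* PERMANOVA partitions the Gower-centred inner-product matrix with
  sequential (Type-I) sums of squares over an ordered list of terms
  (McArdle & Anderson 2001), permuting raw sample identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts_or_props) -> float:
    """Shannon index H' = -sum p_i ln p_i (natural log), zeros skipped."""
    x = np.asarray(counts_or_props, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(counts) -> int:
    """Number of taxa with strictly positive abundance."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    return int((x > 0).sum())


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarities among the samples (columns) of a count
    or relative-abundance table: BC(x, y) = sum|x-y| / sum(x+y)."""
    data = table.data if hasattr(table, "data") else pd.DataFrame(table)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = data.to_numpy(dtype=float).T
    if (mat.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample")
    condensed = pdist(mat, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(data.columns))


@dataclass
class PermutationTestResult:
    method: str
    statistic: float
    n_perm: int
    p_value: float

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")
        if self.p_value < 1.0 / (self.n_perm + 1) - 1e-12:
            raise ValueError("p-value below permutation resolution")


def _condensed_rank_masks(labels: np.ndarray, iu):
    within = labels[iu[0]] == labels[iu[1]]
    return within


def anosim(
    d: DistanceMatrix,
    grouping,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Clarke's ANOSIM with mid-ranks for ties; one-sided (large R).

    ``grouping`` aligns with ``d.ids``.  Every group needs >= 2 members.
    """
    labels = np.asarray(
        pd.Series(grouping).to_numpy() if not isinstance(grouping, np.ndarray) else grouping
    )
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"group(s) with fewer than 2 members: {list(small)}")
    codes = np.searchsorted(uniq, labels)

    iu = np.triu_indices(n, 1)
    ranks = rankdata(d.data[iu])  # mid-ranks
    M = n * (n - 1) // 2
    denom = M / 2.0

    def r_stat(within: np.ndarray) -> float:
        rw = ranks[within].mean()
        rb = ranks[~within].mean()
        return (rb - rw) / denom

    observed = r_stat(_condensed_rank_masks(codes, iu))

    rng = np.random.default_rng(seed)
    if n_perm > 0:
        perms = np.empty((n_perm, n), dtype=codes.dtype)
        for i in range(n_perm):
            perms[i] = rng.permutation(codes)
        within = perms[:, iu[0]] == perms[:, iu[1]]  # (n_perm, M)
        n_within = within.sum(axis=1).astype(float)
        sum_within = within @ ranks
        total = ranks.sum()
        rw = sum_within / n_within
        rb = (total - sum_within) / (M - n_within)
        r_perm = (rb - rw) / denom
        p = (np.count_nonzero(r_perm >= observed - 1e-12) + 1) / (n_perm + 1)
    else:
        p = 1.0
    return PermutationTestResult("ANOSIM", float(observed), n_perm, float(p))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Per-term partition of distance-matrix variance.

    ``table`` has one row per term plus ``Residual`` and ``Total`` with
    columns df, SS, R2, pseudo_F, p_value.  Term R2 plus residual R2 sum
    to 1.
    """

    table: pd.DataFrame
    n_perm: int
    dropped_terms: list[str]


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _dummy_code(values: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(values) and values.nunique() > 2:
        return values.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(values.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def permanova(
    d: DistanceMatrix,
    terms: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential-SS PERMANOVA (pseudo-F per term, raw-data permutation).

    ``terms`` is a DataFrame aligned with ``d.ids`` whose column order is
    the (Type-I) model order.  Numeric columns enter as covariates,
    anything else is dummy-coded.  Constant or collinear terms contribute
    no degrees of freedom and are dropped with a warning.
    """
    n = d.shape[0]
    if len(terms) != n:
        raise ValueError("terms do not align with samples")
    G = _gower_center(d.data.astype(float) ** 2)
    ss_total = float(np.trace(G))

    # nested hat matrices
    X = np.ones((n, 1))
    hats = [X @ np.linalg.pinv(X.T @ X) @ X.T]
    ranks = [1]
    kept: list[str] = []
    dropped: list[str] = []
    for name in terms.columns:
        cols = _dummy_code(terms[name])
        X_new = np.column_stack([X, cols])
        r_new = np.linalg.matrix_rank(X_new)
        if r_new <= ranks[-1]:
            logger.warning("permanova: dropping constant/collinear term %r", name)
            dropped.append(name)
            continue
        X = X_new
        hats.append(X @ np.linalg.pinv(X.T @ X) @ X.T)
        ranks.append(r_new)
        kept.append(name)
    if not kept:
        raise ValueError("no usable terms")
    df_terms = np.diff(ranks)
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual df")

    # projector increments; trailing residual projector
    deltas = [hats[i + 1] - hats[i] for i in range(len(kept))]
    resid_proj = np.eye(n) - hats[-1]

    def partition(Gm: np.ndarray):
        ss = np.array([float(np.sum(delta * Gm.T)) for delta in deltas])
        ss_res = float(np.sum(resid_proj * Gm.T))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df_terms) / (ss_res / df_res)
        return ss, ss_res, f

    ss, ss_res, f_obs = partition(G)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(kept))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, f_perm = partition(G[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs - 1e-12
    p = (exceed + 1) / (n_perm + 1)

    rows = []
    for i, name in enumerate(kept):
        rows.append(
            {
                "term": name,
                "df": int(df_terms[i]),
                "SS": ss[i],
                "R2": ss[i] / ss_total,
                "pseudo_F": f_obs[i],
                "p_value": p[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": int(df_res),
            "SS": ss_res,
            "R2": ss_res / ss_total,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "R2": 1.0,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm, dropped)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples x axes
    stress: float              # Kruskal stress-1 of the best start
    stress_path: list[float]   # per-iteration stress of the best start
    n_starts: int


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: best non-decreasing fit to y (unit weights).

    Stack-based, O(n)."""
    n = len(y)
    vals = np.empty(n)
    wts = np.empty(n)
    starts = np.empty(n, dtype=np.intp)
    top = -1
    for i in range(n):
        top += 1
        vals[top] = y[i]
        wts[top] = 1.0
        starts[top] = i
        while top > 0 and vals[top - 1] > vals[top]:
            total = wts[top - 1] + wts[top]
            vals[top - 1] = (vals[top - 1] * wts[top - 1] + vals[top] * wts[top]) / total
            wts[top - 1] = total
            top -= 1
    out = np.empty(n)
    for k in range(top + 1):
        end = starts[k + 1] if k < top else n
        out[starts[k]:end] = vals[k]
    return out


def _pcoa_config(D: np.ndarray, k: int) -> np.ndarray:
    G = _gower_center(D ** 2)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    return float(np.sqrt(((d - dhat) ** 2).sum() / (d ** 2).sum()))


def _canonical_orientation(X: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes and fix signs so the embedding is
    reproducible up to the rotation/reflection invariance of NMDS."""
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for j in range(X.shape[1]):
        if X[np.argmax(np.abs(X[:, j])), j] < 0:
            X[:, j] = -X[:, j]
    return X


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmdsResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Alternates monotone (isotonic) regression of configuration distances on
    the observed dissimilarities (primary treatment of ties) with a
    SMACOF/Guttman configuration update.  The first start is the classical
    (principal-coordinate) configuration; the remaining ``n_starts - 1``
    are random.  A monotone safeguard keeps the reported stress path
    non-increasing: if an update would raise stress the run stops at the
    previous configuration.  Best start wins.
    """
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    D = d.data.astype(float)
    iu = np.triu_indices(n, 1)
    diss = D[iu]

    def isotonic_fit(dist: np.ndarray) -> np.ndarray:
        # primary treatment of ties: within a tie block of the observed
        # dissimilarities, order by the current configuration distances so
        # disorder inside the block carries no penalty
        order = np.lexsort((dist, diss))
        dhat = np.empty_like(dist)
        dhat[order] = _pava(dist[order])
        return dhat

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        if s == 0:
            X = _pcoa_config(D, k)
            if np.allclose(X, 0):
                X = rng.standard_normal((n, k))
        else:
            X = rng.standard_normal((n, k)) * diss.mean()
        dist = pdist(X)
        # guard exact coincident points
        dist[dist == 0] = 1e-12
        dhat = isotonic_fit(dist)
        stress = _stress1(dist, dhat)
        path = [stress]
        for _ in range(max_iter):
            # Guttman transform with target dhat
            ratio = np.zeros_like(dist)
            nz = dist > 0
            ratio[nz] = dhat[nz] / dist[nz]
            B = squareform(-ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = (B @ X) / n
            dist_new = pdist(X_new)
            dist_new[dist_new == 0] = 1e-12
            dhat_new = isotonic_fit(dist_new)
            stress_new = _stress1(dist_new, dhat_new)
            if stress_new > stress + 1e-12:
                break  # monotone safeguard: keep previous configuration
            X, dist, dhat = X_new, dist_new, dhat_new
            improved = stress - stress_new
            stress = stress_new
            path.append(stress)
            if improved < tol:
                break
        if best is None or stress < best[0] - 1e-12:
            best = (stress, X, path)

    stress, X, path = best
    coords = pd.DataFrame(
        _canonical_orientation(X),
        index=list(d.ids),
        columns=[f"NMDS{i + 1}" for i in range(k)],
    )
    return NmdsResult(coords, stress, path, n_starts)
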