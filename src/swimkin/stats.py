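"""Group comparison statistics and PCA + k-means movement phenotyping.

Nonparametric comparisons (Kruskal–Wallis with ε² effect size and
Holm–Bonferroni correction; Mann–Whitney U with rank-biserial r;
Fisher's exact test for 2×k tables) plus the clustering pipeline:
standardized swim parameters → principal components retaining a target
cumulative variance → k-means with elbow / silhouette / gap-statistic
diagnostics → selection of discriminative parameters.

Because k-means clusters are chosen to maximize separation in component
space, naively testing parameters between the resulting clusters is
circular and would report "significant" structure even in homogeneous
cohorts.  Feature selection is therefore gated by a parametric
bootstrap: the observed maximal Kruskal–Wallis statistic over the
candidate parameters is compared against its null distribution obtained
by re-running the whole selection pipeline on Gaussian cohorts with no
cluster structure.  Only when the gate rejects homogeneity (at level
alpha) are individual parameters tested and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "PCAReduction",
    "ClusterResult",
    "kruskal_epsilon2",
    "holm_bonferroni",
    "mann_whitney_r",
    "fisher_exact_2xk",
    "pca_reduce",
    "kmeans_select",
    "discriminative_features",
]


@dataclass
class GroupComparison:
    parameter: str
    H: float
    p_raw: float
    epsilon2: float
    p_adj: float | None = None


def kruskal_epsilon2(*groups, parameter: str = "") -> GroupComparison:
    """Kruskal–Wallis rank test with the ε² effect size.

    ε² = H·(n+1)/(n²−1) where n is the total number of observations;
    it ranges from 0 (no group effect) to 1.  Identical values across
    all groups yield H = 0, ε² = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    n = pooled.size
    if np.all(pooled == pooled[0]):
        return GroupComparison(parameter, 0.0, 1.0, 0.0)
    H, p = sps.kruskal(*groups)
    eps2 = float(H) * (n + 1) / (n * n - 1)
    return GroupComparison(parameter, float(H), float(p),
                           float(min(max(eps2, 0.0), 1.0)))


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def mann_whitney_r(x, y) -> dict:
    """Mann–Whitney U test with the rank-biserial correlation
    r = 1 − 2U/(n_x·n_y), where U is the statistic of ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    U = float(res.statistic)
    r = 1.0 - 2.0 * U / (x.size * y.size)
    return {"U": U, "p": float(res.pvalue), "r": r}


def _table_logprob(table: np.ndarray) -> float:
    from math import lgamma
    t = table
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()

    def lfact(v):
        return lgamma(v + 1.0)

    return (sum(lfact(r) for r in rows) + sum(lfact(c) for c in cols)
            - lfact(n) - sum(lfact(v) for v in t.ravel()))


def fisher_exact_2xk(table) -> float:
    """Fisher's exact conditional test for a 2×k contingency table.

    For 2×2 this matches the classical two-sided Fisher test; for k > 2
    all tables with the observed margins are enumerated and the p-value
    is the total probability of tables no more probable than the
    observed one.  A table with a zero margin carries no information
    and returns p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2×k")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).all() or t.sum() == 0:
        return 1.0
    if t.shape[1] == 2:
        if (cols == 0).any():
            return 1.0
        return float(sps.fisher_exact(t)[1])

    obs_lp = _table_logprob(t)
    k = t.shape[1]
    r0 = int(rows[0])
    total = 0.0

    def recurse(j: int, remaining: int, row0: list[int]):
        nonlocal total
        if j == k - 1:
            if remaining <= cols[j]:
                cand = np.array([row0 + [remaining],
                                 list(cols[:len(row0)] - row0) + [cols[j] - remaining]])
                lp = _table_logprob(cand)
                if lp <= obs_lp + 1e-9:
                    total += np.exp(lp)
            return
        for a in range(0, min(int(cols[j]), remaining) + 1):
            recurse(j + 1, remaining - a, row0 + [a])

    recurse(0, r0, [])
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# dimensionality reduction and clustering
# ---------------------------------------------------------------------------

@dataclass
class PCAReduction:
    scores: np.ndarray           # (n_subjects, n_components)
    loadings: np.ndarray         # (n_components, n_features)
    explained_variance: np.ndarray  # cumulative fraction per component
    n_components: int
    feature_names: list[str]
    dropped: list[str] = field(default_factory=list)


def pca_reduce(X: np.ndarray, feature_names: list[str] | None = None,
               target_variance: float = 0.70) -> PCAReduction:
    """Standardize-and-reduce: retain the smallest number of principal
    components whose cumulative explained variance reaches
    ``target_variance``.  Constant columns are dropped with a warning.
    """
    import warnings
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 subjects")
    names = feature_names or ["p%d" % i for i in range(X.shape[1])]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn("dropping constant parameters before PCA: %s"
                      % ", ".join(dropped))
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA()
    scores = pca.fit_transform(Xs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    ncomp = int(np.searchsorted(cum, target_variance) + 1)
    ncomp = min(ncomp, scores.shape[1])
    return PCAReduction(scores[:, :ncomp], pca.components_[:ncomp], cum[:ncomp],
                        ncomp, names, dropped)


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray          # cluster id per subject, 1..k
    wcss: dict[int, float]
    silhouette: dict[int, float]
    gap: dict[int, float]
    centers: np.ndarray


def _wcss(X: np.ndarray, km: KMeans) -> float:
    return float(km.inertia_)


def kmeans_select(components: np.ndarray, k_range=None, n_init: int = 50,
                  seed: int = 0, gap_B: int = 50) -> ClusterResult:
    """K-means over a range of k with elbow / silhouette / gap diagnostics.

    The elbow criterion (maximal second difference of the within-cluster
    sum of squares, ties broken toward smaller k) picks the reported k;
    silhouette and gap-statistic curves are exposed for override.  The
    gap statistic compares log-WCSS against ``gap_B`` uniform reference
    draws over the data's bounding box.  Deterministic given ``seed``.
    """
    X = np.asarray(components, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects to cluster")
    if k_range is None:
        k_range = range(2, min(8, n - 1) + 1)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("empty k range")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    wcss, sil, gap, labels, centers = {}, {}, {}, {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        wcss[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(X, km.labels_)) if k < n else -1.0
        labels[k] = km.labels_
        centers[k] = km.cluster_centers_
        ref_logw = []
        for _ in range(gap_B):
            Xr = rng.uniform(lo, hi, size=X.shape)
            kr = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(Xr)
            ref_logw.append(np.log(max(kr.inertia_, 1e-300)))
        gap[k] = float(np.mean(ref_logw) - np.log(max(wcss[k], 1e-300)))

    if len(ks) >= 2:
        # elbow: maximal curvature of the WCSS curve; the k=1 point (total
        # sum of squares) anchors the curve so the smallest k is eligible
        wcss1 = float(np.sum((X - X.mean(axis=0)) ** 2))
        w = np.array([wcss1] + [wcss[k] for k in ks])
        d2 = w[:-2] - 2 * w[1:-1] + w[2:]      # curvature at ks[0]..ks[-2]
        best = ks[int(np.argmax(d2))]          # argmax ties -> smaller k
    else:
        best = ks[0]
    return ClusterResult(best, labels[best] + 1, wcss, sil, gap, centers[best])


# ---------------------------------------------------------------------------
# discriminative-feature selection
# ---------------------------------------------------------------------------

def _top_loading_candidates(red: PCAReduction, top: int = 5) -> list[str]:
    seen: list[str] = []
    for comp in red.loadings:
        order = np.argsort(-np.abs(comp))[:top]
        for j in order:
            name = red.feature_names[j]
            if name not in seen:
                seen.append(name)
    return seen


def _max_H(X: np.ndarray, names: list[str], red: PCAReduction,
           labels: np.ndarray) -> float:
    cand = _top_loading_candidates(red)
    idx = [names.index(c) for c in cand]
    best = 0.0
    for j in idx:
        groups = [X[labels == g, j] for g in np.unique(labels)]
        if any(len(g) < 2 for g in groups):
            continue
        gc = kruskal_epsilon2(*groups)
        best = max(best, gc.H)
    return best


def cluster_structure_pvalue(X: np.ndarray, feature_names: list[str],
                             k: int, target_variance: float = 0.70,
                             B: int = 50, seed: int = 0) -> float:
    """Parametric-bootstrap p-value for the existence of cluster
    structure, using the selection-aware statistic max-H over the
    top-loading candidate parameters.

    Null cohorts are standard-Gaussian matrices of the same shape
    (parameters enter standardized); each is pushed through the same
    PCA → k-means → candidate-selection → Kruskal–Wallis pipeline.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)

    def pipeline_stat(M: np.ndarray, nm: list[str]) -> float:
        red = pca_reduce(M, nm, target_variance)
        km = KMeans(n_clusters=k, n_init=4, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(red.scores)
        Ms = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
        return _max_H(Ms, nm, red, labels)

    red_obs = pca_reduce(X, feature_names, target_variance)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels_obs = km.fit_predict(red_obs.scores)
    Xs = X[:, [feature_names.index(n) for n in red_obs.feature_names]]
    Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=1)
    s_obs = _max_H(Xs, red_obs.feature_names, red_obs, labels_obs)

    null_names = ["p%d" % i for i in range(len(red_obs.feature_names))]
    exceed = 0
    for _ in range(B):
        M = rng.standard_normal((X.shape[0], len(null_names)))
        if pipeline_stat(M, null_names) >= s_obs:
            exceed += 1
    return (1 + exceed) / (B + 1)


def discriminative_features(red: PCAReduction, X: np.ndarray,
                            feature_names: list[str],
                            assignments: np.ndarray,
                            alpha: float = 0.05, top: int = 5,
                            gate_B: int = 50, seed: int = 0) -> dict:
    """Parameters that drive the principal components *and* differ
    between clusters.

    Candidates are the top-``top`` absolute loadings of each retained
    component (deduplicated).  A parametric-bootstrap gate first tests
    whether the apparent cluster separation exceeds what the identical
    pipeline produces on homogeneous Gaussian cohorts; if not, the
    feature list is empty.  Otherwise candidates are tested with
    Kruskal–Wallis across clusters, Holm–Bonferroni corrected at
    ``alpha``, and pairwise post hoc Mann–Whitney results are attached.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(assignments)
    k = len(np.unique(labels))
    p_gate = cluster_structure_pvalue(X, feature_names, k, B=gate_B, seed=seed)
    result = {"gate_p": p_gate, "features": [], "tests": [], "posthoc": {}}
    if p_gate > alpha:
        return result

    cand = _top_loading_candidates(red, top)
    comps = []
    for name in cand:
        j = feature_names.index(name)
        groups = [X[labels == g, j] for g in np.unique(labels)]
        if any(len(g) < 2 for g in groups):
            continue
        comps.append(kruskal_epsilon2(*groups, parameter=name))
    if not comps:
        return result
    p_adj = holm_bonferroni([c.p_raw for c in comps])
    for c, pa in zip(comps, p_adj):
        c.p_adj = float(pa)
    result["tests"] = comps
    selected = [c.parameter for c in comps if c.p_adj <= alpha]
    result["features"] = selected

    uniq = np.unique(labels)
    for name in selected:
        j = feature_names.index(name)
        ph = {}
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                ph["%s_vs_%s" % (uniq[a], uniq[b])] = mann_whitney_r(
                    X[labels == uniq[a], j], X[labels == uniq[b], j])
        result["posthoc"][name] = ph
    return result
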