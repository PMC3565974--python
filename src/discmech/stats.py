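"""Cohort statistics: ANOVA with Dunn-Sidak post-hoc, multilinear
MRI -> mechanics regression with R^2 / SEE / power / VIF, correlation PCA,
and Ward agglomerative clustering with natural-division detection.

The multilinear model is ``MP = a0 + a1 T1 + a2 T2 + a3 MTR + a4 ADC + a5 FA``
for each mechanical property MP.  PCA standardizes the variables (mean 0,
SD 1, denominator n-1) and eigendecomposes the correlation matrix; Ward
merge heights are the increments of the total within-cluster sum of
squares, so they sum to the total sum of squares about the grand centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "one_way_anova",
    "dunn_sidak_pairwise",
    "fit_multilinear",
    "regression_power",
    "compute_vif",
    "vif_eliminate",
    "run_pca",
    "correlation_circle",
    "ward_cluster",
    "natural_division",
    "RegressionResult",
    "PCAResult",
    "Dendrogram",
    "MRI_PREDICTORS",
    "MECH_RESPONSES",
]

log = logging.getLogger(__name__)

MRI_PREDICTORS = ("T1_ms", "T2_ms", "MTR", "ADC", "FA")
MECH_RESPONSES = ("E", "k_r", "H_A0", "k_0", "k_a")


# ---------------------------------------------------------------------------
# ANOVA and post-hoc
# ---------------------------------------------------------------------------

def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA from the between/within decomposition.

    Returns ``(F, p)``; degenerate zero-variance input with equal means
    yields ``(0, 1)``.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df1, df2 = k - 1, n - k
    if ssw == 0:
        return (0.0, 1.0) if ssb == 0 else (np.inf, 0.0)
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(sps.f.sf(f, df1, df2))


def dunn_sidak_pairwise(groups: list[np.ndarray],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise pooled-variance t tests with Sidak adjustment.

    ``p' = 1 - (1 - p)^m`` over the m = k(k-1)/2 comparisons; the adjusted
    p-values are clipped to [0, 1].  Returns a tidy DataFrame with columns
    (i, j, t, p_raw, p_adj, significant).
    """
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    m = k * (k - 1) // 2
    if m == 0:
        raise ValueError("need at least two groups")
    n = sum(g.size for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df = n - k
    s2 = ssw / df
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2 * (1 / groups[i].size + 1 / groups[j].size))
            if se == 0:
                t = 0.0 if groups[i].mean() == groups[j].mean() else np.inf
            else:
                t = (groups[i].mean() - groups[j].mean()) / se
            p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
            p_adj = float(np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0))
            rows.append({"i": i, "j": j, "t": float(t), "p_raw": p,
                         "p_adj": p_adj, "significant": p_adj <= alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multilinear regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS fit of one mechanical property on the five MRI predictors."""
    response: str
    predictors: tuple[str, ...]
    coefficients: np.ndarray        # intercept first
    r2: float
    see: float                      # standard error of estimate
    power_alpha05: float
    vif: dict[str, float]
    n: int
    power_convention: str = "n*f2"
    flags: list = field(default_factory=list)


def regression_power(r2: float, n: int, n_predictors: int,
                     alpha: float = 0.05,
                     convention: str = "n*f2") -> float:
    """Power of the overall regression F test via the noncentral F.

    Noncentrality ``lam = n f^2`` (default) or ``(n - p - 1) f^2`` with
    ``f^2 = r^2/(1 - r^2)``; r2=0 returns alpha exactly, r2=1 returns 1.
    """
    if not (0.0 <= r2 <= 1.0):
        raise ValueError("r2 must lie in [0, 1]")
    if n <= n_predictors + 1:
        raise ValueError("n must exceed n_predictors + 1")
    if r2 == 1.0:
        log.warning("regression_power: r2=1, power set to 1 by convention")
        return 1.0
    f2 = r2 / (1.0 - r2)
    mult = {"n*f2": n, "(n-p-1)*f2": n - n_predictors - 1}[convention]
    lam = mult * f2
    df1, df2 = n_predictors, n - n_predictors - 1
    crit = sps.f.isf(alpha, df1, df2)
    if lam == 0:  # scipy's ncf is numerically unreliable at zero noncentrality
        return float(alpha)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def compute_vif(x: np.ndarray, names: tuple[str, ...] | None = None) -> dict:
    """Variance inflation factors: ``VIF_j = 1/(1 - R_j^2)`` from
    regressing predictor j on the others (with intercept)."""
    x = np.asarray(x, float)
    n, p = x.shape
    if p < 2 or n <= p:
        raise ValueError("need >= 2 predictors and n > predictors")
    names = names or tuple(f"x{j}" for j in range(p))
    out = {}
    for j in range(p):
        others = sm.add_constant(np.delete(x, j, axis=1))
        r2 = sm.OLS(x[:, j], others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            log.warning("perfect collinearity: VIF of %s is infinite", names[j])
            out[names[j]] = np.inf
        else:
            out[names[j]] = float(1.0 / (1.0 - r2))
    return out


def fit_multilinear(cohort: pd.DataFrame, response: str,
                    predictors: tuple[str, ...] = MRI_PREDICTORS,
                    power_convention: str = "n*f2") -> RegressionResult:
    """OLS of one mechanical property on the MRI predictors plus intercept.

    Rows with missing values are dropped (listwise).  ``SEE =
    sqrt(SSE/(n - p - 1))`` in the units of the response.
    """
    cols = [response, *predictors]
    data = cohort[cols].dropna()
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError(f"need more than {len(predictors) + 1} complete rows")
    if n < len(cohort):
        log.info("fit_multilinear: dropped %d incomplete rows", len(cohort) - n)
    x = data[list(predictors)].to_numpy(float)
    y = data[response].to_numpy(float)
    design = sm.add_constant(x)
    flags = []
    if np.linalg.matrix_rank(design) < design.shape[1]:
        flags.append("rank-deficient design; coefficients withheld")
        log.warning("fit_multilinear(%s): %s", response, flags[-1])
        coef = np.full(design.shape[1], np.nan)
        r2 = see = power = np.nan
        vif = {nm: np.inf for nm in predictors}
    else:
        fit = sm.OLS(y, design).fit()
        coef = fit.params
        r2 = float(fit.rsquared)
        sse = float(fit.ssr)
        see = float(np.sqrt(sse / (n - len(predictors) - 1)))
        power = regression_power(min(r2, 1.0), n, len(predictors),
                                 convention=power_convention)
        vif = compute_vif(x, predictors)
    return RegressionResult(response=response, predictors=tuple(predictors),
                            coefficients=np.asarray(coef), r2=r2, see=see,
                            power_alpha05=power, vif=vif, n=n,
                            power_convention=power_convention, flags=flags)


def vif_eliminate(cohort: pd.DataFrame, response: str,
                  threshold: float = 10.0,
                  predictors: tuple[str, ...] = MRI_PREDICTORS):
    """Iteratively drop the highest-VIF predictor while max VIF > threshold.

    Returns ``(RegressionResult, trace)`` where the trace records each
    removal with the VIF that triggered it and the change in R^2.
    """
    current = list(predictors)
    result = fit_multilinear(cohort, response, tuple(current))
    trace = []
    while len(current) > 2:
        worst = max(result.vif, key=result.vif.get)
        if not (result.vif[worst] > threshold):
            break
        reduced = tuple(p for p in current if p != worst)
        new_result = fit_multilinear(cohort, response, reduced)
        trace.append({"removed": worst, "vif": result.vif[worst],
                      "delta_r2": new_result.r2 - result.r2})
        current, result = list(reduced), new_result
    return result, trace


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    variables: tuple[str, ...]
    loadings: np.ndarray            # variables x components, orthonormal cols
    scores: np.ndarray              # samples x components
    eigenvalues: np.ndarray         # non-increasing; sums to n_vars
    cumulative_variability: np.ndarray


def run_pca(data: pd.DataFrame | np.ndarray,
            variables: tuple[str, ...] | None = None) -> PCAResult:
    """Correlation PCA: standardize columns (ddof=1), eigendecompose the
    correlation matrix, sort components by eigenvalue.

    Deterministic sign convention: the largest-magnitude loading of each
    component is positive.  Scores are the standardized data projected on
    the loadings; cumulative variability is the running eigenvalue sum
    over the number of variables.
    """
    if isinstance(data, pd.DataFrame):
        variables = variables or tuple(data.columns)
        x = data[list(variables)].to_numpy(float)
    else:
        x = np.asarray(data, float)
        variables = variables or tuple(f"v{j}" for j in range(x.shape[1]))
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant column(s): {[variables[j] for j in const]}")
    z = (x - x.mean(axis=0)) / sd
    corr = z.T @ z / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(p):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = z @ evecs
    return PCAResult(variables=tuple(variables), loadings=evecs,
                     scores=scores, eigenvalues=evals,
                     cumulative_variability=np.cumsum(evals) / p)


def correlation_circle(pca: PCAResult, components: tuple[int, int] = (0, 1)
                       ) -> pd.DataFrame:
    """Variable coordinates on a pair of components: loading x sqrt(eigenvalue)
    (the correlation between variable and component score); all points lie
    in the unit disk."""
    if pca.loadings.shape[1] < 2:
        raise ValueError("need at least 2 components")
    coords = pca.loadings[:, components] * np.sqrt(
        np.maximum(pca.eigenvalues[list(components)], 0.0))
    return pd.DataFrame(coords, index=pca.variables,
                        columns=[f"F{c + 1}" for c in components])


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree.  ``merges[k] = (i, j, height, new_id)``
    with heights equal to the Ward within-cluster sum-of-squares
    increments (non-decreasing)."""
    merges: list[tuple[int, int, float, int]]
    n_leaves: int
    leaf_labels: tuple[str, ...] | None = None

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def cut(self, k: int) -> np.ndarray:
        """Cluster assignment (0..k-1, by order of appearance) after
        stopping at k clusters."""
        parent = list(range(self.n_leaves + len(self.merges)))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for (i, j, _, new) in self.merges[:self.n_leaves - k]:
            parent[find(i)] = new
            parent[find(j)] = new
        roots = {}
        out = np.empty(self.n_leaves, int)
        for leaf in range(self.n_leaves):
            r = find(leaf)
            out[leaf] = roots.setdefault(r, len(roots))
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths from the merge heights."""
        labels = self.leaf_labels or tuple(str(i) for i in range(self.n_leaves))
        node_repr = {i: labels[i] for i in range(self.n_leaves)}
        node_h = {i: 0.0 for i in range(self.n_leaves)}
        for (i, j, h, new) in self.merges:
            bi = max(h - node_h[i], 0.0)
            bj = max(h - node_h[j], 0.0)
            node_repr[new] = f"({node_repr[i]}:{bi:.6g},{node_repr[j]}:{bj:.6g})"
            node_h[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return node_repr[root] + ";"


def ward_cluster(points: np.ndarray,
                 leaf_labels: tuple[str, ...] | None = None) -> Dendrogram:
    """Ward agglomerative clustering on Euclidean coordinates.

    Merge cost is the increase in total within-cluster sum of squared
    distances to centroids, ``n_i n_j/(n_i+n_j) ||c_i - c_j||^2``,
    maintained by the Lance-Williams recurrence; ties are broken by the
    lowest (i, j) node-index pair.  Heights are the incremental sums, so
    they total the sum of squares about the grand centroid.
    """
    x = np.asarray(points, float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    # active clusters: id -> (size, index into cost table)
    ids = list(range(n))
    sizes = {i: 1 for i in ids}
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    cost = {}
    for i in range(n):
        for j in range(i + 1, n):
            cost[(i, j)] = 0.5 * d2[i, j]
    merges = []
    next_id = n
    active = set(ids)
    for _ in range(n - 1):
        (i, j) = min(cost, key=lambda ij: (cost[ij], ij))
        h = cost[(i, j)]
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        merges.append((i, j, float(h), new))
        active.discard(i)
        active.discard(j)
        for k in list(active):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            nk = sizes[k]
            dik, djk = cost.pop(a), cost.pop(b)
            cost[(k, new)] = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (
                ni + nj + nk)
        for key in [key for key in cost if i in key or j in key]:
            del cost[key]
        sizes[new] = ni + nj
        active.add(new)
    return Dendrogram(merges=merges, n_leaves=n, leaf_labels=leaf_labels)


def natural_division(dendrogram: Dendrogram, lookback: int = 10) -> dict:
    """Choose the cluster count at the largest height jump.

    Over the last ``lookback`` merges, the ratio ``h_i / h_{i-1}`` is
    computed; the cut is placed below the merge with the maximal ratio,
    giving ``k = n_merges - i + 1`` clusters.  The full ratio table is
    returned so a user can override k.
    """
    h = dendrogram.heights
    if dendrogram.n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    if np.allclose(h, h[0]):
        log.warning("natural_division: all merge heights equal; k=1")
        return {"k": 1, "assignments": np.zeros(dendrogram.n_leaves, int),
                "ratios": pd.DataFrame(), "flag": "all heights equal"}
    m = h.size
    start = max(1, m - lookback)
    rows = []
    for i in range(start, m):
        prev = h[i - 1]
        ratio = h[i] / prev if prev > 0 else np.inf
        rows.append({"merge_index": i, "height": h[i],
                     "prev_height": prev, "ratio": ratio,
                     "k_if_cut_here": m - i + 1})
    ratios = pd.DataFrame(rows)
    best = ratios.loc[ratios["ratio"].idxmax()]
    k = int(best["k_if_cut_here"])
    return {"k": k, "assignments": dendrogram.cut(k), "ratios": ratios,
            "flag": None}
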