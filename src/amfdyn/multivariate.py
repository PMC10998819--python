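"""Distance matrices and permutation-based community statistics.

PERMANOVA partitions the sum of squares of a (Gower-centered) distance
matrix among design factors sequentially (Type-I, adonis2-style) and
tests each term's pseudo-F by whole-row label permutation; an
exhaustive mode enumerates every permutation on small designs.  The
Mantel test correlates two distance matrices' lower triangles
(Spearman by default) with joint row/column permutation.  RDA regresses
column-centered compositions on z-standardized environmental variables
and eigen-decomposes the fitted values; the model F is permutation
tested and a per-OTU table reports rank correlations of each OTU with
each variable.  NMDS is Kruskal stress-1 minimization (SMACOF
majorization with monotone regression), best of seeded restarts.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .io import DesignError, TableFormatError

MAX_EXHAUSTIVE_N = 9


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = self.values
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise TableFormatError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise TableFormatError("distance matrix not symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise TableFormatError("distance matrix diagonal not zero")
        if (d < 0).any():
            raise TableFormatError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclasses.dataclass(frozen=True)
class PermutationTestResult:
    name: str
    statistic: float
    p: float
    n_permutations: int
    seed: int | None
    r2: float | None = None
    df: tuple[int, int] | None = None


def distance_matrix(data: pd.DataFrame, metric: str = "bray-curtis") -> DistanceMatrix:
    """Bray-Curtis on compositions, or Euclidean on z-scored columns."""
    if data.shape[0] < 2:
        raise DesignError("need at least 2 samples")
    x = data.to_numpy(dtype=float)
    if metric == "bray-curtis":
        if (x < 0).any():
            raise TableFormatError("Bray-Curtis requires non-negative input")
        d = squareform(pdist(x, metric="braycurtis"))
    elif metric == "euclidean":
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = data.columns[sd == 0].tolist()
            raise TableFormatError(f"zero-variance column(s) for standardization: {bad}")
        z = (x - x.mean(axis=0)) / sd
        d = squareform(pdist(z, metric="euclidean"))
    else:
        raise DesignError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(data.index), values=d, metric=metric)


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def _design_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-code a factor term; 'a:b' denotes an interaction."""
    parts = term.split(":")
    for p in parts:
        if p not in metadata.columns:
            raise DesignError(f"term {term!r}: column {p!r} not in metadata")
    combined = metadata[parts[0]].astype(str)
    for p in parts[1:]:
        combined = combined + "\x00" + metadata[p].astype(str)
    return pd.get_dummies(combined).to_numpy(dtype=float)


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str] | str,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    strata: str | None = None,
) -> list[PermutationTestResult]:
    """Sequential (Type-I) PERMANOVA over one or more factor terms.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under whole-row label
    permutation (within ``strata`` blocks if given).  ``exhaustive``
    enumerates all n! permutations (n <= 9) and then p is the exact
    fraction of arrangements, the identity included.
    """
    if isinstance(terms, str):
        terms = [terms]
    meta = metadata.loc[dm.ids]
    g = _gower_center(dm.values)
    n = dm.n
    ss_total = float(np.trace(g))
    # cumulative hat matrices: intercept, then one per added term
    x = np.ones((n, 1))
    hats = []
    dfs = []
    prev_rank = 1
    for term in terms:
        x = np.hstack([x, _design_columns(meta, term)])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        hats.append(h)
        dfs.append(rank - prev_rank)
        prev_rank = rank
    h_full = hats[-1]
    df_res = n - prev_rank
    if df_res <= 0:
        raise DesignError("zero residual degrees of freedom")
    if any(df == 0 for df in dfs):
        bad = [t for t, df in zip(terms, dfs) if df == 0]
        raise DesignError(f"term(s) confounded with earlier terms: {bad}")

    h_prev = np.full((n, n), 1.0 / n)  # intercept hat
    deltas = []
    for h in hats:
        deltas.append(h - h_prev)
        h_prev = h
    resid_proj = np.eye(n) - h_full

    def stats_for(gperm: np.ndarray) -> np.ndarray:
        ss_res = float(np.einsum("ij,ij->", resid_proj, gperm))
        out = np.empty(len(terms))
        for t, (delta, df) in enumerate(zip(deltas, dfs)):
            ss_t = float(np.einsum("ij,ij->", delta, gperm))
            out[t] = (ss_t / df) / (ss_res / df_res)
        return out

    f_obs = stats_for(g)
    ss_terms = [float(np.einsum("ij,ij->", delta, g)) for delta in deltas]
    tie_tol = 1e-9 * np.maximum(1.0, np.abs(f_obs))  # relative tie tolerance

    if exhaustive:
        if n > MAX_EXHAUSTIVE_N:
            raise DesignError(f"exhaustive enumeration limited to n <= {MAX_EXHAUSTIVE_N}")
        count = np.zeros(len(terms))
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            f_perm = stats_for(g[np.ix_(idx, idx)])
            count += f_perm >= f_obs - tie_tol
            total += 1
        pvals = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = _permute_indices(rng, n, meta, strata)
            f_perm = stats_for(g[np.ix_(idx, idx)])
            count += f_perm >= f_obs - tie_tol
        pvals = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm
    return [
        PermutationTestResult(
            name=f"PERMANOVA[{term}]",
            statistic=float(f_obs[t]),
            p=float(pvals[t]),
            n_permutations=n_used,
            seed=seed,
            r2=ss_terms[t] / ss_total if ss_total > 0 else np.nan,
            df=(dfs[t], df_res),
        )
        for t, term in enumerate(terms)
    ]


def _permute_indices(
    rng: np.random.Generator, n: int, meta: pd.DataFrame, strata: str | None
) -> np.ndarray:
    if strata is None:
        return rng.permutation(n)
    idx = np.arange(n)
    out = idx.copy()
    for _, block in pd.Series(idx, index=meta.index).groupby(meta[strata], observed=True):
        vals = block.to_numpy()
        out[vals] = rng.permutation(vals)
    return out


def pairwise_permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    n_perm: int = 999,
    seed: int | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """PERMANOVA restricted to each level pair of ``factor``.

    Reports raw and adjusted p ("bonferroni", "bh", or "none").
    """
    meta = metadata.loc[dm.ids]
    levels = sorted(meta[factor].astype(str).unique())
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} has fewer than 2 levels")
    frame = dm.to_frame()
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(levels, 2)):
        keep = meta.index[meta[factor].astype(str).isin([a, b])]
        if (meta.loc[keep, factor].astype(str).value_counts() < 2).any():
            raise DesignError(f"pair ({a}, {b}) has a level with < 2 samples")
        sub = DistanceMatrix(list(keep), frame.loc[keep, keep].to_numpy(), dm.metric)
        pair_seed = None if seed is None else seed + i
        res = permanova(sub, meta.loc[keep], [factor], n_perm=n_perm, seed=pair_seed)[0]
        rows.append(
            {"level_1": a, "level_2": b, "pseudo_F": res.statistic,
             "R2": res.r2, "p": res.p}
        )
    out = pd.DataFrame(rows)
    if adjust == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p"] * len(out))
    elif adjust == "bh":
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    elif adjust == "none":
        out["p_adjusted"] = out["p"]
    else:
        raise DesignError(f"unknown adjustment {adjust!r}")
    return out


# ---------------------------------------------------------------------------
# Mantel


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    alternative: str = "greater",
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices.

    The correlation (Spearman by default) is computed over the lower
    triangles; p comes from jointly permuting one matrix's rows and
    columns.  One-sided ("greater") by default, as conventional for
    ecological distance-distance association.
    """
    if d1.ids != d2.ids:
        raise DesignError("distance matrices must share ids and order")
    n = d1.n
    if n < 4:
        raise DesignError("Mantel test needs n >= 4")
    tri = np.tril_indices(n, k=-1)
    x = d1.values[tri]
    y0 = d2.values[tri]
    if np.ptp(x) == 0 or np.ptp(y0) == 0:
        raise DesignError("constant lower triangle; correlation undefined")

    if method == "spearman":
        x_r = st.rankdata(x)
    elif method == "pearson":
        x_r = x
    else:
        raise DesignError(f"unknown method {method!r}")

    def corr(perm: np.ndarray) -> float:
        y = d2.values[np.ix_(perm, perm)][tri]
        y_r = st.rankdata(y) if method == "spearman" else y
        return float(np.corrcoef(x_r, y_r)[0, 1])

    r_obs = corr(np.arange(n))

    def extreme(r: float) -> bool:
        if alternative == "greater":
            return r >= r_obs - 1e-12
        if alternative == "less":
            return r <= r_obs + 1e-12
        return abs(r) >= abs(r_obs) - 1e-12

    if exhaustive:
        if n > MAX_EXHAUSTIVE_N:
            raise DesignError(f"exhaustive enumeration limited to n <= {MAX_EXHAUSTIVE_N}")
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            hits += extreme(corr(np.asarray(perm)))
            total += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            hits += extreme(corr(rng.permutation(n)))
        p = (1.0 + hits) / (1.0 + n_perm)
        n_used = n_perm
    return PermutationTestResult(
        name=f"Mantel[{method}]", statistic=r_obs, p=p, n_permutations=n_used, seed=seed
    )


# ---------------------------------------------------------------------------
# RDA


@dataclasses.dataclass(frozen=True)
class RdaResult:
    axis_proportions: np.ndarray  # constrained axes, share of total inertia
    unconstrained_proportions: np.ndarray
    sample_scores: pd.DataFrame
    otu_scores: pd.DataFrame
    env_scores: pd.DataFrame
    model: PermutationTestResult
    otu_env_correlations: pd.DataFrame

    @property
    def constrained_proportion(self) -> float:
        return float(self.axis_proportions.sum())

    @property
    def first_two_axes(self) -> float:
        return float(self.axis_proportions[: 2].sum())


def rda(
    community: pd.DataFrame,
    environment: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    corr_threshold: float = 0.5,
    adjust_correlations: bool = False,
) -> RdaResult:
    """Redundancy analysis of compositions on environmental variables.

    Community columns are centered, environment columns z-standardized;
    constrained axes come from the SVD of the fitted values of the
    multivariate regression.  The overall model F is tested by
    permuting rows.  The per-OTU table holds the Spearman correlation
    of each OTU with each variable, a permutation p (sharing the model
    permutations), and a flag at |r| >= ``corr_threshold``.
    """
    if not community.index.equals(environment.index):
        environment = environment.loc[community.index]
    n, m = community.shape
    q = environment.shape[1]
    if n <= q + 1:
        raise DesignError("need n samples > n environment variables + 1")
    y = community.to_numpy(dtype=float)
    y = y - y.mean(axis=0)
    xe = environment.to_numpy(dtype=float)
    sd = xe.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = environment.columns[sd == 0].tolist()
        raise TableFormatError(f"zero-variance environment column(s): {bad}")
    x = (xe - xe.mean(axis=0)) / sd
    if np.linalg.cond(x) > 1e8:
        raise DesignError("environment columns are collinear")

    qx, _ = np.linalg.qr(x)
    yhat = qx @ (qx.T @ y)
    resid = y - yhat
    ss_total = float((y**2).sum())
    ss_fit = float((yhat**2).sum())
    ss_res = max(ss_total - ss_fit, 0.0)
    if ss_res <= 1e-12 * ss_total:  # saturated fit (noiseless construction)
        f_obs = np.inf
    else:
        f_obs = (ss_fit / q) / (ss_res / (n - q - 1))

    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    n_axes = min(q, int((s > 1e-10 * max(s.max(), 1e-30)).sum()))
    axis_props = (s[:n_axes] ** 2) / ss_total if ss_total > 0 else np.zeros(n_axes)
    _, s_res, _ = np.linalg.svd(resid, full_matrices=False)
    uncon = (s_res[s_res > 1e-12] ** 2) / ss_total if ss_total > 0 else np.array([])

    sample_scores = pd.DataFrame(
        u[:, :n_axes] * s[:n_axes], index=community.index,
        columns=[f"RDA{i + 1}" for i in range(n_axes)],
    )
    otu_scores = pd.DataFrame(
        vt[:n_axes].T, index=community.columns,
        columns=[f"RDA{i + 1}" for i in range(n_axes)],
    )
    env_scores = pd.DataFrame(
        x.T @ u[:, :n_axes], index=environment.columns,
        columns=[f"RDA{i + 1}" for i in range(n_axes)],
    )

    # permutation test of the model F (rows of Y permuted) plus
    # per-OTU Spearman correlation permutation p, sharing the stream
    rng = np.random.default_rng(seed)
    y_ranks = st.rankdata(community.to_numpy(dtype=float), axis=0)
    y_ranks = (y_ranks - y_ranks.mean(axis=0)) / np.maximum(y_ranks.std(axis=0), 1e-30)
    e_ranks = st.rankdata(xe, axis=0)
    e_ranks = (e_ranks - e_ranks.mean(axis=0)) / np.maximum(e_ranks.std(axis=0), 1e-30)
    r_obs = (y_ranks.T @ e_ranks) / n  # OTU x env Spearman matrix
    hits_f = 0
    hits_r = np.zeros_like(r_obs)
    f_thresh = np.inf if np.isinf(f_obs) else f_obs - 1e-9 * max(1.0, abs(f_obs))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        yp = y[idx]
        yhat_p = qx @ (qx.T @ yp)
        ss_fit_p = float((yhat_p**2).sum())
        ss_res_p = max(ss_total - ss_fit_p, 0.0)
        f_p = np.inf if ss_res_p <= 1e-12 * ss_total else (ss_fit_p / q) / (ss_res_p / (n - q - 1))
        hits_f += f_p >= f_thresh
        r_p = (y_ranks[idx].T @ e_ranks) / n
        hits_r += np.abs(r_p) >= np.abs(r_obs) - 1e-12
    p_model = (1.0 + hits_f) / (1.0 + n_perm)
    p_r = (1.0 + hits_r) / (1.0 + n_perm)
    rows = []
    for i, otu in enumerate(community.columns):
        for j, var in enumerate(environment.columns):
            rows.append(
                {"otu_id": otu, "variable": var,
                 "spearman_r": float(r_obs[i, j]), "p": float(p_r[i, j])}
            )
    corr_table = pd.DataFrame(rows)
    if adjust_correlations:
        corr_table["p_adjusted"] = multipletests(corr_table["p"], method="fdr_bh")[1]
    corr_table["strong"] = corr_table["spearman_r"].abs() >= corr_threshold
    model = PermutationTestResult(
        name="RDA[model]", statistic=float(f_obs), p=float(p_model),
        n_permutations=n_perm, seed=seed, r2=ss_fit / ss_total if ss_total else np.nan,
        df=(q, n - q - 1),
    )
    return RdaResult(
        axis_proportions=axis_props,
        unconstrained_proportions=uncon,
        sample_scores=sample_scores,
        otu_scores=otu_scores,
        env_scores=env_scores,
        model=model,
        otu_env_correlations=corr_table,
    )


# ---------------------------------------------------------------------------
# NMDS


@dataclasses.dataclass(frozen=True)
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    restarts: int = 20,
    tol: float = 1e-6,
    seed: int | None = None,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric MDS, best of ``restarts`` seeded SMACOF runs."""
    if dm.n < dims + 1:
        raise DesignError(f"NMDS needs at least dims + 1 = {dims + 1} samples")
    common = dict(
        n_components=dims, n_init=restarts, random_state=seed,
        max_iter=max_iter, eps=tol, normalized_stress=True,
    )
    try:
        model = MDS(metric="precomputed", metric_mds=False, init="random", **common)
    except TypeError:  # older sklearn API
        model = MDS(metric=False, dissimilarity="precomputed", **common)
    coords = model.fit_transform(dm.values)
    converged = model.n_iter_ < max_iter
    return NmdsResult(
        coordinates=pd.DataFrame(
            coords, index=dm.ids, columns=[f"NMDS{i + 1}" for i in range(dims)]
        ),
        stress=float(model.stress_),
        n_restarts=restarts,
        converged=bool(converged),
    )
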