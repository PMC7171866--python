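"""Spatial structure: geographic distances, Mantel tests and correlograms,
PERMANOVA, variance partitioning and local contributions to beta diversity.

Permutation tests throughout permute sample identities (joint rows/columns
of a distance matrix) and use the add-one rule, p = (hits + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio.stats.ordination import pcoa

from ._utils import holm_progressive
from .distances import DistanceMatrix
from .table import OtuTable, SampleMetadata

EARTH_RADIUS_KM = 6371.0


def haversine_distances(meta: SampleMetadata) -> DistanceMatrix:
    """Great-circle distances between stations in km (spherical Earth)."""
    lat = np.radians(meta.data["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta.data["longitude"].to_numpy(dtype=float))
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise ValueError("missing coordinates")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(meta.sample_ids, d, "dissimilarity", "km")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _condensed(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "pearson",
           n_perm: int = 999, seed: int | None = None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a one-sided
    permutation test (H1: positive association)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = d2.reorder(d1.labels)
    x = _condensed(d1.values)
    y2 = d2.values
    y = _condensed(y2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix; correlation undefined")
    if method == "spearman":
        x = rankdata(x)
        transform = lambda v: rankdata(v)
    elif method == "pearson":
        transform = lambda v: v
    else:
        raise ValueError(f"unknown method {method!r}")

    def corr(v):
        return float(np.corrcoef(x, transform(v))[0, 1])

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    n = d1.n
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = corr(_condensed(y2[np.ix_(p, p)]))
        if r >= r_obs:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


def membership_correlogram(d_struct: DistanceMatrix, d_resp: DistanceMatrix,
                           class_width: float | None = None,
                           breaks: np.ndarray | None = None,
                           n_perm: int = 999, seed: int | None = None
                           ) -> pd.DataFrame:
    """Mantel correlogram over distance classes of ``d_struct``.

    For each class, the statistic is the negative Pearson correlation between
    class membership (1 for pairs whose structural distance falls in the
    class) and the response distances, so positive values mean pairs in the
    class are more similar than average.  Two-sided permutation p-values are
    corrected progressively (Holm over classes 1..k).  Classes with fewer
    than two pairs or constant membership are reported as NaN.
    """
    d_resp = d_resp.reorder(d_struct.labels)
    s = _condensed(d_struct.values)
    r = d_resp.values
    y = _condensed(r)
    if breaks is None:
        if class_width is None or class_width <= 0:
            raise ValueError("give class_width or explicit breaks")
        upper = max(s.max(), class_width)
        breaks = np.arange(0.0, upper + class_width, class_width)
        if breaks[-1] < upper:
            breaks = np.append(breaks, upper)
    breaks = np.asarray(breaks, dtype=float)
    # class c: breaks[c] <= d < breaks[c+1]; the last class includes its upper bound
    klass = np.clip(np.searchsorted(breaks, s, side="right") - 1, 0, len(breaks) - 2)
    rng = np.random.default_rng(seed)
    n = d_struct.n
    perms = [rng.permutation(n) for _ in range(n_perm)]
    y_perms = np.array([_condensed(r[np.ix_(p, p)]) for p in perms])
    rows = []
    for c in range(len(breaks) - 1):
        member = (klass == c).astype(float)
        n_pairs = int(member.sum())
        row = {"lower": breaks[c], "upper": breaks[c + 1], "n_pairs": n_pairs,
               "mantel_r": np.nan, "p_raw": np.nan}
        if n_pairs >= 2 and 0 < n_pairs < member.size and np.ptp(y) > 0:
            r_obs = -float(np.corrcoef(member, y)[0, 1])
            mz = (member - member.mean()) / member.std()
            yz = (y_perms - y_perms.mean(axis=1, keepdims=True))
            sd = y_perms.std(axis=1)
            r_perm = -(yz @ mz) / (member.size * sd)
            hits = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
            row["mantel_r"] = r_obs
            row["p_raw"] = (hits + 1) / (n_perm + 1)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_corrected"] = holm_progressive(out["p_raw"])
    return out


def mantel_correlogram(d_geo: DistanceMatrix, d_beta: DistanceMatrix,
                       class_width: float = 1000.0, n_perm: int = 999,
                       seed: int | None = None) -> pd.DataFrame:
    """Distance-decay correlogram: geographic distance classes (km) vs beta
    diversity.  The conventional class width for global ocean transects is
    1000 km."""
    return membership_correlogram(d_geo, d_beta, class_width=class_width,
                                  n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PERMANOVA (ADONIS-style, sequential SS)
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _design_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    col = meta[term]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"term {term!r} has a single level")
        dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
        return dummies
    x = col.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(f"missing values in term {term!r}")
    return (x - x.mean())[:, None]


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(dist: DistanceMatrix, meta: SampleMetadata | pd.DataFrame,
              terms: list[str], n_perm: int = 999,
              seed: int | None = None) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Partitions the total sum of squares of the Gower-centred matrix among
    ``terms`` sequentially (Type I, in the order given), so term order is
    part of the model specification.  p-values come from free permutation of
    sample identities.  Returns a table with df, SS, pseudo-F, R2 and p per
    term plus residual and total rows.
    """
    df_meta = meta.data if isinstance(meta, SampleMetadata) else meta
    df_meta = df_meta.loc[dist.labels]
    n = dist.n
    g = _gower_center(dist.values)
    ones = np.ones((n, 1))
    blocks = [ones]
    dfs = []
    rank_prev = 1
    for term in terms:
        blocks.append(_design_columns(df_meta, term))
        x = np.hstack(blocks)
        rank = np.linalg.matrix_rank(x)
        if rank <= rank_prev:
            raise ValueError(f"term {term!r} is collinear with preceding terms")
        dfs.append(rank - rank_prev)
        rank_prev = rank
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    def seq_ss(gm: np.ndarray) -> tuple[np.ndarray, float, float]:
        total = float(np.trace(gm))
        fitted_prev = 0.0
        ss = np.empty(len(terms))
        for t in range(len(terms)):
            h = _hat(np.hstack(blocks[: t + 2]))
            fitted = float(np.trace(h @ gm))
            ss[t] = fitted - fitted_prev
            fitted_prev = fitted
        return ss, total - fitted_prev, total

    ss_terms, ss_resid, ss_total = seq_ss(g)
    dfs_arr = np.array(dfs, dtype=float)
    with np.errstate(divide="ignore"):
        f_obs = (ss_terms / dfs_arr) / (ss_resid / df_resid)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        ssp, ssr, _ = seq_ss(g[np.ix_(p, p)])
        with np.errstate(divide="ignore", invalid="ignore"):
            fp = (ssp / dfs_arr) / (ssr / df_resid)
        hits += fp >= f_obs - 1e-12
    pvals = (hits + 1) / (n_perm + 1)
    rows = []
    for t, term in enumerate(terms):
        rows.append({"term": term, "df": dfs[t], "ss": ss_terms[t],
                     "pseudo_f": f_obs[t], "r2": ss_terms[t] / ss_total,
                     "p": pvals[t]})
    rows.append({"term": "Residual", "df": df_resid, "ss": ss_resid,
                 "pseudo_f": np.nan, "r2": ss_resid / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total,
                 "pseudo_f": np.nan, "r2": 1.0, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    """Adjusted-R2 partition of community variance between two predictor sets.

    Fractions follow the usual inclusion-exclusion decomposition; adjusted
    R2 can be slightly negative, in which case fractions are reported as-is.
    """

    pure_env: float
    pure_geo: float
    shared: float
    unexplained: float
    r2_env: float
    r2_geo: float
    r2_both: float

    def as_dict(self) -> dict[str, float]:
        return {"pure_env": self.pure_env, "pure_geo": self.pure_geo,
                "shared": self.shared, "unexplained": self.unexplained}


def _predictor_matrix(meta: pd.DataFrame, names: list[str]) -> np.ndarray:
    return np.hstack([_design_columns(meta, v) for v in names])


def _adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    n = y.shape[0]
    p = np.linalg.matrix_rank(x)
    if p >= n - 1:
        raise ValueError("more predictors than samples - 1")
    xi = np.hstack([np.ones((n, 1)), x])
    beta, *_ = np.linalg.lstsq(xi, y, rcond=None)
    resid = y - xi @ beta
    yc = y - y.mean(axis=0)
    r2 = 1.0 - (resid ** 2).sum() / (yc ** 2).sum()
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition(dist: DistanceMatrix, meta: SampleMetadata | pd.DataFrame,
                       env_vars: list[str], geo_vars: list[str],
                       n_axes: int | None = None) -> VariancePartition:
    """Partition community variance into pure environmental, pure geographic,
    shared and unexplained fractions.

    The dissimilarity matrix is embedded by principal coordinates (axes with
    positive eigenvalues, up to ``n_axes``), then each predictor set's
    explanatory power is the Ezekiel-adjusted redundancy-analysis R2.
    """
    if not env_vars or not geo_vars:
        raise ValueError("both variable sets must be non-empty")
    df_meta = (meta.data if isinstance(meta, SampleMetadata) else meta).loc[dist.labels]
    ord_res = pcoa(dist.to_skbio(), warn_neg_eigval=False)
    eig = ord_res.eigvals.to_numpy()
    keep = np.flatnonzero(eig > 1e-10)
    if n_axes is not None:
        keep = keep[:n_axes]
    y = ord_res.samples.to_numpy()[:, keep]
    x_env = _predictor_matrix(df_meta, env_vars)
    x_geo = _predictor_matrix(df_meta, geo_vars)
    r2_env = _adjusted_r2(y, x_env)
    r2_geo = _adjusted_r2(y, x_geo)
    r2_both = _adjusted_r2(y, np.hstack([x_env, x_geo]))
    pure_env = r2_both - r2_geo
    pure_geo = r2_both - r2_env
    shared = r2_env + r2_geo - r2_both
    return VariancePartition(pure_env, pure_geo, shared, 1.0 - r2_both,
                             r2_env, r2_geo, r2_both)


# ---------------------------------------------------------------------------
# LCBD
# ---------------------------------------------------------------------------

@dataclass
class LcbdResult:
    """Per-sample share of the total community sum of squares."""

    values: pd.Series
    p_values: pd.Series
    ss_total: float


def lcbd(table: OtuTable, transform: str = "hellinger", n_perm: int = 999,
         seed: int | None = None) -> LcbdResult:
    """Local contributions to beta diversity.

    Rows are Hellinger-transformed (square root of relative abundances),
    columns centred; LCBD_i is sample i's fraction of the total sum of
    squared deviations, so the values always sum to one.  Significance is
    one-sided, permuting each species' values independently across samples.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    if transform == "hellinger":
        y = np.sqrt(table.relative_abundances())
    elif transform == "none":
        y = table.counts.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    def lcbd_of(mat: np.ndarray) -> tuple[np.ndarray, float]:
        dev = mat - mat.mean(axis=0)
        ss_i = (dev ** 2).sum(axis=1)
        tot = ss_i.sum()
        return ss_i / tot, tot

    values, ss_total = lcbd_of(y)
    if ss_total == 0:
        raise ValueError("all samples identical; total sum of squares is zero")
    rng = np.random.default_rng(seed)
    hits = np.zeros(table.n_samples)
    n = table.n_samples
    for _ in range(n_perm):
        perm = np.empty_like(y)
        for j in range(y.shape[1]):
            perm[:, j] = y[rng.permutation(n), j]
        v, tot = lcbd_of(perm)
        if tot == 0:
            v = np.full(n, 1.0 / n)
        hits += v >= values - 1e-12
    p = (hits + 1) / (n_perm + 1)
    ids = pd.Index(table.sample_ids, name="sample")
    return LcbdResult(pd.Series(values, index=ids, name="lcbd"),
                      pd.Series(p, index=ids, name="p"), float(ss_total))
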