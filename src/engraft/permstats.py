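"""Permutation-based multivariate inference on distance matrices.

PERMANOVA partitions the sums of squares of a Gower-centered distance
matrix against a model matrix of host covariates (McArdle–Anderson trace
formulation), with marginal (each term given all others) or sequential
term assessment and permutation p-values.  PERMDISP tests homogeneity of
group dispersions via distances to group centroids in principal-coordinate
space with the standard negative-eigenvalue correction.  PCoA is classical
scaling of the same centered matrix.  Kruskal–Wallis (tie-corrected) wraps
the standard rank test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import DistanceMatrix

logger = logging.getLogger("engraft")

_EIG_TOL = 1e-9


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    table: pd.DataFrame           # index: term (+ Residual, Total); df, SS, F, R2, p
    n_permutations: int | str
    seed: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index(names="term")

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def r_squared(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])


@dataclass
class PermdispResult:
    group_means: pd.Series        # mean distance-to-centroid per group
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = self.group_means.rename("mean_dist_to_centroid").reset_index(names="group")
        df["F"] = self.f_statistic
        df["p"] = self.p_value
        return df


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame     # samples x retained axes (positive eigenvalues)
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray


# ---------------------------------------------------------------------------
# core linear algebra
# ---------------------------------------------------------------------------


def gower_center(d_values: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 C (D*D) C."""
    a = -0.5 * d_values ** 2
    n = a.shape[0]
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    return c @ a @ c


def _hat(x: np.ndarray) -> np.ndarray:
    """Projection onto the column space of x (pinv handles rank deficiency)."""
    return x @ np.linalg.pinv(x)


def _term_matrix(col: pd.Series, term: str) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        v = col.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"term {term!r} is constant")
        return v.reshape(-1, 1)
    levels = pd.unique(col.astype(str))
    if len(levels) < 2:
        raise ValueError(f"term {term!r} has a single level")
    dummies = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
    return dummies.to_numpy()


def _design(metadata: pd.DataFrame, sample_ids: list[str], terms: list[str]):
    meta = metadata.loc[sample_ids]
    blocks = {}
    for term in terms:
        if term not in meta.columns:
            raise KeyError(f"metadata has no column {term!r}")
        col = meta[term]
        if col.isna().any():
            bad = meta.loc[col.isna(), "sample_id"].tolist() if "sample_id" in meta else list(col.index[col.isna()])
            raise ValueError(f"term {term!r} has missing values for samples {bad}")
        blocks[term] = _term_matrix(col, term)
    return blocks


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def pcoa(d: DistanceMatrix, k: int | None = None) -> PcoaResult:
    """Principal coordinates (classical scaling) of a distance matrix.

    Axes are ordered by eigenvalue; negative eigenvalues are reported but
    their axes are dropped from the coordinates.
    """
    n = len(d.sample_ids)
    if k is not None and k > n - 1:
        raise ValueError(f"k={k} exceeds n-1={n - 1}")
    g = gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > _EIG_TOL * max(1.0, abs(eigvals[0]) if eigvals.size else 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if k is not None:
        coords = coords[:, :k]
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    total = eigvals[pos].sum()
    prop = eigvals[pos] / total if total > 0 else np.zeros(pos.sum())
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.sample_ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _permutation_iter(n: int, n_perm, rng: np.random.Generator):
    if n_perm == "exact":
        return (np.array(p) for p in itertools.permutations(range(n)))
    return (rng.permutation(n) for _ in range(int(n_perm)))


def permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: list[str] | str,
    *,
    mode: str = "marginal",
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with permutation p-values.

    ``mode='marginal'`` assesses each term given all others (Type-III-like);
    ``mode='sequential'`` adds terms in order (Type-I), in which case the
    term R² values plus the residual sum to 1.  ``n_perm`` may be the string
    ``'exact'`` to enumerate all n! sample permutations (small n only); the
    Monte Carlo p-value uses the (1+b)/(1+m) estimator, the exact mode the
    enumeration fraction (identity included).

    ``metadata`` must be indexed by (or contain) ``sample_id`` covering the
    distance matrix's samples.
    """
    if isinstance(terms, str):
        terms = [terms]
    if mode not in ("marginal", "sequential"):
        raise ValueError("mode must be 'marginal' or 'sequential'")
    # canonical sample order makes permutation p-values invariant to the
    # caller's row ordering, not just the observed statistics
    d = d.submatrix(sorted(d.sample_ids))
    meta = metadata.set_index("sample_id", drop=False) if metadata.index.name != "sample_id" else metadata
    blocks = _design(meta, d.sample_ids, terms)
    n = len(d.sample_ids)
    ones = np.ones((n, 1))

    g = gower_center(d.values)
    ss_total = np.trace(g)

    x_full = np.hstack([ones] + [blocks[t] for t in terms])
    h_full = _hat(x_full)
    df_model = int(np.round(np.linalg.matrix_rank(x_full))) - 1
    df_terms = {}
    h_lower = {}   # projection whose trace is subtracted for the term's SS
    h_upper = {}   # projection whose trace is added (full model in marginal mode)
    if mode == "marginal":
        for t in terms:
            x_red = np.hstack([ones] + [blocks[u] for u in terms if u != t])
            h_lower[t] = _hat(x_red)
            h_upper[t] = h_full
            df_terms[t] = np.linalg.matrix_rank(x_full) - np.linalg.matrix_rank(x_red)
    else:
        prev = ones
        prev_hat = _hat(prev)
        prev_rank = 1
        for t in terms:
            h_lower[t] = prev_hat
            prev = np.hstack([prev, blocks[t]])
            prev_hat = _hat(prev)
            rank = np.linalg.matrix_rank(prev)
            h_upper[t] = prev_hat
            df_terms[t] = rank - prev_rank
            prev_rank = rank
    for t in terms:
        if df_terms[t] == 0:
            raise ValueError(f"term {t!r} is aliased with the other terms")
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual degrees of freedom")

    def _stats(g_mat: np.ndarray):
        tr_full = float(np.sum(h_full * g_mat))
        ss_res = np.trace(g_mat) - tr_full
        out = {}
        for t in terms:
            ss_t = float(np.sum(h_upper[t] * g_mat)) - float(np.sum(h_lower[t] * g_mat))
            f_t = (ss_t / df_terms[t]) / (ss_res / df_res)
            out[t] = (ss_t, f_t)
        return out, ss_res

    obs, ss_res = _stats(g)

    rng = np.random.default_rng(seed)
    exceed = {t: 0 for t in terms}
    m = 0
    for perm in _permutation_iter(n, n_perm, rng):
        gp = g[np.ix_(perm, perm)]
        perm_stats, _ = _stats(gp)
        for t in terms:
            if perm_stats[t][1] >= obs[t][1] - 1e-12:
                exceed[t] += 1
        m += 1
    if n_perm == "exact":
        pvals = {t: exceed[t] / m for t in terms}
    else:
        pvals = {t: (1 + exceed[t]) / (1 + m) for t in terms}

    rows = []
    for t in terms:
        ss_t, f_t = obs[t]
        rows.append({"term": t, "df": df_terms[t], "SS": ss_t, "F": f_t,
                     "R2": ss_t / ss_total, "p": pvals[t]})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res, "F": np.nan,
                 "R2": ss_res / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "F": np.nan,
                 "R2": 1.0, "p": np.nan})
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed, mode=mode)


def pairwise_permanova(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    *,
    n_perm: int | str = 999,
    seed: int = 0,
    adjust: str = "holm",
) -> pd.DataFrame:
    """One PERMANOVA per pair of factor levels, with adjusted p-values.

    Levels with fewer than 2 samples are skipped with a warning.  ``adjust``
    is ``holm``, ``bh`` or ``none``.
    """
    if adjust not in ("holm", "bh", "none"):
        raise ValueError("adjust must be 'holm', 'bh' or 'none'")
    meta = metadata.set_index("sample_id", drop=False) if metadata.index.name != "sample_id" else metadata
    groups = meta.loc[d.sample_ids, factor].astype(str)
    levels = sorted(groups.unique())
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(levels, 2)):
        ids = [s for s in d.sample_ids if groups[s] in (a, b)]
        n_a, n_b = (groups.loc[ids] == a).sum(), (groups.loc[ids] == b).sum()
        if min(n_a, n_b) < 2:
            logger.warning("pairwise PERMANOVA: skipping %s vs %s (a level has <2 samples)", a, b)
            continue
        res = permanova(d.submatrix(ids), meta.loc[ids], [factor],
                        mode="marginal", n_perm=n_perm, seed=seed + i)
        rows.append({"level_a": a, "level_b": b, "n_a": int(n_a), "n_b": int(n_b),
                     "F": res.table.loc[factor, "F"], "R2": res.r_squared(factor),
                     "p": res.p_value(factor)})
    out = pd.DataFrame(rows)
    if not out.empty:
        if adjust == "none":
            out["p_adjusted"] = out["p"]
        else:
            method = {"holm": "holm", "bh": "fdr_bh"}[adjust]
            out["p_adjusted"] = multipletests(out["p"], method=method)[1]
    return out


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


def _dist_to_centroids(pos: np.ndarray, neg: np.ndarray, labels: np.ndarray) -> np.ndarray:
    z = np.empty(len(labels))
    for lev in np.unique(labels):
        mask = labels == lev
        cp = pos[mask].mean(axis=0)
        cn = neg[mask].mean(axis=0) if neg.size else np.zeros(0)
        d2 = ((pos[mask] - cp) ** 2).sum(axis=1)
        if neg.size:
            d2 = d2 - ((neg[mask] - cn) ** 2).sum(axis=1)
        z[mask] = np.sqrt(np.clip(d2, 0.0, None))
    return z


def permdisp(
    d: DistanceMatrix,
    metadata: pd.DataFrame,
    factor: str,
    *,
    n_perm: int = 999,
    seed: int = 0,
) -> PermdispResult:
    """Homogeneity of multivariate dispersions, permutation-tested.

    Distances to group centroids are computed in full principal-coordinate
    space; axes with negative eigenvalues contribute negatively (imaginary
    part subtraction).  The F statistic is the one-way ANOVA F on those
    distances; p comes from permuting group labels.
    """
    d = d.submatrix(sorted(d.sample_ids))
    meta = metadata.set_index("sample_id", drop=False) if metadata.index.name != "sample_id" else metadata
    labels = meta.loc[d.sample_ids, factor].astype(str).to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups of size 1 are not allowed: {small}")

    g = gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(1.0, abs(eigvals[0]) if eigvals.size else 1.0)
    pos_mask = eigvals > _EIG_TOL * scale
    neg_mask = eigvals < -_EIG_TOL * scale
    pos = eigvecs[:, pos_mask] * np.sqrt(eigvals[pos_mask])
    neg = eigvecs[:, neg_mask] * np.sqrt(-eigvals[neg_mask])

    def _f(lab: np.ndarray) -> float:
        z = _dist_to_centroids(pos, neg, lab)
        groups = [z[lab == lev] for lev in np.unique(lab)]
        grand = z.mean()
        ss_between = sum(len(gz) * (gz.mean() - grand) ** 2 for gz in groups)
        ss_within = sum(((gz - gz.mean()) ** 2).sum() for gz in groups)
        df_b, df_w = len(groups) - 1, len(z) - len(groups)
        if ss_within <= 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = _f(labels)
    z_obs = _dist_to_centroids(pos, neg, labels)
    means = pd.Series(z_obs).groupby(labels).mean()

    rng = np.random.default_rng(seed)
    exceed = sum(_f(rng.permutation(labels)) >= f_obs - 1e-12 for _ in range(n_perm))
    p = (1 + exceed) / (1 + n_perm)
    return PermdispResult(group_means=means, f_statistic=float(f_obs),
                          p_value=float(p), n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    ``groups`` labels each value; requires >=2 groups with >=1 value each.
    When every value is identical the test is degenerate and (H=0, p=1)
    is returned.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    samples = [values[groups == lev] for lev in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
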