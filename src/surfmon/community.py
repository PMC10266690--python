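"""Presence-absence community comparison across survey methods and sites.

Covers the Jaccard-binary dissimilarity, a sequential (Type I)
distance-based PERMANOVA on the model ``detection ~ method + site``, the
companion homogeneity-of-dispersions test on principal-coordinate
distances to group centroids, Venn overlap of species sets, and
incidence-based sample coverage with rarefaction/extrapolation of species
richness (Hill number q = 0).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# community matrix + Jaccard


def build_community_matrix(histories: pd.DataFrame) -> pd.DataFrame:
    """Pivot detection histories to a binary (site, method) x taxon matrix."""
    pres = histories.assign(present=(histories["N"] >= 1).astype(int))
    mat = pres.pivot_table(
        index=["site", "method"], columns="species", values="present", fill_value=0
    )
    return mat.astype(int)


def drop_incomplete_sites(matrix: pd.DataFrame, methods=None) -> pd.DataFrame:
    """Listwise-drop sites missing any method (e.g. a site with no BRUV survey)."""
    methods = set(methods) if methods is not None else set(
        matrix.index.get_level_values("method")
    )
    by_site = matrix.index.to_frame(index=False).groupby("site")["method"].agg(set)
    complete = by_site[by_site.apply(methods.issubset)].index
    return matrix[matrix.index.get_level_values("site").isin(complete)]


def jaccard_binary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard-binary dissimilarity 1 - |shared| / |union|.

    Pairs where both rows are empty are defined as distance 0; such rows
    are flagged with a warning.
    """
    X = matrix.to_numpy() > 0
    if X.shape[0] < 2:
        raise ValueError("need at least two community rows")
    empty = ~X.any(axis=1)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} all-zero community row(s); "
            "their mutual distances are defined as 0"
        )
    d = squareform(pdist(X, metric="jaccard"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential distance-based ANOVA table with permutation p-values."""

    table: pd.DataFrame  # term x (df, SS, R2, pseudo_F, p)
    n_permutations: int
    exact: bool
    seed: int | None


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(design: np.ndarray) -> np.ndarray:
    # SVD-based projector: dummy-coded designs are rank deficient
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    r = u[:, s > s.max() * design.shape[0] * np.finfo(float).eps]
    return r @ r.T


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels))
    out[np.arange(codes.size), codes] = 1.0
    return out


def permanova_sequential(
    dist: pd.DataFrame,
    factors: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = 0,
    exact_limit: int = 10_000,
) -> PermanovaResult:
    """Sequential (Type I) PERMANOVA partitioning a distance matrix.

    ``factors`` holds one categorical column per term, in entry order
    (e.g. method first, then site). Sums of squares use the
    Gower-centered inner-product matrix: SS(term) = tr(H_term G) with hat
    matrices of the sequentially growing design. p-values come from free
    permutation of rows; when the number of row permutations n! does not
    exceed ``exact_limit`` the full enumeration replaces random sampling.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    if d.shape[1] != n or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("dist must be square symmetric with zero diagonal")
    if len(factors) != n:
        raise ValueError("factors must have one row per distance-matrix row")
    terms = list(factors.columns)
    codes = {}
    for t in terms:
        c, levels = pd.factorize(factors[t].to_numpy())
        if len(levels) == n:
            raise ValueError(f"factor {t!r} has one row per level; confounded")
        if len(levels) < 2:
            raise ValueError(f"factor {t!r} has a single level")
        codes[t] = (c, len(levels))

    g = _gower_center(d)
    ss_total = float(np.trace(g))

    # sequentially growing designs: intercept, +term1, +term1+term2, ...
    blocks = [np.ones((n, 1))]
    hats = [_hat(np.hstack(blocks))]
    dfs = []
    for t in terms:
        c, k = codes[t]
        blocks.append(_dummy(c, k))
        design = np.hstack(blocks)
        hats.append(_hat(design))
        dfs.append(np.linalg.matrix_rank(design) - np.linalg.matrix_rank(np.hstack(blocks[:-1])))
    df_resid = n - np.linalg.matrix_rank(np.hstack(blocks))
    if df_resid < 1:
        raise ValueError("model saturates the data; no residual degrees of freedom")

    diffs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]

    def stats_for(gmat: np.ndarray):
        ss_terms = np.array([float(np.sum(h * gmat)) for h in diffs])
        ss_res = float(np.sum(resid_proj * gmat))
        f = (ss_terms / np.array(dfs)) / (ss_res / df_resid)
        return ss_terms, ss_res, f

    ss_terms, ss_res, f_obs = stats_for(g)

    n_fact = math.factorial(n)
    exact = n_fact <= exact_limit
    if exact:
        perms = itertools.permutations(range(n))
        count = np.zeros(len(terms))
        total = 0
        for p in perms:
            idx = np.array(p)
            _, _, f_p = stats_for(g[np.ix_(idx, idx)])
            count += f_p >= f_obs - 1e-12
            total += 1
        p_values = count / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_permutations):
            idx = rng.permutation(n)
            _, _, f_p = stats_for(g[np.ix_(idx, idx)])
            count += f_p >= f_obs - 1e-12
        p_values = (count + 1) / (n_permutations + 1)
        n_used = n_permutations

    rows = []
    for i, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "df": dfs[i],
                "SS": ss_terms[i],
                "R2": ss_terms[i] / ss_total,
                "pseudo_F": f_obs[i],
                "p": p_values[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "SS": ss_res,
            "R2": ss_res / ss_total,
            "pseudo_F": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_used, exact=exact, seed=seed)


# ---------------------------------------------------------------------------
# homogeneity of dispersions


@dataclass
class DispersionResult:
    distances: pd.Series  # per-row distance to its group centroid
    group_means: pd.Series
    f_statistic: float | None
    p_value: float | None


def dispersion_homogeneity(dist: pd.DataFrame, groups) -> DispersionResult:
    """Distances to group centroids in principal-coordinate space + ANOVA.

    The distance matrix is embedded by eigendecomposition of its
    Gower-centered matrix; axes with negative eigenvalues contribute with
    a negative sign to squared distances (the standard imaginary-part
    correction), clipped at zero. Groups with a single member are excluded
    from the F-test with a warning; with fewer than two usable groups only
    the distances are returned.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    groups = pd.Series(np.asarray(groups), index=dist.index, name="group")
    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = np.abs(eigval) > 1e-10 * max(np.abs(eigval).max(), 1.0)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))[None, :]
    pos = eigval > 0

    sq_dist = np.zeros(n)
    for grp in groups.unique():
        members = np.flatnonzero(groups.to_numpy() == grp)
        centroid = coords[members].mean(axis=0)
        delta = coords[members] - centroid
        sq = (delta[:, pos] ** 2).sum(axis=1) - (delta[:, ~pos] ** 2).sum(axis=1)
        sq_dist[members] = np.clip(sq, 0.0, None)
    distances = pd.Series(np.sqrt(sq_dist), index=dist.index, name="dist_to_centroid")

    sizes = groups.value_counts()
    usable = sizes[sizes >= 2].index
    dropped = sorted(set(sizes.index) - set(usable))
    if dropped:
        warnings.warn(f"groups with a single member excluded from dispersion test: {dropped}")
    group_means = distances.groupby(groups).mean()
    if len(usable) < 2:
        return DispersionResult(distances, group_means, None, None)
    arrays = [distances[groups == grp].to_numpy() for grp in usable]
    if np.ptp(np.concatenate(arrays)) < 1e-10:  # degenerate: all dispersions equal
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
    return DispersionResult(distances, group_means, float(f_stat), float(p_val))


# ---------------------------------------------------------------------------
# Venn overlap


def venn_overlap(sets: dict) -> dict:
    """Region counts of the 2- or 3-set partition plus pairwise shared fractions."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_overlap supports exactly 2 or 3 named sets")
    sets = {k: set(v) for k, v in sets.items()}
    regions = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(*(sets[c] for c in names if c not in combo), set())
            regions["&".join(combo)] = len(inside - outside)
    union_all = set.union(*sets.values())
    pairwise = {}
    for a, b in itertools.combinations(names, 2):
        shared = len(sets[a] & sets[b])
        union = len(sets[a] | sets[b])
        pairwise[f"{a}&{b}"] = {
            "shared": shared,
            "union": union,
            "shared_fraction": shared / union if union else float("nan"),
        }
    return {
        "regions": regions,
        "pairwise": pairwise,
        "total_species": len(union_all),
        "set_sizes": {k: len(v) for k, v in sets.items()},
    }


# ---------------------------------------------------------------------------
# incidence-based coverage / rarefaction (Hill q = 0)


@dataclass
class CoverageEstimate:
    method: str
    T: int  # sampling units
    S_obs: int
    Q1: int  # uniques
    Q2: int  # duplicates
    U: int  # total incidences
    coverage: float  # C-hat in [0, 1]


def _incidence_freqs(incidence: pd.DataFrame) -> np.ndarray:
    """Per-species incidence frequencies Y_i over sampling-unit rows."""
    X = (incidence.to_numpy() > 0).astype(int)
    return X.sum(axis=0)


def sample_coverage(incidence: pd.DataFrame, method: str = "") -> CoverageEstimate:
    """Estimated sample coverage of an incidence matrix (units x species).

    C-hat = 1 - (Q1/U) * [(T-1) Q1 / ((T-1) Q1 + 2 Q2)], the fraction of
    the total incidence probability attributable to species already
    discovered. Undefined (NaN) when there are no incidences.
    """
    T = incidence.shape[0]
    if T < 2:
        raise ValueError("need at least 2 sampling units")
    y = _incidence_freqs(incidence)
    y = y[y > 0]
    u = int(y.sum())
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    s_obs = int(len(y))
    if u == 0:
        warnings.warn("no incidences: coverage undefined")
        return CoverageEstimate(method, T, 0, 0, 0, 0, float("nan"))
    if q1 == 0:
        c = 1.0
    else:
        c = 1.0 - (q1 / u) * ((T - 1) * q1 / ((T - 1) * q1 + 2 * q2))
    return CoverageEstimate(method, T, s_obs, q1, q2, u, c)


def chao2_richness(incidence: pd.DataFrame) -> float:
    """Chao2 asymptotic species richness from uniques and duplicates."""
    est = sample_coverage(incidence)
    t, q1, q2 = est.T, est.Q1, est.Q2
    if q2 > 0:
        return est.S_obs + (t - 1) / t * q1**2 / (2 * q2)
    return est.S_obs + (t - 1) / t * q1 * (q1 - 1) / (2 * (q2 + 1))


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_extrapolate_richness(
    incidence: pd.DataFrame, target_units
) -> pd.DataFrame:
    """Expected species richness and coverage at each target number of units.

    Interpolation (t <= T) uses the combinatorial incidence rarefaction
    expectation S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t); extrapolation
    (t > T) the Chao2-type asymptotic form. Coverage at t <= T uses the
    analogous combinatorial estimator; extrapolated coverage approaches 1
    geometrically.
    """
    targets = np.atleast_1d(np.asarray(target_units, dtype=int))
    if (targets < 1).any():
        raise ValueError("target units must be >= 1")
    T = incidence.shape[0]
    y = _incidence_freqs(incidence)
    y = y[y > 0]
    s_obs = len(y)
    u = y.sum()
    q1 = int((y == 1).sum())
    q2 = int((y == 2).sum())
    q0_hat = chao2_richness(incidence) - s_obs
    rows = []
    for t in targets:
        if t <= T:
            with np.errstate(divide="ignore"):
                log_term = _log_choose(T - y, t) - _log_choose(T, t)
            miss = np.where(T - y >= t, np.exp(log_term), 0.0)
            richness = s_obs - miss.sum()
            if t < T:
                cov_miss = np.where(
                    T - y >= t,
                    (y / u) * np.exp(_log_choose(T - y, t) - _log_choose(T - 1, t)),
                    0.0,
                )
                coverage = 1.0 - cov_miss.sum()
            else:
                coverage = sample_coverage(incidence).coverage
        else:
            if q0_hat <= 0:
                richness = float(s_obs)
            else:
                rate = q1 / (T * q0_hat + q1) if (T * q0_hat + q1) > 0 else 0.0
                richness = s_obs + q0_hat * (1.0 - (1.0 - rate) ** (t - T))
            denom = (T - 1) * q1 + 2 * q2
            base = (T - 1) * q1 / denom if denom > 0 else 0.0
            coverage = 1.0 - (q1 / u) * base ** (t - T + 1) if u > 0 else float("nan")
        rows.append({"units": int(t), "richness": float(richness), "coverage": float(coverage)})
    return pd.DataFrame(rows)
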