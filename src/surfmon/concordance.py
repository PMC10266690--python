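"""Species-specific cross-method abundance comparisons.

Compares per-site mean eDNA index scores, mean seine catch per haul, and
mean BRUV MaxN per deployment with unweighted ordinary least squares, one
regression per species, restricted to species detected jointly by both
methods at a minimum number of sites. Raw compositional read indices are
an imperfect abundance proxy, so both regression directions are emitted
(R-squared is direction-invariant; slopes are labelled).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def site_means_from_records(records: pd.DataFrame, method: str, k: int | None = None) -> pd.DataFrame:
    """Per-site mean count per replicate survey, species x site.

    Absent (species, replicate) records count as zeros, so the mean is the
    total catch over the site's replicates divided by ``k`` (the number of
    replicate surveys; defaults to the highest replicate index at the site).
    """
    sub = records[records["method"] == method]
    species = sorted(sub["species"].unique())
    out = {}
    for site, site_rows in sub.groupby("site"):
        k_site = k if k is not None else int(site_rows["replicate"].max())
        totals = site_rows.groupby("species")["value"].sum()
        out[site] = totals.reindex(species, fill_value=0) / k_site
    return pd.DataFrame(out)


def site_means_from_index(index_table: pd.DataFrame) -> pd.DataFrame:
    """Per-site mean eDNA index over a site's PCR replicates, taxon x site."""
    return index_table.T.groupby(level="site").mean().T


def joint_detection_pairs(
    x: pd.Series, y: pd.Series, min_sites: int = 3
) -> pd.DataFrame | None:
    """Site-aligned (x, y) pairs where both methods have nonzero means.

    Returns ``None`` when fewer than ``min_sites`` sites have joint nonzero
    detection (the species is skipped).
    """
    if min_sites < 2:
        raise ValueError("min_sites must be >= 2")
    joint = pd.DataFrame({"x": x, "y": y}).dropna()
    joint = joint[(joint["x"] > 0) & (joint["y"] > 0)]
    if len(joint) < min_sites:
        return None
    return joint


@dataclass
class RegressionResult:
    species: str
    predictor: str
    response: str
    n_sites: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def species_ols_regression(
    pairs: pd.DataFrame, species: str = "", predictor: str = "x", response: str = "y"
) -> RegressionResult:
    """Unweighted OLS of y on x with the two-sided slope t-test."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired sites")
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn(f"{species or 'series'}: zero variance in predictor; slope undefined")
        return RegressionResult(
            species, predictor, response, len(pairs),
            float("nan"), float("nan"), float("nan"), float("nan"),
        )
    if np.ptp(y) == 0:  # constant response: the fit explains nothing
        return RegressionResult(
            species, predictor, response, len(pairs), 0.0, float(y[0]), 0.0, 1.0
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        species=species,
        predictor=predictor,
        response=response,
        n_sites=len(pairs),
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
    )


def cross_method_regressions(
    method_means: dict,
    min_sites: int = 3,
    both_directions: bool = True,
) -> pd.DataFrame:
    """All species-specific regressions between every pair of methods.

    ``method_means`` maps a method name to a species x site DataFrame of
    per-site means. Species failing the joint-detection rule are reported
    with ``included=False`` and NaN statistics.
    """
    rows = []
    for m_x, m_y in itertools.combinations(method_means, 2):
        mx, my = method_means[m_x], method_means[m_y]
        shared_species = sorted(set(mx.index) & set(my.index))
        for sp in shared_species:
            pairs = joint_detection_pairs(mx.loc[sp], my.loc[sp], min_sites=min_sites)
            directions = [(m_x, m_y)] + ([(m_y, m_x)] if both_directions else [])
            for pred, resp in directions:
                if pairs is None:
                    rows.append(
                        {
                            "species": sp, "predictor": pred, "response": resp,
                            "n_sites": 0, "included": False,
                            "slope": np.nan, "intercept": np.nan,
                            "r_squared": np.nan, "p_value": np.nan,
                        }
                    )
                    continue
                ordered = pairs if pred == m_x else pairs.rename(columns={"x": "y", "y": "x"})
                res = species_ols_regression(ordered, species=sp, predictor=pred, response=resp)
                rows.append(
                    {
                        "species": sp, "predictor": pred, "response": resp,
                        "n_sites": res.n_sites, "included": True,
                        "slope": res.slope, "intercept": res.intercept,
                        "r_squared": res.r_squared, "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(rows)
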