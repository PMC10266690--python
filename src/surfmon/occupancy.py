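"""Bayesian site-occupancy model with false-positive detections.

For one species observed by one survey method, each site i contributes a
detection history (N_i, K_i): N detections out of K replicate surveys. The
model has three parameters,

    z_i ~ Bernoulli(psi)                    site truly occupied?
    N_i | z_i = 1 ~ Binomial(K_i, p11)      true-positive detection rate
    N_i | z_i = 0 ~ Binomial(K_i, p10)      false-positive detection rate

with the latent z_i marginalized analytically, giving the mixture
likelihood  psi*Bin(N;K,p11) + (1-psi)*Bin(N;K,p10)  per site. The
ordering constraint p10 < p11 resolves the label-switching degeneracy.

Derived quantities follow the standard conditional-occurrence algebra:

    P(occupied | N of K) = psi*p11^N*(1-p11)^(K-N) /
        [psi*p11^N*(1-p11)^(K-N) + (1-psi)*p10^N*(1-p10)^(K-N)]
    sensitivity = p11 / (p11 + p10)
    specificity = (1-p10) / ((1-p10) + (1-p11))

Posteriors are drawn with an affine-invariant ensemble sampler (emcee);
convergence is reported via split-chain R-hat and effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator


def _log_detection_kernel(p, N, K):
    """log[ p^N (1-p)^(K-N) ] without the binomial coefficient."""
    p = np.asarray(p, dtype=float)
    N = np.asarray(N, dtype=float)
    K = np.asarray(K, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hit = np.where(N > 0, N * np.log(p), 0.0)
        miss = np.where(K - N > 0, (K - N) * np.log1p(-p), 0.0)
    return hit + miss


def probability_of_occurrence(psi, p11, p10, K, N):
    """Posterior probability a site is occupied given N detections in K replicates.

    Evaluated in log space for stability; broadcasts over array inputs.
    With p10 = 0 any detection is definitive (probability 1); with
    p11 = p10 the detections are uninformative and the prior ``psi`` is
    returned.
    """
    psi, p11, p10 = (np.asarray(x, dtype=float) for x in (psi, p11, p10))
    N_arr = np.asarray(N)
    K_arr = np.asarray(K)
    if np.any(N_arr > K_arr):
        raise ValueError("N must not exceed K")
    if np.any(N_arr < 0) or np.any(K_arr < 0):
        raise ValueError("N and K must be nonnegative")
    with np.errstate(divide="ignore"):
        log_occ = np.log(psi) + _log_detection_kernel(p11, N, K)
        log_empty = np.log1p(-psi) + _log_detection_kernel(p10, N, K)
    out = expit(log_occ - log_empty)
    return out.item() if np.isscalar(N) and out.ndim == 0 else out


def sensitivity(p11, p10):
    """Proportion of detections that are true positives: p11 / (p11 + p10)."""
    p11 = np.asarray(p11, dtype=float)
    p10 = np.asarray(p10, dtype=float)
    denom = p11 + p10
    undefined = denom == 0
    if np.any(undefined):
        warnings.warn("sensitivity undefined at p11 = p10 = 0; returning NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(undefined, np.nan, p11 / np.where(undefined, 1.0, denom))
    return float(out) if out.ndim == 0 else out


def specificity(p11, p10):
    """Proportion of true negatives correctly negative: (1-p10)/((1-p10)+(1-p11))."""
    p11 = np.asarray(p11, dtype=float)
    p10 = np.asarray(p10, dtype=float)
    denom = (1.0 - p10) + (1.0 - p11)
    undefined = denom == 0
    if np.any(undefined):
        warnings.warn("specificity undefined at p11 = p10 = 1; returning NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(undefined, np.nan, (1.0 - p10) / np.where(undefined, 1.0, denom))
    return float(out) if out.ndim == 0 else out


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for (n_chains, n_draws)."""
    import arviz as az

    return float(np.asarray(az.rhat(az.convert_to_dataset(chains))["x"]).max())


class OccupancyModel(BaseEstimator):
    """Three-parameter occupancy model for one species x method.

    Parameters
    ----------
    n_walkers : ensemble size of the sampler (split into pseudo-chains for
        the R-hat diagnostic).
    n_steps, n_warmup : iterations per walker and discarded warmup.
    psi_prior, p11_prior, p10_prior : Beta(a, b) prior parameters. The
        default Beta(1, 10) on p10, together with the hard constraint
        p10 < p11, keeps the false-positive component identified.
    seed : integer seed; the same seed reproduces the fit exactly.

    Fitted attributes (after :meth:`fit`): ``samples_`` (draws x 3 in the
    order psi, p11, p10), ``summary_``, ``psi_``, ``p11_``, ``p10_``,
    ``sensitivity_``, ``specificity_``, ``rhat_``, ``ess_``, ``converged_``.
    """

    _param_names = ("psi", "p11", "p10")

    def __init__(
        self,
        n_walkers: int = 32,
        n_steps: int = 2000,
        n_warmup: int = 1000,
        psi_prior: tuple = (1.0, 1.0),
        p11_prior: tuple = (1.0, 1.0),
        p10_prior: tuple = (1.0, 10.0),
        rhat_threshold: float = 1.05,
        seed: int | None = None,
    ):
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_warmup = n_warmup
        self.psi_prior = psi_prior
        self.p11_prior = p11_prior
        self.p10_prior = p10_prior
        self.rhat_threshold = rhat_threshold
        self.seed = seed

    # -- likelihood ---------------------------------------------------

    @staticmethod
    def _prepare(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Collapse histories to unique (N, K) cells with multiplicities."""
        if isinstance(X, pd.DataFrame):
            arr = X[["N", "K"]].to_numpy()
        else:
            arr = np.asarray(X)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must be (n_sites, 2) columns N, K")
        if arr.shape[0] < 1:
            raise ValueError("at least one site is required")
        N, K = arr[:, 0], arr[:, 1]
        if np.any(K < 1):
            raise ValueError("K must be >= 1 at every site")
        if np.any(N < 0) or np.any(N > K):
            raise ValueError("need 0 <= N <= K at every site")
        cells, counts = np.unique(arr, axis=0, return_counts=True)
        return cells[:, 0].astype(float), cells[:, 1].astype(float), counts.astype(float)

    @staticmethod
    def _log_beta_kernel(x, a, b):
        """Unnormalized Beta(a, b) log-density, safe at the support edges."""
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(a != 1.0, (a - 1.0) * np.log(x), 0.0)
            t2 = np.where(b != 1.0, (b - 1.0) * np.log1p(-x), 0.0)
        return t1 + t2

    def _log_prob(self, theta, N, K, counts):
        """Vectorized log-posterior for a (n_walkers, 3) parameter block."""
        theta = np.atleast_2d(theta)
        psi, p11, p10 = theta[:, 0], theta[:, 1], theta[:, 2]
        valid = (
            (psi > 0) & (psi < 1) & (p11 > 0) & (p11 < 1)
            & (p10 >= 0) & (p10 < 1) & (p10 < p11)
        )
        out = np.full(theta.shape[0], -np.inf)
        if not valid.any():
            return out
        v_psi, v_p11, v_p10 = psi[valid], p11[valid], p10[valid]
        lp = (
            self._log_beta_kernel(v_psi, *self.psi_prior)
            + self._log_beta_kernel(v_p11, *self.p11_prior)
            + self._log_beta_kernel(v_p10, *self.p10_prior)
        )
        log_occ = (
            np.log(v_psi)[:, None]
            + _log_detection_kernel(v_p11[:, None], N[None, :], K[None, :])
        )
        log_empty = (
            np.log1p(-v_psi)[:, None]
            + _log_detection_kernel(v_p10[:, None], N[None, :], K[None, :])
        )
        out[valid] = lp + np.logaddexp(log_occ, log_empty) @ counts
        return out

    # -- fitting ------------------------------------------------------

    def fit(self, X, y=None):
        """Sample the posterior from detection histories.

        ``X`` is a DataFrame with integer columns ``N`` and ``K`` (one row
        per site) or an equivalent (n_sites, 2) array.
        """
        import emcee

        N, K, counts = self._prepare(X)
        if np.dot(counts, N) == 0:
            warnings.warn(
                "species never detected: the occupancy posterior is prior-driven"
            )
        rng = np.random.default_rng(self.seed)
        n_walkers = max(int(self.n_walkers), 8)
        p0 = np.column_stack(
            [
                rng.uniform(0.05, 0.95, n_walkers),
                rng.uniform(0.5, 0.95, n_walkers),
                rng.uniform(0.005, 0.2, n_walkers),
            ]
        )
        p0[:, 2] = np.minimum(p0[:, 2], p0[:, 1] * 0.5)
        # differential-evolution moves traverse the psi/p10 mixture ridge
        # far better than the default stretch move on this posterior
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            n_walkers, 3, self._log_prob, args=(N, K, counts),
            vectorize=True, moves=moves,
        )
        sampler.random_state = np.random.RandomState(
            rng.integers(0, 2**31 - 1)
        ).get_state()
        sampler.run_mcmc(p0, self.n_steps, progress=False)
        chain = sampler.get_chain(discard=self.n_warmup)  # (draws, walkers, 3)
        self.samples_ = chain.reshape(-1, 3)

        per_walker = np.moveaxis(chain, 1, 0)  # (walkers, draws, 3)
        self.rhat_ = {
            name: _split_rhat(per_walker[:, :, j])
            for j, name in enumerate(self._param_names)
        }
        import logging

        emcee_logger = logging.getLogger("emcee")
        old_level = emcee_logger.level
        emcee_logger.setLevel(logging.ERROR)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tau = np.asarray(
                    sampler.get_autocorr_time(discard=self.n_warmup, quiet=True),
                    dtype=float,
                )
        finally:
            emcee_logger.setLevel(old_level)
        tau = np.where(np.isfinite(tau) & (tau >= 1.0), tau, 1.0)
        self.ess_ = {
            name: float(self.samples_.shape[0] / tau[j])
            for j, name in enumerate(self._param_names)
        }
        self.converged_ = all(r <= self.rhat_threshold for r in self.rhat_.values())
        if not self.converged_:
            warnings.warn(
                f"occupancy sampler not converged (max R-hat "
                f"{max(self.rhat_.values()):.3f} > {self.rhat_threshold})"
            )

        q = np.percentile(self.samples_, [2.5, 50.0, 97.5], axis=0)
        self.summary_ = pd.DataFrame(
            {
                "mean": self.samples_.mean(axis=0),
                "median": q[1],
                "q2.5": q[0],
                "q97.5": q[2],
            },
            index=list(self._param_names),
        )
        self.psi_, self.p11_, self.p10_ = self.samples_.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.sensitivity_ = float(
                np.nanmean(sensitivity(self.samples_[:, 1], self.samples_[:, 2]))
            )
            self.specificity_ = float(
                np.nanmean(specificity(self.samples_[:, 1], self.samples_[:, 2]))
            )
        self.n_sites_ = int(counts.sum())
        return self

    def site_occurrence_prob(self, X) -> np.ndarray:
        """Posterior-mean probability of occurrence for each site's (N, K)."""
        if not hasattr(self, "samples_"):
            raise RuntimeError("fit the model before querying site occurrence")
        if isinstance(X, pd.DataFrame):
            arr = X[["N", "K"]].to_numpy()
        else:
            arr = np.asarray(X)
        out = np.empty(arr.shape[0])
        draws = self.samples_
        for i, (n, k) in enumerate(arr):
            out[i] = float(
                np.mean(
                    probability_of_occurrence(
                        draws[:, 0], draws[:, 1], draws[:, 2], float(k), float(n)
                    )
                )
            )
        return out


def estimate_occupancy(
    histories: pd.DataFrame,
    n_walkers: int = 32,
    n_steps: int = 2000,
    n_warmup: int = 1000,
    seed: int = 0,
    **model_kwargs,
) -> pd.DataFrame:
    """Fit the occupancy model per species x method over a tidy history table.

    ``histories`` has columns ``species, method, site, N, K``. Species never
    detected by a method are skipped with a warning (their parameters are
    unidentified). Returns one row per fitted species x method with posterior
    summaries, derived metrics and diagnostics; the per-group seeds are
    spawned deterministically from ``seed``.
    """
    required = {"species", "method", "site", "N", "K"}
    if not required.issubset(histories.columns):
        raise ValueError(f"histories must have columns {sorted(required)}")
    groups = sorted(histories.groupby(["species", "method"]).groups)
    base = np.random.SeedSequence(seed)
    children = base.spawn(len(groups))
    rows = []
    for (sp, method), child in zip(groups, children):
        sub = histories[(histories["species"] == sp) & (histories["method"] == method)]
        if sub["N"].sum() == 0:
            warnings.warn(f"{sp}/{method}: never detected; skipped")
            continue
        model = OccupancyModel(
            n_walkers=n_walkers,
            n_steps=n_steps,
            n_warmup=n_warmup,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            **model_kwargs,
        )
        model.fit(sub)
        occ = model.site_occurrence_prob(sub)
        row = {"species": sp, "method": method, "n_sites": len(sub)}
        for pname in model._param_names:
            for col in ("mean", "median", "q2.5", "q97.5"):
                row[f"{pname}_{col}"] = model.summary_.loc[pname, col]
        row["sensitivity"] = model.sensitivity_
        row["specificity"] = model.specificity_
        row["mean_site_occurrence"] = float(np.mean(occ))
        row["rhat_max"] = max(model.rhat_.values())
        row["ess_min"] = min(model.ess_.values())
        row["converged"] = model.converged_
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MethodMetricSummary:
    """Per-method metric means with ANOVA and Tukey HSD comparisons."""

    means: pd.DataFrame  # method x metric
    anova: pd.DataFrame  # metric -> F, p, df
    tukey: dict  # metric -> pairwise DataFrame


def compare_method_metrics(
    fits: pd.DataFrame,
    metrics: tuple = ("sensitivity", "specificity", "mean_site_occurrence"),
) -> MethodMetricSummary:
    """Compare methods on species-level metrics with one-way ANOVA + Tukey HSD.

    Each species contributes one observation per method; methods with fewer
    than two species-level values are excluded with a warning.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    counts = fits.groupby("method").size()
    keep = counts[counts >= 2].index
    dropped = sorted(set(fits["method"]) - set(keep))
    if dropped:
        warnings.warn(f"methods with < 2 species excluded from comparison: {dropped}")
    sub = fits[fits["method"].isin(keep)]
    if sub["method"].nunique() < 2:
        raise ValueError("need at least two methods with >= 2 species each")
    means = sub.groupby("method")[list(metrics)].mean()
    anova_rows = []
    tukey = {}
    for metric in metrics:
        clean = sub.dropna(subset=[metric])
        groups = [g[metric].to_numpy() for _, g in clean.groupby("method")]
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p_val = 0.0, 1.0  # identical groups carry no signal
        else:
            f_stat, p_val = stats.f_oneway(*groups)
            if np.isnan(f_stat):
                f_stat, p_val = 0.0, 1.0
        anova_rows.append(
            {
                "metric": metric,
                "F": float(f_stat),
                "p": float(p_val),
                "df_between": clean["method"].nunique() - 1,
                "df_within": len(clean) - clean["method"].nunique(),
            }
        )
        res = pairwise_tukeyhsd(clean[metric].to_numpy(), clean["method"].to_numpy())
        tukey[metric] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return MethodMetricSummary(
        means=means, anova=pd.DataFrame(anova_rows).set_index("metric"), tukey=tukey
    )
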