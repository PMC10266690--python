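"""Decontamination and normalization of ASV-by-replicate read tables.

The pipeline is: (1) a replicate-consistency filter that zeroes, per site,
any ASV seen in fewer than a minimum number of that site's technical PCR
replicates (the mandatory decontamination step; single-replicate records
are the signature of index hopping and carry-over contamination); (2) an
optional per-ASV occupancy screen; (3) summation of ASVs sharing an
assigned taxonomic path; (4) the eDNA index — per-replicate relative
abundance of a taxon scaled by that taxon's maximum relative abundance
across all samples, giving a within-taxon abundance signal in [0, 1];
(5) collapse to site-level detection histories (N detections out of K
replicate units) for the occupancy model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import occupancy as occ


def _require_key_columns(table: pd.DataFrame) -> None:
    if not isinstance(table.columns, pd.MultiIndex) or list(table.columns.names)[:2] != [
        "site",
        "bottle",
    ]:
        raise ValueError(
            "read table must carry a (site, bottle, pcr, marker) column MultiIndex"
        )


class ReplicateConsistencyFilter(BaseEstimator, TransformerMixin):
    """Zero an ASV's reads at a site unless seen in >= ``min_replicates`` there.

    ``scope`` controls what counts as the pool of technical replicates:
    ``"site"`` pools all PCR reactions at the site across bottles (default,
    e.g. 9 for 3 bottles x 3 PCRs); ``"bottle"`` evaluates the rule within
    each bottle. The rule is evaluated independently per site, so an ASV
    may survive at one site and be removed at another. ``min_replicates=1``
    is the identity.
    """

    def __init__(self, min_replicates: int = 2, scope: str = "site"):
        self.min_replicates = min_replicates
        self.scope = scope

    def fit(self, X, y=None):
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")
        if self.scope not in ("site", "bottle"):
            raise ValueError("scope must be 'site' or 'bottle'")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        _require_key_columns(X)
        out = X.copy()
        levels = ["site"] if self.scope == "site" else ["site", "bottle"]
        for _, cols in X.columns.to_frame(index=False).groupby(levels).groups.items():
            block = X.iloc[:, list(cols)]
            prevalence = (block > 0).sum(axis=1)
            kill = prevalence < self.min_replicates
            if kill.any():
                out.iloc[np.flatnonzero(kill.to_numpy()), list(cols)] = 0
        return out


def replicate_consistency_filter(
    reads: pd.DataFrame, min_replicates: int = 2, scope: str = "site"
) -> pd.DataFrame:
    return ReplicateConsistencyFilter(min_replicates, scope).transform(reads)


def asv_occupancy_filter(
    reads: pd.DataFrame,
    threshold: float = 0.8,
    seed: int = 0,
    n_walkers: int = 32,
    n_steps: int = 4000,
    n_warmup: int = 2000,
) -> pd.DataFrame:
    """Optional occupancy-based screen applied at the ASV level.

    Each ASV's per-site detection history (replicate = one PCR reaction) is
    fitted with the occupancy model; sites whose posterior probability of
    occurrence falls below ``threshold`` are zeroed for that ASV.
    ``threshold=0`` is the identity. If the sampler fails to converge for
    an ASV, the ASV is retained unchanged (conservative) with a warning.
    """
    if threshold <= 0:
        return reads.copy()
    _require_key_columns(reads)
    out = reads.copy()
    site_cols = {
        site: list(cols)
        for site, cols in reads.columns.to_frame(index=False).groupby("site").groups.items()
    }
    base = np.random.SeedSequence(seed)
    children = iter(base.spawn(len(reads.index)))
    for asv in reads.index:
        child = next(children)
        row = reads.loc[asv]
        hist = []
        for site, cols in site_cols.items():
            block = row.iloc[cols]
            hist.append((site, int((block > 0).sum()), len(cols)))
        hist_df = pd.DataFrame(hist, columns=["site", "N", "K"])
        if hist_df["N"].sum() == 0:
            continue
        model = occ.OccupancyModel(
            n_walkers=n_walkers,
            n_steps=n_steps,
            n_warmup=n_warmup,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(hist_df)
        if not model.converged_:
            warnings.warn(f"occupancy screen: sampler not converged for {asv}; retained")
            continue
        probs = model.site_occurrence_prob(hist_df)
        for (site, _n, _k), p in zip(hist, probs):
            if p < threshold:
                out.loc[asv, out.columns[site_cols[site]]] = 0
    return out


class TaxonomyAggregator(BaseEstimator, TransformerMixin):
    """Sum reads of ASVs sharing an identical assigned taxonomic path.

    Paths that terminate above species rank (e.g. a family-level
    assignment shared by barcode-indistinguishable surfperches) become a
    single taxon keyed by that coarser path. Per-replicate totals are
    conserved exactly.
    """

    def __init__(self, taxonomy: pd.Series):
        self.taxonomy = taxonomy

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        orphans = sorted(set(X.index) - set(self.taxonomy.index))
        if orphans:
            raise ValueError(f"ASVs without taxonomic assignment: {orphans}")
        paths = self.taxonomy.reindex(X.index)
        out = X.groupby(paths.values).sum()
        out.index.name = "taxon"
        return out


def aggregate_by_taxonomy(reads: pd.DataFrame, taxonomy: pd.Series) -> pd.DataFrame:
    return TaxonomyAggregator(taxonomy).transform(reads)


class EdnaIndexTransformer(BaseEstimator, TransformerMixin):
    """Compute the eDNA index from a taxon read table.

    Step 1: per replicate, each taxon's proportional relative abundance
    (reads over the replicate's total). Step 2: divide by the taxon's
    maximum relative abundance across all replicates of all samples. The
    result lies in [0, 1] with the per-taxon maximum exactly 1 whenever the
    taxon has any reads; all-zero taxa and zero-total replicates yield 0.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        totals = X.sum(axis=0).astype(float)
        if not (totals > 0).any():
            warnings.warn("eDNA index of an all-zero table is all zeros")
        with np.errstate(divide="ignore", invalid="ignore"):
            props = X.div(totals.where(totals > 0), axis=1).fillna(0.0)
        taxon_max = props.max(axis=1)
        index = props.div(taxon_max.where(taxon_max > 0), axis=0).fillna(0.0)
        return index


def compute_edna_index(taxa: pd.DataFrame) -> pd.DataFrame:
    return EdnaIndexTransformer().transform(taxa)


def terminal_taxon(path: str) -> str:
    """Finest resolved rank of a semicolon-delimited taxonomic path.

    A species-level path yields the binomial; a path truncated at family
    (barcode-shared taxa) yields the family name, so cross-method species
    lists only match where the marker resolves to species.
    """
    return path.rsplit(";", 1)[-1].strip()


def build_detection_history(
    data: pd.DataFrame,
    method: str,
    threshold: int = 1,
    edna_unit: str = "bottle",
    k: int | None = None,
    k_by_site: dict | None = None,
) -> pd.DataFrame:
    """Collapse observations to per-site detection histories (N of K).

    For seine/BRUV, ``data`` is the long survey-record frame and a
    replicate detects a species iff its count >= ``threshold``; ``k`` (or
    ``k_by_site``) gives the replicates surveyed, defaulting to the highest
    replicate index seen at the site. Sites with no record rows for the
    method emit no history (missing deployment). For eDNA, ``data`` is a
    decontaminated taxon read table; with ``edna_unit="bottle"`` a bottle
    detects a taxon iff any of its PCR replicates reaches ``threshold``
    reads, K = bottles at the site; with ``"pcr"`` every PCR reaction is a
    unit.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    rows = []
    if method in ("seine", "bruv"):
        sub = data[data["method"] == method]
        if len(sub) == 0:
            return pd.DataFrame(columns=["species", "method", "site", "N", "K"])
        species = sorted(sub["species"].unique())
        for site, site_rows in sub.groupby("site"):
            k_site = (k_by_site or {}).get(site, k)
            if k_site is None:
                k_site = int(site_rows["replicate"].max())
            if (site_rows["replicate"] > k_site).any():
                raise ValueError(
                    f"replicate index exceeds K={k_site} at site {site!r}"
                )
            for sp in species:
                hits = site_rows[
                    (site_rows["species"] == sp) & (site_rows["value"] >= threshold)
                ]["replicate"].nunique()
                rows.append((sp, method, site, int(hits), int(k_site)))
    elif method == "edna":
        _require_key_columns(data)
        if edna_unit not in ("bottle", "pcr"):
            raise ValueError("edna_unit must be 'bottle' or 'pcr'")
        col_frame = data.columns.to_frame(index=False)
        for site, cols in col_frame.groupby("site").groups.items():
            cols = list(cols)
            block = data.iloc[:, cols]
            if edna_unit == "bottle":
                bottles = col_frame.iloc[cols]["bottle"]
                detected = (block >= threshold).T.groupby(bottles.values).any().T
                k_site = detected.shape[1]
            else:
                detected = block >= threshold
                k_site = len(cols)
            for taxon in data.index:
                rows.append(
                    (taxon, "edna", site, int(detected.loc[taxon].sum()), int(k_site))
                )
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows, columns=["species", "method", "site", "N", "K"])
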