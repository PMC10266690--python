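"""Synthetic multi-method survey data with known generating truth.

Emulates a contemporaneous surf-zone fish survey campaign: a fixed set of
sites holds a latent fish community (occupancy states ``z`` and local
abundances ``lambda``), which is observed by three methods — beach seine
hauls (counts), baited remote underwater video (MaxN per deployment), and
eDNA metabarcoding (ASV read tables over bottle x PCR replicates). Every
generator is seeded and returns the generating parameters so downstream
estimators can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

METHODS = ("seine", "bruv", "edna")


class ConfigurationError(ValueError):
    """Inconsistent simulation settings (e.g. p10 >= p11)."""


@dataclass
class SurveyDesign:
    """Replication structure of the field campaign.

    Defaults mirror a campaign of 18 beach sites surveyed with four seine
    hauls, three BRUV deployments, and three 0.5 L water bottles each
    amplified in PCR triplicate.
    """

    n_sites: int = 18
    k_seine: int = 4
    k_bruv: int = 3
    n_bottles: int = 3
    n_pcr: int = 3
    read_depth: int = 50_000
    marker: str = "teleost"
    catchability: dict = field(default_factory=lambda: {"seine": 1.0, "bruv": 1.0})
    #: (site, method) pairs with no deployment (e.g. BRUV lost to surf).
    missing_deployments: tuple = ()

    def __post_init__(self) -> None:
        for name in ("n_sites", "k_seine", "k_bruv", "n_bottles", "n_pcr", "read_depth"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"design {name} must be >= 1")

    @property
    def sites(self) -> list[str]:
        return [f"Site{i + 1:02d}" for i in range(self.n_sites)]

    def k_for(self, method: str) -> int:
        return {"seine": self.k_seine, "bruv": self.k_bruv, "edna": self.n_bottles}[method]


@dataclass
class SimulationTruth:
    """Generating parameters and latent states of one synthetic campaign.

    ``psi`` is the per-species probability of occupying a site; the latent
    state ``z`` is shared across methods because all three observe the same
    community. Detection rates ``p11`` (given presence) and ``p10`` (given
    absence) are species x method. ``efficiency`` is the species' relative
    PCR amplification efficiency; ``lam`` the latent local abundance.
    """

    species: list[str]
    sites: list[str]
    psi: pd.Series
    p11: pd.DataFrame
    p10: pd.DataFrame
    efficiency: pd.Series
    z: pd.DataFrame
    lam: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if (self.efficiency <= 0).any():
            raise ConfigurationError("amplification efficiencies must be > 0")
        if not (self.p10.values < self.p11.values).all():
            raise ConfigurationError(
                "p10 must be < p11 for every species x method (identifiability)"
            )


def _broadcast(value, index, columns=None, rng=None, sampler=None):
    """Expand a scalar/None parameter to a Series or DataFrame."""
    if columns is None:
        if value is None:
            return pd.Series(sampler(rng, len(index)), index=index)
        return pd.Series(float(value), index=index)
    if value is None:
        return pd.DataFrame(
            sampler(rng, (len(index), len(columns))), index=index, columns=columns
        )
    return pd.DataFrame(float(value), index=index, columns=columns)


def make_truth(
    design: SurveyDesign,
    n_species: int = 40,
    seed: int = 0,
    psi: float | None = None,
    p11: float | None = None,
    p10: float | None = None,
    lam_mean: float = 20.0,
    lam_sigma: float = 1.0,
    efficiency_sigma: float = 0.7,
) -> SimulationTruth:
    """Draw a generating truth for ``n_species`` over the design's sites.

    ``psi``, ``p11``, ``p10`` may be fixed scalars (applied to every
    species/method) or ``None`` for realistic heterogeneous draws:
    psi ~ Beta(0.7, 1.8), a right-skewed occupancy distribution (fish
    assemblages hold many rare and few widespread species), p11 ~
    Uniform(0.55, 0.95), p10 ~ Uniform(0.01, 0.10). Local abundance is
    log-normal around ``lam_mean`` and shared across methods.
    """
    rng = np.random.default_rng(seed)
    species = [f"Fish_sp_{i + 1:03d}" for i in range(n_species)]
    sites = design.sites
    methods = list(METHODS)

    psi_s = _broadcast(psi, species, rng=rng, sampler=lambda r, n: r.beta(0.7, 1.8, n))
    p11_sm = _broadcast(
        p11, species, methods, rng=rng, sampler=lambda r, sh: r.uniform(0.55, 0.95, sh)
    )
    p10_sm = _broadcast(
        p10, species, methods, rng=rng, sampler=lambda r, sh: r.uniform(0.01, 0.10, sh)
    )
    efficiency = pd.Series(
        np.exp(rng.normal(0.0, efficiency_sigma, n_species)), index=species,
        name="efficiency",
    )
    z = pd.DataFrame(
        (rng.random((len(sites), n_species)) < psi_s.values[None, :]).astype(int),
        index=sites, columns=species,
    )
    lam = pd.DataFrame(
        np.exp(rng.normal(np.log(lam_mean) - lam_sigma**2 / 2, lam_sigma,
                          (len(sites), n_species))),
        index=sites, columns=species,
    )
    return SimulationTruth(
        species=species, sites=sites, psi=psi_s.rename("psi"),
        p11=p11_sm, p10=p10_sm, efficiency=efficiency, z=z, lam=lam, seed=seed,
    )


def simulate_occupancy_detections(
    truth: SimulationTruth, design: SurveyDesign, seed: int = 0
) -> pd.DataFrame:
    """Detection histories N ~ Binomial(K, p11 if z else p10) per species x method x site.

    Returns a tidy frame with columns ``species, method, site, N, K``; sites
    listed in ``design.missing_deployments`` emit no history for that method.
    """
    rng = np.random.default_rng(seed)
    missing = set(design.missing_deployments)
    rows = []
    for method in METHODS:
        k = design.k_for(method)
        for sp in truth.species:
            p11 = truth.p11.loc[sp, method]
            p10 = truth.p10.loc[sp, method]
            if p10 >= p11:
                raise ConfigurationError(f"p10 >= p11 for {sp}/{method}")
            z = truth.z[sp].values
            p = np.where(z == 1, p11, p10)
            n = rng.binomial(k, p)
            for site, n_i in zip(truth.sites, n):
                if (site, method) in missing:
                    continue
                rows.append((sp, method, site, int(n_i), k))
    return pd.DataFrame(rows, columns=["species", "method", "site", "N", "K"])


def _taxonomy_paths(species: Sequence[str], rng, family_only_fraction: float) -> dict:
    """Assign ranked taxonomy; a fraction resolve only to family (barcode sharing)."""
    n_families = max(1, len(species) // 3)
    paths = {}
    for i, sp in enumerate(species):
        fam = f"Family_{i % n_families + 1:02d}"
        base = f"Actinopteri;Order_{i % 7 + 1};{fam}"
        if rng.random() < family_only_fraction:
            paths[sp] = base
        else:
            paths[sp] = f"{base};Genus_{i + 1};{sp}"
    return paths


def simulate_read_table(
    truth: SimulationTruth,
    design: SurveyDesign,
    contamination_rate: float = 0.0,
    seed: int = 0,
    family_only_fraction: float = 0.1,
    mean_asvs_per_species: float = 1.7,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Simulate the ASV-by-replicate read table entering decontamination.

    Per PCR replicate, species presence in the amplicon pool is a Bernoulli
    thinning with the species' eDNA p11 (p10 for absent species, emulating
    trace contamination); detected species receive one guaranteed read plus
    a multinomial share of the remaining depth with weights proportional to
    ``efficiency * lambda``. Species reads are split over their ASVs with
    fixed per-species proportions; contaminant ASVs from a disjoint taxon
    pool land in exactly one PCR replicate each, at ``contamination_rate``
    per replicate.

    Returns ``(read_table, taxonomy, info)`` where ``info`` carries the
    per-replicate true detection matrix and the contaminant ASV ids.
    """
    if not 0.0 <= contamination_rate <= 1.0:
        raise ConfigurationError("contamination_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = truth.species
    paths = _taxonomy_paths(species, rng, family_only_fraction)

    # fixed ASV split per species
    asv_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    asv_of_species: dict[str, tuple[list[str], np.ndarray]] = {}
    counter = 1
    for sp in species:
        n_asv = 1 + rng.poisson(max(mean_asvs_per_species - 1.0, 0.0))
        ids = [f"ASV_{counter + j:05d}" for j in range(n_asv)]
        counter += n_asv
        props = rng.dirichlet(np.ones(n_asv) * 2.0)
        asv_of_species[sp] = (ids, props)
        for a in ids:
            taxonomy[a] = paths[sp]
        asv_ids.extend(ids)

    columns = [
        (site, b + 1, p + 1, design.marker)
        for site in truth.sites
        for b in range(design.n_bottles)
        for p in range(design.n_pcr)
    ]
    col_index = pd.MultiIndex.from_tuples(columns, names=["site", "bottle", "pcr", "marker"])
    data = np.zeros((len(asv_ids), len(columns)), dtype=np.int64)
    asv_pos = {a: i for i, a in enumerate(asv_ids)}
    p11_e = truth.p11["edna"]
    p10_e = truth.p10["edna"]
    eff = truth.efficiency
    detections = np.zeros((len(species), len(columns)), dtype=bool)

    for ci, (site, _b, _p, _m) in enumerate(columns):
        z = truth.z.loc[site]
        p_det = np.where(z.values == 1, p11_e.values, p10_e.values)
        det = rng.random(len(species)) < p_det
        detections[:, ci] = det
        det_idx = np.flatnonzero(det)
        if det_idx.size == 0:
            continue
        lam_site = truth.lam.loc[site].values
        # absent-but-detected species amplify from trace template, weight ~ efficiency
        weights = eff.values[det_idx] * np.where(
            truth.z.loc[site].values[det_idx] == 1, lam_site[det_idx], 1.0
        )
        remaining = max(design.read_depth - det_idx.size, 0)
        counts = np.ones(det_idx.size, dtype=np.int64)
        if remaining > 0:
            counts += rng.multinomial(remaining, weights / weights.sum())
        for sp_i, n_reads in zip(det_idx, counts):
            ids, props = asv_of_species[species[sp_i]]
            split = rng.multinomial(n_reads, props) if len(ids) > 1 else [n_reads]
            for a, c in zip(ids, split):
                data[asv_pos[a], ci] += c

    contaminants: list[str] = []
    if contamination_rate > 0:
        extra_rows = []
        for ci in range(len(columns)):
            if rng.random() < contamination_rate:
                cid = f"CONTAM_{len(contaminants) + 1:04d}"
                contaminants.append(cid)
                taxonomy[cid] = f"Contaminantia;OrderX;FamilyX;GenusX;Contaminant_sp_{len(contaminants)}"
                row = np.zeros(len(columns), dtype=np.int64)
                row[ci] = rng.integers(1, 200)
                extra_rows.append(row)
        if extra_rows:
            data = np.vstack([data, np.array(extra_rows)])
            asv_ids = asv_ids + contaminants

    table = pd.DataFrame(data, index=pd.Index(asv_ids, name="asv_id"), columns=col_index)
    tax = pd.Series({a: taxonomy[a] for a in asv_ids}, name="path")
    tax.index.name = "asv_id"
    info = {
        "detections": pd.DataFrame(
            detections, index=species, columns=col_index
        ),
        "contaminant_asvs": contaminants,
        "species_asvs": {sp: ids for sp, (ids, _) in asv_of_species.items()},
    }
    return table, tax, info


def simulate_survey_counts(
    truth: SimulationTruth, design: SurveyDesign, seed: int = 0
) -> pd.DataFrame:
    """Seine catches and BRUV MaxN as Poisson thinnings of latent abundance.

    Counts per replicate are Poisson(c_method * lambda * z); only nonzero
    records are emitted (long format), and (site, method) pairs listed as
    missing deployments are skipped entirely.
    """
    rng = np.random.default_rng(seed)
    missing = set(design.missing_deployments)
    rows = []
    for method in ("seine", "bruv"):
        c = design.catchability.get(method, 1.0)
        k = design.k_for(method)
        for site in truth.sites:
            if (site, method) in missing:
                continue
            mu = c * truth.lam.loc[site].values * truth.z.loc[site].values
            for rep in range(1, k + 1):
                counts = rng.poisson(mu)
                for sp, n in zip(truth.species, counts):
                    if n > 0:
                        rows.append((site, method, rep, sp, int(n)))
    return pd.DataFrame(rows, columns=["site", "method", "replicate", "species", "value"])


def truth_to_frame(truth: SimulationTruth) -> pd.DataFrame:
    """Tidy species x method view of the generating parameters."""
    rows = []
    for sp in truth.species:
        for m in METHODS:
            rows.append(
                (sp, m, truth.psi[sp], truth.p11.loc[sp, m], truth.p10.loc[sp, m],
                 truth.efficiency[sp])
            )
    return pd.DataFrame(
        rows, columns=["species", "method", "psi", "p11", "p10", "efficiency"]
    )
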