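# surfmon

Multi-method biomonitoring analysis for surf-zone fish communities.

Sandy-beach surf zones are hard to survey: seine nets under-sample fast or
structure-associated fish, baited cameras (BRUV) miss cryptic species, and
eDNA metabarcoding detects almost everything but says little about
abundance and can produce false positives. `surfmon` is for ecologists
comparing these survey methods on the same set of sites. It provides, as a
tested pipeline:

- **Metabarcoding preparation** — replicate-consistency decontamination of
  ASV read tables (an ASV must appear in ≥ 2 technical PCR replicates at a
  site), optional occupancy-based screening, summation of ASVs sharing a
  taxonomic path, and the **eDNA index** (per-replicate read proportion
  scaled by the taxon's maximum proportion across all samples, in [0, 1]).
- **Site-occupancy modelling with false positives** — per species × method,
  detection histories (N detections of K replicates per site) are fitted to
  the mixture z ~ Bernoulli(ψ), N | z ~ Binomial(K, z ? p₁₁ : p₁₀) by MCMC
  with the latent state marginalized, yielding posteriors for occupancy ψ,
  true-positive rate p₁₁ and false-positive rate p₁₀, and the derived
  per-site probability of occurrence, sensitivity p₁₁/(p₁₁+p₁₀) and
  specificity (1−p₁₀)/((1−p₁₀)+(1−p₁₁)), compared across methods by ANOVA
  and Tukey HSD.
- **Community comparison** — Jaccard-binary dissimilarities, a sequential
  (Type I) PERMANOVA for `detection ~ method + site` with permutation (or
  exact) p-values, homogeneity of multivariate dispersions, Venn overlap of
  species lists, and incidence-based sample coverage with
  rarefaction/extrapolation (Hill q = 0, Chao2 asymptote).
- **Abundance concordance** — species-specific OLS regressions between
  per-site mean eDNA index, mean seine catch and mean BRUV MaxN for species
  jointly detected at ≥ 3 sites.
- **A synthetic-data generator** with known truth (occupancy states, latent
  abundance, amplification efficiencies, injected single-replicate
  contaminants) so every stage is testable end to end without any download.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

```python
import pandas as pd
from surfmon import (SurveyDesign, make_truth, simulate_read_table,
                     replicate_consistency_filter, aggregate_by_taxonomy,
                     compute_edna_index, build_detection_history, OccupancyModel)

design = SurveyDesign(n_sites=12)                      # 3 bottles x 3 PCRs per site
truth = make_truth(design, n_species=10, seed=42)
reads, taxonomy, info = simulate_read_table(truth, design,
                                            contamination_rate=0.2, seed=43)
print("raw ASVs:", len(reads), "including", len(info["contaminant_asvs"]),
      "contaminants")
clean = replicate_consistency_filter(reads, min_replicates=2)
print("ASVs with reads after filter:", int((clean.sum(axis=1) > 0).sum()))

taxa = aggregate_by_taxonomy(clean, taxonomy)
index = compute_edna_index(taxa)                       # in [0, 1], max 1 per taxon
hist = build_detection_history(taxa, "edna")           # bottle-level N of K=3

one = hist[hist["species"] == hist.groupby("species")["N"].sum().idxmax()]
fit = OccupancyModel(seed=0).fit(one)
print(fit.summary_.round(3))
print(f"sensitivity {fit.sensitivity_:.3f}  specificity {fit.specificity_:.3f}")
print("P(occupied | N=0 of 3):",
      fit.site_occurrence_prob(pd.DataFrame({"N": [0], "K": [3]})).round(4))
```

Output:

```
raw ASVs: 37 including 17 contaminants
ASVs with reads after filter: 20
      mean  median   q2.5  q97.5
psi  0.499   0.500  0.256  0.744
p11  0.951   0.965  0.831  0.999
p10  0.033   0.025  0.001  0.112
sensitivity 0.967  specificity 0.954
P(occupied | N=0 of 3): [0.0008]
```

The filter removed all 17 single-replicate contaminant ASVs. The fitted
species was generated occupying about half the sites and detected in every
bottle wherever present: the posterior recovers ψ ≈ 0.5 and a high
true-positive rate, and three empty bottles at a site make true presence
there very unlikely (probability of occurrence 0.0008).

The same stages are scriptable from a shell — `surfmon simulate`,
`decontaminate`, `index`, `occupancy`, `compare`, `regress` — each taking
`--config <YAML>` and `--seed` and writing CSVs plus a JSON run-metadata
sidecar.

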