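# fishbeta

Incidence-based analysis of temporal and spatial biodiversity change in
multi-area species checklists, built for basin-scale freshwater fish fauna
surveyed in two periods (a historical and a current one), but applicable to
any presence/absence metacommunity data.

Regional checklist studies ask three linked questions: how much richness
was lost (alpha and gamma diversity, extirpation rates by area and by
ecological type), how compositional differences among areas are structured
(is beta diversity driven by species *replacement* between areas or by
poorer assemblages being *nested subsets* of richer ones?), and what
geographical drivers explain that structure. `fishbeta` covers the full
workflow: checklist ingestion and incidence-matrix construction, richness
and extirpation accounting, Baselga's pairwise partition of Sørensen
dissimilarity, principal coordinates analysis, permutation Mantel tests,
Chao richness/completeness estimation, and a seeded metacommunity
simulator with known ground truth for validation.

## The core statistic

For two areas sharing *a* species, with *b* and *c* species unique to each
side, total compositional dissimilarity is the Sørensen index

    β_sor = (b + c) / (2a + b + c)

partitioned into a richness-insensitive spatial-turnover component (the
Simpson dissimilarity) and a nestedness-resultant component:

    β_sim = min(b, c) / (a + min(b, c))
    β_sne = |b − c| / (2a + b + c) · a / (a + min(b, c))

so that β_sor = β_sim + β_sne holds exactly for every pair. β_sim = 0
whenever one assemblage is a subset of the other; β_sne = 0 when both
sides contribute equally many unique species. Comparing the two components
across periods distinguishes biotic homogenization from spatial
reorganization.

## Worked example

```python
import fishbeta as fb

truth = fb.generate_metacommunity(fb.SyntheticConfig(seed=1))
print(fb.gamma_richness(truth.historical), fb.gamma_richness(truth.current))
# 210 182

from fishbeta.beta_partition import area_focal_summary, summary_frame
mats = fb.beta_matrices(truth.historical)
print(summary_frame(area_focal_summary(mats))[
    ["group", "beta_sor", "beta_sim", "beta_sne"]].to_string(index=False))
```

```
         group    beta_sor    beta_sim    beta_sne
   Poyang Lake 0.20 ± 0.10 0.07 ± 0.02 0.12 ± 0.10
Ganjiang River 0.25 ± 0.10 0.07 ± 0.05 0.17 ± 0.11
    Fuhe River 0.18 ± 0.09 0.07 ± 0.03 0.11 ± 0.07
Xinjiang River 0.18 ± 0.08 0.07 ± 0.04 0.11 ± 0.09
   Raohe River 0.25 ± 0.11 0.07 ± 0.02 0.18 ± 0.10
   Xiuhe River 0.25 ± 0.10 0.06 ± 0.03 0.19 ± 0.11
          Mean 0.22 ± 0.03 0.07 ± 0.01 0.15 ± 0.04
```

The simulated basin lost 28 of 210 species between periods (gamma 210 →
182). Each row summarizes one area's pairwise dissimilarities to the other
five (mean ± SD); the nestedness component dominates turnover everywhere,
as expected for a community generated with a strong richness gradient and
a small turnover weight. Trait-dependent losses are summarized the same
way:

```python
print(fb.ecotype_loss(truth.historical, truth.current,
                      truth.attributes, "life_habit").to_string(index=False))
```

```
      axis        category  n_historical  n_extirpated  pct_extirpated
life_habit       migration            47            13            27.7
life_habit mountain_stream            24             6            25.0
life_habit      settlement           139            18            12.9
```

Migratory species are lost at roughly twice the resident rate, mirroring
the generator's per-ecotype extirpation probabilities.

## Command line

```
fishbeta simulate --seed 1 --out data/          # emit a synthetic dataset
fishbeta analyze --config run.yaml --out out/   # full two-period pipeline
fishbeta beta / pcoa / mantel / completeness    # single stages
```

`analyze` writes incidence matrices, alpha/gamma tables, per-area
extirpation and ecotype-loss reports, the three beta matrices with area
and species-subset summaries, PCoA coordinates, a Mantel grid against the
geographical drivers, a completeness report, and a manifest recording
every seed and warning.

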