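# darscale

Diversity-area relationship (DAR) scaling analysis for microbiome
abundance tables.

The species-area relationship (SAR), `S = c·A^z`, links the number of
species to the sampled area; in host-associated microbiome surveys the
"area" `A` is the number of accumulated samples — individuals at one
body site, or sites along the digestive tract of one individual.  The
DAR generalises the SAR by replacing richness with the Hill number of
order `q`,

    ^qD = (Σᵢ pᵢ^q)^(1/(1−q)),    ^1D = exp(−Σᵢ pᵢ ln pᵢ),

so that one framework covers richness (q=0), typical diversity
(q=1, exp-Shannon), and dominance-weighted diversity (q=2, inverse
Simpson).  Two accrual models are fit in log-linear form by ordinary
least squares:

* power law (PL):  `^qD = c·A^z`, i.e. `ln D = ln c + z·ln A`;
* power law with exponential cutoff (PLEC):
  `^qD = c·A^z·e^{dA}`, i.e. `ln D = ln c + z·ln A + d·A`.

From the fits come four parameters and their profiles over q:

* **z** — the diversity scaling rate across accumulated units;
* **g = 2 − 2^z** — pairwise diversity overlap (z=0 ⇒ total overlap,
  z=1 ⇒ none);
* **D_max = c·(−z/d)^z·e^{−z}** — maximal accrual diversity, the PLEC
  maximum at `A_max = −z/d` (d<0), a proxy for the potential (regional)
  diversity of the population;
* **RIP = 100·c/D_max** — the percentage of population-level diversity
  carried by one individual (the first accrual unit).

The package implements two resampling designs (inter-individual per
body site with randomly permuted accumulation orders, and intra-DT
across sites in anatomical order with one random sample per site),
permutation tests for pairwise z/D_max differences between sites with
the coded significance-matrix output, multi-level taxonomic collapsing
(phylum…genus), and a seeded synthetic-cohort generator whose
core–satellite occupancy structure can be calibrated, in closed form,
to any target scaling rate.

It is aimed at microbial-ecology analysts who have pre-binned taxon
tables (TSV or BIOM) plus per-sample subject/site metadata and want
reproducible DAR parameter profiles and between-site comparisons.

## Worked example

```python
from darscale import (CohortSpec, generate_cohort, calibrate_occupancy,
                      inter_individual_profiles)

# occupancy shapes whose closed-form richness-accrual slope over
# 1..60 samples is 0.30
beta = calibrate_occupancy(0.30, range(1, 61), 300)       # (1.0, 4.586)

spec = CohortSpec(n_subjects=60, sites=("Stool",), pool_size=300,
                  taxonomy_counts=(14, 30, 60, 120, 400),
                  occupancy_beta=beta, seed=42)
table = generate_cohort(spec)                             # 60 x 300 counts

prof = inter_individual_profiles(table, "Stool", n_resamples=100, seed=1)
print(prof.stats[["mean_z", "se_z", "mean_g", "mean_Dmax",
                  "mean_RIP", "R", "N_success"]].round(3))
```

prints

```
     mean_z   se_z  mean_g  mean_Dmax  mean_RIP      R  N_success
q
0.0   0.313  0.001   0.758    283.652    31.504  0.933        100
1.0   0.292  0.006   0.774     91.017    34.375  0.899        100
2.0   0.287  0.009   0.778     49.761    35.423  0.863        100
3.0   0.280  0.009   0.783     36.448    36.360  0.842        100
```

Reading the q=0 row: richness accrues across individuals with scaling
rate z ≈ 0.31 (close to the calibration target 0.30); any two
individuals share about 76% of their diversity (g); the population's
potential genus richness is ≈ 284 (D_max), of which a single individual
carries ≈ 32% (RIP).  All 100 resampled fits succeeded.  z falls and g
rises with q: individuals differ mostly in which taxa they carry, less
in how abundance is distributed.

The same analysis runs from the shell:

```sh
darscale synth --subjects 60 --seed 42 --out cohort/
darscale inter --table cohort/table.tsv --meta cohort/metadata.tsv \
               --site Stool --levels genus --reps 100 --seed 1 --out out/
darscale test  --table cohort/table.tsv --meta cohort/metadata.tsv \
               --stat Dmax --perms 1000 --seed 7 --out tests_out/
darscale report --profiles out/profiles.tsv --out figs/
```

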