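# rarebiome

Community-ecology analysis of microbial OTU tables, centered on the rare
biosphere: who is rare, who is a habitat specialist, what structures the
community, and how much of its assembly looks neutral.

The package targets the standard workflow applied to amplicon surveys of
soil or sediment bacteria — a samples × OTUs read-count table, a taxonomy,
and sample metadata (habitat / vegetation zone, season, coordinates,
physicochemical covariates) — and reimplements the full chain as a tested,
scriptable Python library with a CLI. A synthetic metacommunity generator
with known ground truth stands in for sequencing data, so every stage has
recovery tests.

## What it computes

* **Rarity partitioning** — each OTU is *rare* (relative abundance < 0.01%
  in every sample), *conditionally rare* (< 0.01% somewhere, never ≥ 1%),
  or *abundant* (the complement), with summary tables and a MultiCoLA
  cutoff-sensitivity profile (Spearman correlation between full and
  truncated Bray–Curtis matrices).
* **Diversity** — ACE, bias-corrected Chao1, Shannon H′ = −Σpᵢ ln pᵢ,
  Simpson D = Σpᵢ², Pielou J = H′/ln S, analytic rarefaction curves, the CV
  of within-group Bray–Curtis dissimilarities, and ANOVA / Bonferroni-t /
  Mann–Whitney group comparisons.
* **Habitat specialization** — Levins niche breadth B_j = 1/Σᵢ P²ᵢⱼ over
  habitats (generalist B > 3, specialist B < 1.5) and Dufrêne–Legendre
  indicator analysis, IndVal = A·B (specificity × fidelity), with
  permutation p-values; *strict habitat specialists* have p < 0.05 and
  A, B ≥ 0.8.
* **Ordination & inference** — NMDS (Kruskal stress-1), ANOSIM
  R = (r̄_B − r̄_W)/(n(n−1)/4), Mantel-style Spearman matrix correlations,
  RDA with log(x+1) transforms, VIF > 20 pruning and forward selection,
  three-block variation partitioning (environment / vegetation / season)
  via adjusted R², and distance-based RDA along taxonomic ranks.
* **Neutral community model** — Sloan's fit of occurrence frequency against
  mean relative abundance, f(p) = 1 − BetaCDF(d; Nmp, Nm(1−p)), estimating
  the migration rate m by bounded least squares, with a 95% Wilson score
  envelope partitioning taxa into above / within / below neutral
  expectation, at the OTU level and per taxonomic rank.

## Worked example

```python
from rarebiome import (MetacommunityDesign, simulate_metacommunity, rarefy,
                       to_relative, classify_rarity, rarity_summary,
                       bray_curtis, anosim, indval, strict_specialist_summary,
                       fit_ncm)

design = MetacommunityDesign(n_otus=2000, depth=12_000, seed=42)
table, taxonomy, meta, truth = simulate_metacommunity(design)
table = rarefy(table, 10_342, seed=42)          # uniform sequencing effort
print(table.total_reads)                        # 165472  (16 x 10,342)

rel = to_relative(table)
print(rarity_summary(classify_rarity(rel), table).round(2))
#                     n_otus  pct_otus  n_reads  pct_reads
# category
# abundant               309     15.45   133728      80.82
# conditionally_rare    1040     52.00    30566      18.47
# rare                   651     32.55     1178       0.71

res = anosim(bray_curtis(table), meta.habitat, n_perm=999, seed=42)
print(f"R = {res.R:.3f}, p = {res.p:.3f}")      # R = 1.000, p = 0.001

iv = indval(table, meta.habitat, n_perm=999, seed=42)
print(strict_specialist_summary(iv).to_dict())
# {'mudflat': 6, 'cordgrass': 3, 'ecotone': 16, 'mangrove': 13, 'total': 38}

fit = fit_ncm(table)
print(f"m = {fit.m:.3f}, R2 = {fit.r2:.3f}")    # m = 1.000, R2 = 0.888
```

The rarity table says most reads sit in a few hundred abundant OTUs while
a third of OTUs never leave the rare tail; ANOSIM R = 1 reflects the
planted habitat structure (every between-habitat dissimilarity exceeds
every within-habitat one); the strict-specialist counts recover a subset of
the planted specialists; and m ≈ 1 is expected here because this generator
adds only multinomial sampling noise around each habitat's expected
composition — fitting neutral simulations with true migration m = 0.1
recovers m ≈ 0.1 (see `tests/test_acceptance.py`).

## Command line

```bash
rarebiome simulate --out-dir data --seed 1            # 4 TSVs + ground truth
rarebiome run -c config.yml                           # full 8-stage workflow
rarebiome classify-rarity -i data/otu_table.tsv -o rarity.tsv
rarebiome ncm -i data/otu_table.tsv -o ncm.tsv
```

`rarebiome run` reads a YAML config (input paths or a `simulate:` block,
rarefaction depth, thresholds, permutation counts, a mandatory top-level
`seed`) and writes per-stage TSVs plus a `manifest.json` recording the
config hash, derived per-stage seeds and wall times. Stages whose outputs
are current are skipped; `--stage` re-runs a subset.

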