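# segscreen

Analysis toolkit for plate-based small-molecule screens scored with
multi-parameter ordinal phenotypic vectors (12 parameters: six general
morphology — E, H, Y, D, A, T — and six segmentation — S, BD, AD, TD, PD,
BS — each rated 0–3 against untreated controls of the same genotype).

The package covers the full desk-side pipeline of such a screen:

- **`segscreen.model`** — score-table data model, TSV I/O, validation,
  dead/unscored-treatment filtering, and embryo-level consensus calling
  (a well shows a phenotype when at least 3 of 5 embryos support it).
- **`segscreen.simulate`** — synthetic screen generator with planted ground
  truth: compound classes (inactive, direct segmentation, segmentation +
  morphology, morphology-only, secondary tail, toxic), threshold dose
  activation, concentration-dependent toxicity and lethality, genotype
  modifiers (*her1* enhancement, *hes6* suppression), and two wild-type
  replicates differing only through noise.
- **`segscreen.qc`** — replicate reproducibility: pointwise Pearson
  correlation of paired scores and normalized Hamming distance.
- **`segscreen.ranking`** — per-treatment SSMD
  (`(seg_mean − morph_mean) / sqrt(seg_var + morph_var)`) and
  mean-difference rankings with exclusion rules, the direct-segmentation
  predicate, compound-level hit calling with a wild-type reproducibility
  filter, genotype classification and concentration-masking summaries.
- **`segscreen.clustering`** — hierarchical clustering of phenotypic
  vectors with correlation distance and deterministic average linkage,
  flat clusters at a correlation cutoff (default 0.6), cluster
  characterization, Newick export, and random pulse-retest candidate
  selection.
- **`segscreen.profiles`** — lethal / any-defect / no-defect concentration
  profiles with a two-way ANOVA (concentration × experiment), and
  bipartite compound–parameter network export (SIF / GraphML, readable by
  Cytoscape).

## Command-line interface

All functionality is exposed through the `segscreen` entry point:

```bash
# generate a synthetic screen with ground truth
segscreen simulate --seed 1 --out sim/

# replicate QC between the two wild-type replicates
segscreen qc --table sim/screen.tsv --a wt_A --b wt_B --out qc.json

# rank treatments (ssmd or meandiff), with an exclusion log
segscreen rank --table sim/screen.tsv --method ssmd \
    --out ranking.tsv --exclusions excluded.tsv

# compound-level hit calls with genotype / concentration profiles
segscreen hits --table sim/screen.tsv --out hits.tsv

# cluster phenotypic vectors at a correlation cutoff of 0.6
segscreen cluster --table sim/screen.tsv --cutoff 0.6 --out clusters/

# pick random pulse-retest candidates from a labeled cluster
segscreen pulse-candidates --table sim/screen.tsv \
    --label seg_plus_morph -k 25 --seed 1

# concentration-dependence profile with two-way ANOVA
segscreen profile --table sim/screen.tsv --out profile.json

# compound-parameter network for one screen slice
segscreen network --table sim/screen.tsv --experiment wt_A \
    --concentration 10 --format graphml --out net.graphml

# table validation report
segscreen validate --table sim/screen.tsv --out report.json
```

## Score table format

Tab-separated, UTF-8, header mandatory:

```
compound_id  plate  well  concentration_uM  experiment  lethal  n_embryos
n_scoreable  E  H  Y  D  A  T  S  BD  AD  TD  PD  BS
```

Scores are integers 0–3 or empty (a row with blank score cells is an
*unscored* treatment, distinct from an all-zero scored-normal one).
`experiment` is one of `wt_A`, `wt_B`, `her1`, `hes6`. Embryo-level tables
carry the same columns plus `embryo_index`, one row per embryo.

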