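# atherocytof

A tested, reusable pipeline for peripheral-immune mass-cytometry (CyTOF)
analysis of coronary atherosclerosis cohorts:

- **`synthetic`** — synthetic cohort generator: per-sample event matrices
  with known cluster structure, group-dependent frequency and marker
  shifts, clinical covariates, per-segment coronary stenosis profiles, and
  full ground truth (cluster labels, mixture weights, planted features,
  injected artifact flags).
- **`preprocess`** — FCS 3.0/3.1 and CSV event I/O, simplified bead-based
  sensitivity-drift normalization, debris/dead-cell/doublet gating (event
  length, DNA intercalator, cisplatin viability), arcsinh transform
  (cofactor 5).
- **`clustering`** — pooled kNN-graph Leiden community clustering with
  weak-edge pruning and small-cluster merging, marker-rule lineage
  annotation (T / B / NK / myeloid / granulocyte; CD4/CD8/γδ/DNT and
  cMon/iMon/ncMon subsets), t-SNE embedding, per-sample frequency tables.
- **`gensini`** — Gensini coronary plaque-burden scoring (severity step
  scores 1/2/4/8/16/32 at 25/50/75/90/99/100% stenosis, canonical segment
  weights).
- **`stats`** — chi-squared contingency tests, one-way ANOVA reconstructed
  from group summaries, pairwise t-tests with Benjamini-Hochberg
  adjustment, Pearson/Spearman correlations, cross-feature correlation
  networks.
- **`models`** — the two random-forest risk models (disease, and disease
  progression): bootstrap class balancing, 1000-repeat stability feature
  selection (importance > 0.04 in > 500 repeats), 70/30 split with 10-fold
  CV ensembles, and evaluation by ROC/AUC, decision-curve net benefit, and
  sensitivity/specificity cutoff analysis.

## CLI

An umbrella command `atherocytof` exposes every stage; the main stages are
also installed standalone (`simulate-cohort`, `preprocess`, `cluster`,
`gensini`).

```bash
# synthesize a cohort (FCS or CSV events, clinical + stenosis CSV, truth JSON)
simulate-cohort --panel myeloid --out cohort/ --seed 7 --format csv

# gate + arcsinh one sample
preprocess --in cohort/NC01.csv --out clean.csv --report report.json

# pooled clustering + annotation + frequency tables
cluster --in cohort/ --k 30 --resolution 1.0 --seed 7 --out clusters/

# plaque-burden scores from long-format stenosis CSV
gensini --in cohort/stenosis.csv --out scores.csv

# group statistics and correlation networks
atherocytof stats-compare --features clusters/cluster_frequencies.csv \
    --meta cohort/clinical.csv --out stats/

# stability selection + ensemble + ROC/DCA for one task (dp or dpp)
atherocytof model-fit --task dpp --features freq.csv --clinical clinical.csv \
    --repeats 1000 --seed 7 --out model/
```

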