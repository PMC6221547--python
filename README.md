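# npemix

Non-parametric EM mixture clustering and missing-data-tolerant
classification for birth-cohort trajectory phenotyping.

Early-life cohort studies collect hundreds of mixed-type measurements per
child — immunoglobulin titres (IgE, IgG, IgG4), skin-prick tests,
respiratory-infection counts, demographics — and ask whether children fall
into latent risk trajectories for asthma and wheeze.  `npemix` implements
the analysis workflow for this question: quality-control filtering and
scaling of the raw table, a non-parametric EM (npEM) mixture model whose
per-cluster, per-feature densities are weighted kernel density estimates,
BIC selection of the number of clusters, a product-of-densities posterior
classifier that handles arbitrarily missing features (including cross-cohort
replication with partially matched feature rosters), and cluster stability
assessment by leave-one-out Jaccard indices and silhouette widths.  A
synthetic cohort generator with latent-cluster ground truth supports
end-to-end validation.

## The model

Subjects are draws from an `L`-component mixture with conditionally
independent coordinates; coordinate `j` under cluster `k` has a free density
`f_jk` estimated by a weighted KDE with a standard normal kernel and a
constant per-feature Silverman bandwidth.  Fitting iterates

* E-step: `P(k|x_i) ∝ λ_k Π_j f_jk(x_ij)`
* M-step: `λ_k = mean_i P(k|x_i)`
* KDE step: re-estimate each `f_jk` with posterior weights

from a seed-controlled k-means initial partition.  `L` is chosen by
minimising `BIC = −2 log p̂ + ν ln N`, `ν = L·M + (L−1)`.  New subjects get
the posterior above with missing features contributing density 1 and
out-of-range values clipped to the training support; assignment requires a
maximum posterior strictly above 0.90.  See `docs/methods.md` for the full
account.

## Worked example

Run the whole pipeline on the default synthetic cohort (220 subjects, three
latent clusters with mixing proportions 0.41/0.49/0.10, ~60 features across
antibody / infection / demographic blocks):

```sh
npemix run-all --seed 1 --out demo_out
cat demo_out/report.txt
```

```
npemix pipeline report
======================
subjects (raw): 220
roster features: 60 (retained after QC: 58)
complete-case subjects: 169
low-missingness subjects: 29 (29 classified at >90%)
total classified: 198
selected L: 3
mixing proportions: 0.515, 0.385, 0.101
cluster sizes: 1: 100, 2: 80, 3: 18
mean silhouette width: 0.098
LOO-individual Jaccard per cluster: 1.000, 1.000, 1.000
LOO-feature Jaccard per cluster: 1.000, 1.000, 1.000
outcome rate by cluster: 1: 25%, 2: 21%, 3: 78%
```

Reading this: two high-missingness features were removed by the >20%
feature filter, 22 heavy-missingness subjects by the >30% subject filter;
169 complete-case subjects trained the model and all 29 low-missingness
subjects cleared the 90% posterior threshold.  The BIC sweep picked three
clusters; the fitted mixing proportions track the generating ones (up to
label order), the small third cluster carries the high outcome rate (78%
vs. 25%/21% — the generator's high-risk analogue), and the partition is
perfectly reproducible under leave-one-out refits despite the modest
silhouette widths typical of many weakly informative features.

The stages are also available individually (`simulate`, `preprocess`,
`fit`, `select-l`, `classify`, `stability`), or from Python:

```python
import npemix

cohort = npemix.generate(npemix.cas_like_default())
summary = npemix.run_pipeline(npemix.RunConfig(
    synthetic=cohort.config, l_max=6, output_dir="demo_out"))
```

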