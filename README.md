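# phylochron

Tools for comparing independently dated time-calibrated phylogenies
(chronograms) and for detecting exceptional diversification-rate shifts
on richness-annotated backbone trees.

The package covers four stages, plus simulators that generate every
input needed to exercise them offline:

1. **`tree_io`** — read posterior samples of rooted ultrametric trees
   (Newick, or NEXUS with translate tables), remove burn-in per input
   file before concatenating runs, and extract per-clade crown/stem age
   posteriors with explicit monophyly and ultrametricity handling.
2. **`calibration`** — fossil calibration priors: exact minimum-age
   arithmetic on a 0.1-My decimal grid, offset-lognormal priors whose
   mean exceedance is a fixed fraction of the fossil age
   (`mu = ln(f * age) - sigma^2/2`, defaults `f = 0.05`,
   `sigma = 0.75`), truncated-normal and uniform priors, and the
   calibration-placement rule that walks rootward to the first node with
   posterior probability >= 0.95 and bootstrap >= 0.70.
3. **`age_compare`** — Gaussian KDE of two node-age posteriors, a
   Monte Carlo distribution of paired age differences (default 100,000
   draws), probabilities of the difference falling within
   {1, 5, 10, 20, 40, 60} My ranges, and 95% highest-posterior-density
   intervals (shortest-window scan). Positive differences mean the
   first-labeled event is older.
4. **`diversification`** — constant-rate birth–death likelihood of the
   backbone (Nee-style, survival-conditioned, factorized per edge) plus
   conditional-geometric probabilities of terminal-clade richness, per-
   class maximum-likelihood fitting (Yule and full BD), AICc model
   selection, and a greedy stepwise search for rate shifts on edges.
5. **`synthetic_data`** — Gillespie birth–death tree simulation,
   clade-size simulation (the independent Monte Carlo oracle for the
   richness likelihood), collapsing resolved trees into richness
   backbones, pseudo-posterior chronogram samples around a base tree,
   and Gaussian age posteriors with known truth.

## CLI

All stages are exposed through one executable with fixed-seed
reproducibility (identical config + seed gives byte-identical output;
TSV outputs carry `#`-prefixed provenance headers):

```bash
# synthetic inputs
phylochron simulate bd-tree --birth 1.0 --n-tips 50 --seed 1 --out tree.nwk
phylochron simulate pseudo-posterior --base-tree tree.nwk --cv 0.05 \
    --n-trees 200 --seed 2 --out sample.nwk
phylochron simulate gaussian-ages --spec fungal:484:23:100000 \
    --spec plant:482:3:100000 --seed 3 --out ages_a.tsv

# extract clade age posteriors from a tree sample (10% burn-in per file)
phylochron extract-ages --trees sample.nwk --burnin 0.10 \
    --clade myclade:crown:t1,t2,t3 --out ages.tsv

# compare two age tables (labels: clade:mode on each side)
phylochron compare --ages-a ages_a.tsv --ages-b ages_b.tsv \
    --pair fungal:crown:plant:crown --seed 4 --out results/

# resolve a calibration table into explicit prior parameters
phylochron calibrate --table calibrations.tsv --out priors.tsv

# diversification-rate-shift search on a richness tree
phylochron shifts --tree backbone.nwk --richness richness.tsv \
    --threshold 4 --seed 5 --out shifts/
```

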