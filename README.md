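# circuc

Circulating miRNA biomarker discovery for case/control blood-fraction
microarray studies.

Blood carries miRNAs in several distinct compartments — platelets,
peripheral blood mononuclear cells (PBMC), and cell-free micro-vesicles —
and the miRNA cargo of each compartment can shift with disease. `circuc`
implements the complete analysis chain used to mine such data for
diagnostic biomarker panels:

1. **Probe-level preprocessing** — GC-matched background subtraction using
   anti-genomic control probes, a `log2(x + 16)` transform, quantile
   normalization within each blood fraction, median summarization of probe
   sets, and technical-replicate averaging.
2. **SAM differential expression** — the two-class unpaired Significance
   Analysis of Microarrays: a variance-stabilized score
   `d_i = (x̄_case − x̄_control) / (s_i + s0)`, a label-permutation null,
   delta/FDR calibration with the median permuted false-call count, and
   per-feature q-values.
3. **Consensus biomarker selection** — SAM repeated on 100 random
   18-of-20-per-arm subsamples (a 9:1 split); features called in ≥ 90 % of
   iterations form the panel.
4. **Nested Monte-Carlo cross-validation** — repeated 18:2-per-class
   train/test splits with the consensus selector re-run *inside* each
   training set (16-per-class inner subsamples), an RBF-kernel SVM
   (`gamma = 1/n_features`, `C = 1`) on standardized selected features, and
   an aggregated confusion matrix yielding accuracy, sensitivity,
   specificity, PPV, NPV, FPR and FNR.
5. **Correlation clusters** — biomarker subgroups whose minimum pairwise
   Pearson correlation exceeds 0.6 (complete-linkage tree, greedy subtree
   validation), plus genomic co-localization of panel members.
6. **Target enrichment** — one-sided Fisher / binomial tests for
   down-regulation of predicted miRNA target mRNAs, and generic
   hypergeometric term enrichment.
7. **qPCR validation arithmetic** — ΔCt normalization against a normalizer
   panel, `2^(−ΔCt)` replicate statistics, Student's t-tests, and paired
   cross-platform concordance tests.

A synthetic-data module (`circuc.synth`) generates probe- and feature-level
case/control datasets with planted fold changes, latent-factor correlation
blocks, and GC-dependent background, so the full pipeline is exercisable
and testable without any external download.

## Worked example

Create a config and run the full pipeline (simulate → SAM → consensus →
nested evaluation → clusters):

```yaml
# demo.yaml
seed: 7
fraction: platelet
simulate:
  n_features: 200
  n_de: 12
  log2_fc_range: [1.0, 1.6]
  noise_sd_range: [0.5, 0.5]
  corr_blocks: [[6, 0.75], [4, 0.75]]
consensus:
  n_iterations: 50
evaluate:
  n_repetitions: 25
```

```bash
circuc run --config demo.yaml --out demo_run
```

`demo_run/summary.json` then contains (abridged):

```json
{
  "sam":       {"n_called": 13, "s0": 0.1112614836, "delta": 0.7206016807, "pi0": 1.0},
  "consensus": {"n_selected": 12, "threshold": 0.9},
  "evaluate":  {"confusion": {"tp": 50, "tn": 50, "fp": 0, "fn": 0},
                "metrics": {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}},
  "cluster":   {"n_clusters": 3, "sample_two_group_misclassified": 1}
}
```

Reading: a single SAM pass at FDR 1 % called 13 of 200 features (12 planted
plus one false call); the resampling consensus kept exactly the 12 planted
features at the 90 % frequency threshold; the nested cross-validated SVM
classified all 100 held-out samples (25 repetitions × 2 cases + 2 controls)
correctly; and the panel resolved into 3 tight correlation clusters
(the two planted blocks plus one spurious pair). Each stage also writes its
full table (`sam.tsv`, `panel.tsv`, `eval.json`, `clusters.json`).

Every stage is also available as a standalone subcommand
(`circuc simulate|preprocess|sam|consensus|evaluate|cluster|enrich|qpcr`)
and as a plain library call.

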