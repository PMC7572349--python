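# cmnet

Analysis pipeline for discovering group-discriminative connections in
**cortical morphological networks** (CMNs). A CMN is a per-subject,
per-hemisphere graph over cortical ROIs whose edge weight is the absolute
difference of an ROI-averaged morphological attribute (maximum principal
curvature, cortical thickness, sulcal depth, average curvature) between two
regions. The pipeline:

1. **synthetic** — generates two-group cohorts of ROI-level (optionally
   vertex-level) attribute values with known injected mean shifts, plus a
   closed-form folded-normal oracle for the population effect size of any
   connection (`expected_connection_effect`, `shift_for_effect`).
2. **cmn** — ROI-averages vertex fields, builds `|m_i − m_j|` distance
   matrices, and vectorizes their strict upper triangle into fixed-order
   feature vectors (595 features for the 35-region Desikan-Killiany
   parcellation shipped in `cmnet.atlas`).
3. **infs** — graph-based infinite feature selection: adjacency
   `A(k,l) = α·max(σ_k, σ_l) + (1−α)(1 − |spearman(k,l)|)`, relevance scores
   from the closed form `(I − rA)^{-1} − I` (row sums), with an explicit
   convergence check on the spectral radius of `rA` (default `r = 0.01`).
4. **cv** — leave-one-out / stratified 5-fold / 10-fold cross-validation of a
   linear max-margin classifier on the top-K connections (default K = 100),
   feature ranking computed on training subjects only, margin cost tuned by
   nested stratified 5-fold grid search; pooled held-out accuracy.
5. **aggregate** — per-scheme feature weights (mean selection score over
   outer training folds, min-max normalized), averaged across CV schemes and
   then across measurements with absent-as-zero contributions; final top-k_f
   edges (default 5) reported as ROI-name pairs.
6. **effects** — Cohen's d per connection,
   `|μ_a − μ_b| / ((σ_a + σ_b)/2)` with sample sds, plus the conventional
   large/medium/small banding (0.8 / 0.5 / 0.2).

## CLI

```sh
cmnet simulate  --config examples/demo.yaml --out cohort.csv --truth-out truth.csv
cmnet build-cmn --input cohort.csv --out cmn/
cmnet select    --input cohort.csv --out scores/
cmnet classify  --input cohort.csv --out clf/ --scheme all --top-k 100
cmnet aggregate --weights-dir clf/ --out agg/ --k-f 5
cmnet effects   --input cohort.csv --out eff/
cmnet run-all   --config examples/demo.yaml --out demo-run
```

`run-all` executes every stage from one YAML config (CLI flags override
config keys) and writes `summary.json` with full parameter provenance,
per-scheme accuracies, and the final top edges with effect sizes; identical
configs and seeds give byte-identical summaries. Cohorts are exchanged as
tidy CSV (`subject_id, group, hemisphere, measurement, roi_name, value`);
FreeSurfer aparc-stats-like whitespace tables can be read with
`cmnet.cmn.read_aparc_stats`.

## Notes

- Feature scores are computed on the raw feature scale by default: a group
  mean shift inflates a connection's pooled standard deviation, which is the
  only route by which group separation enters the (label-free) scoring
  formula. `standardize=True` z-scores features first and is useful for
  bounded adjacencies, but erases that dispersion signal.
- The walk-series scores require spectral radius `ρ(rA) < 1`; divergence
  raises with guidance instead of being silently regularized.
- ROI order (alphabetical FreeSurfer label order) and edge order (row-major
  strict upper triangle) are fixed and define all indexing.
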