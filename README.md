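# nicheflow

Toolkit for discovering and quantifying **metabolic cross-feeding** between
microbes — the situation where one species (here, a yeast) secretes
metabolites that another (lactic acid bacteria, LAB) depends on for growth.
It is aimed at systems biologists who want to combine three independent
lines of evidence for a cross-feeding interaction, plus the small analytic
controls that make the case airtight:

1. **Community constraint-based modeling** (`nicheflow.community_fba`) —
   species stoichiometric models are coupled through a shared environment
   pool under a defined medium. With every member's growth imposed as a
   constraint (μᵢ ≥ μ_min, no optimality assumption), the space of
   inter-species transfers is enumerated by mixed-integer programming: each
   candidate transfer flux *v* is gated by a binary *y* via *v ≤ M·y*, the
   number of open transfers is minimized, and integer cuts exclude found
   sets until exhaustion. Transfers present in *every* feasible set are the
   predicted obligate exchanges.
2. **Exo-metabolome profiling** (`nicheflow.exometabolome`) — untargeted
   ion-intensity time series spanning a yeast *conditioning* phase and a
   subsequent *bacterial* phase are classified by two fold changes,
   fc_accum = peak/initial and fc_deplete = peak/final (peak taken within
   the conditioning phase, ε-floored). Ions with both fold changes ≥ 2 trace
   the bell shape of a compound secreted by yeast and consumed by bacteria;
   bell ions are annotated by accurate mass (±0.005 Da; [M−H]⁻, [M+F]⁻,
   H/Na and H/K exchange, NaCl adducts) to yield candidate cross-fed
   metabolites.
3. **Regulatory association** (`nicheflow.regulation_stats`) — per-gene
   Spearman and Pearson correlations between expression in yeast regulatory
   mutants and LAB growth in their conditioned media; rank-based normal
   scores combined into one z per gene; reporter gene-set enrichment
   against a permutation null (10,000 draws, min set size 5) with
   Benjamini–Hochberg correction. Because the strain panel is tiny (n = 5),
   headline correlations get **exact** permutation p-values by full
   enumeration of all n! rank permutations.

`nicheflow.aux_analyses` adds the control estimators (cell-lysis release
bound, biosynthetic-cost rank test for secreted amino acids, nitrogen-load
proportionality fit), `nicheflow.synthetic_data` generates every input
class with known ground truth, and `nicheflow.pipeline` orchestrates the
stages with a provenance manifest.

## Worked example

The one-command demo simulates all inputs, runs every stage, and reports
the ground-truth recovery checks:

```bash
nicheflow demo --out demo_run --seed 1
```

prints (abridged):

```json
{
  "modeling":     {"n_solutions": 1, "designed_in_all_solutions": true},
  "metabolomics": {"n_ions": 300, "n_bell": 31, "bell_recall": 1.0,
                   "bell_precision": 0.967741935483871},
  "regulation":   {"n_sets_tested": 20, "true_sets_rank_top": true},
  "aux":          {"lysis_release_mM": 3.497472e-06,
                   "release_ratio_vs_observed_0.07mM": 20014.456155760505}
}
```

Reading this: the MILP enumeration found exactly one minimal exchange set
and it contains both designed obligate transfers; every true bell-shaped
ion was recovered by the ≥2-fold filter (one noisy ion was called bell in
excess, hence precision 0.97); the two gene sets constructed to correlate
with LAB growth rank top by q among 20; and lysis of 0.04% dead cells
could explain only 3.5×10⁻⁶ mM of extracellular alanine — about 20,000-fold
less than a typical observed 0.07 mM, ruling out cell death as the source.

The same stages are available piecewise, e.g.

```bash
nicheflow leakage --c-intra 6 --dead-frac 0.0004 --observed 0.07
# {"lysis_release_mM": 3.497472e-06, "observed_over_estimated": 20014.456155760505}
nicheflow costs --secreted thr,gln,ala,glu,ser,gly --metric energetic_atp
# {"ranks": {...}, "rank_sum": 27.0, "p_one_sided": 0.0007223942208462332}
```

— the six secreted amino acids occupy the cheap end of the biosynthetic
cost ranking (exact one-sided rank-sum p ≈ 7×10⁻⁴).

## Layout

```
src/nicheflow/
  model_io.py         plain-text model/medium/TSV formats and validation
  community_fba.py    community assembly, FBA, MILP exchange enumeration
  exometabolome.py    ion annotation, profile classification, candidates
  regulation_stats.py correlations, exact small-n inference, enrichment
  aux_analyses.py     lysis bound, cost rank test, proportionality fit
  synthetic_data.py   ground-truth generators for all input classes
  pipeline.py, cli.py orchestration and command-line entry points
  data/               metabolite reference, cost table, 35-component medium
docs/methods.md       models, assumptions, parameter choices, limitations
```
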