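# Methods

This note documents the models and procedures nicheflow implements, the
parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Community model and exchange enumeration

**Model.** Each species is a stoichiometric network at steady state
(S·v = 0) with flux bounds in mmol·gDW⁻¹·h⁻¹. Compartments are metabolite
suffixes (`_e` environment, `_c` cytosol); exchange reactions are detected
mechanically as single-metabolite boundary reactions on `_e` metabolites,
with positive flux defined as secretion. In the community, species
metabolites are namespaced so nothing internal is shared; each member's
exchange reaction is routed through explicit non-negative variables: import
from the medium (capped per metabolite, with the cap shared across
members), export to waste (uncapped), and pairwise transfer variables
v[met, donor, receiver] for every (metabolite, secreter, up-taker) pair.
Keeping transfers pairwise rather than pooled makes donor/receiver
attribution a property of the certifying flux distribution itself, not a
post-hoc decomposition: a transfer is "present" when its pair variable
exceeds the activity threshold.

**Growth as a constraint.** Feasibility questions impose a lower bound
μᵢ ≥ μ_min on each member's biomass flux. No growth objective is optimized
for enumeration — neither per species nor for the community — so the
enumeration explores the whole feasible exchange space rather than a
single optimal corner.

**Enumeration.** A binary yₖ gates each candidate transfer (vₖ ≤ M·yₖ);
the MILP minimizes Σyₖ subject to all-member growth; after each solve the
active set (by flux, not by y) is excluded with an integer cut
Σ_{k∈active} yₖ ≤ |active|−1 and the problem re-solved until infeasible or
`max_solutions` is reached. Because later solutions under accumulated cuts
need not be subset-minimal, each candidate set is certified by LP deletion
checks (feasibility is monotone in the allowed-transfer set, so testing
single-element deletions suffices); non-minimal sets are cut away without
being reported when `minimal_only` is set. A brute-force oracle
(`brute_force_exchange_sets`) solves the 2^k LP feasibility problems
directly and is used to certify toy ground truth and to test the MILP.

**Parameters.** μ_min = 0.01 h⁻¹ (strictly positive, small against toy
maxima of ~10 h⁻¹); big-M = 1000, matching the conventional bound
magnitude; transfer activity threshold 10⁻⁶; solver: scipy/HiGHS at
default tolerances. Members are sorted by species id during construction,
making results invariant to input order. Both subset-minimal and
all-feasible enumeration modes are exposed because either reading of
"systematically enumerated" is defensible.

**Auxotrophy curation.** `curate_auxotrophies` reproduces the curation
workflow used for fastidious LAB models: add uptake routes (exchange +
transporter) for specified metabolites, append repair reactions, and block
biosynthesis routes by clamping bounds to zero, returning a copy.

## Exo-metabolome profiling

**Fold-change rule.** For each ion, the reference peak is the maximum
intensity within the conditioning phase (boundary inclusive — the phase in
which the yeast is growing);
fc_accum = (peak+ε)/(initial+ε), fc_deplete = (peak+ε)/(final+ε).
ε is 1% of the table's median positive intensity; it regularizes zeros and
near-zeros, at the cost that a raw ratio exactly at the threshold falls
just below it — the threshold comparison itself is inclusive (≥ 2). An ion
is **bell** when both fold changes pass, **accumulating**/**depleting**
when one does, **flat** otherwise. All-zero series are floored to (1, 1)
and flagged low-signal rather than dropped. Classification is
scale-invariant per table (ε scales with the table median).

**Annotation.** Negative-mode adduct offsets are composed from IUPAC
monoisotopic atomic masses in a single editable table
(`masses.ADDUCT_OFFSETS`): deprotonation [M−H]⁻, fluoride attachment
[M+F]⁻, H/Na and H/K exchange followed by deprotonation, NaCl attachment
followed by deprotonation. Every (ion, metabolite, adduct) match within
the tolerance (default 0.005 Da) is reported; accurate-mass annotation is
inherently ambiguous (isomers share formulas) and suppressing secondary
matches would hide that. Shrinking the tolerance can only remove matches.

**Clustering and statistics.** Shape clustering is k-means on per-ion
z-scored profiles (default k = 4, one per archetype; fixed seed;
degenerate inputs produce a warning rather than an error). Differential
secretion between replicate arms is a per-ion two-sample t-test at the
end-of-conditioning timepoint on culture-AUC-normalized tables, BH-corrected
with q < 0.1 as the significance call; ions with zero variance in both arms
get q = 1 and a flag. Culture-AUC normalization divides by the trapezoid
area under the culture density curve, expressing secretion per cumulative
biomass exposure.

## Regulation statistics

**Per-gene correlations** are computed vectorized (Pearson on values,
Spearman as Pearson on midranks) and match textbook formulas to 1e-12;
zero-variance genes are flagged, not dropped.

**Exact small-n Spearman p.** For 3 ≤ n ≤ 8, all n! rank permutations are
enumerated; p is the exact rational fraction of permutations with
ρ ≥ ρ_obs (one-sided-greater) or |ρ| ≥ |ρ_obs| (two-sided). At n = 5 this
gives 1/120 ≈ 0.0083 for ρ = 1 one-sided, 5/120 ≈ 0.0416 for ρ = 0.9
one-sided, and 2/120 ≈ 0.017 for ρ = 1 two-sided. One-sided-greater is the
default for directional secretion→growth claims; two-sided is available.
Ties are midranked, with a logged caveat that the untied-permutation null
is then approximate. n > 8 raises, directing to approximate methods.

**Rank combination.** Each correlation column is midranked across genes
and mapped to normal scores Φ⁻¹(rank/(n+1)); the two scores are averaged.
The variance of the average depends on how correlated the two rankings
are, which is data-dependent, so the default rescaling uses the
empirically estimated correlation ρ̂ between the score vectors
(scale = √((1+ρ̂)/2)); the independence assumption (√2 scaling) is
available via `scaling="sqrt2"`. p is the upper tail of the standard
normal.

**Reporter enrichment.** Set score = mean member z; the null for size k is
the distribution of mean z over `n_perm` draws of k genes without
replacement (one shared null per distinct size); p is the upper-tail
fraction with (r+1)/(n_perm+1) continuity and mid-p handling of exact ties
(a tolerance of 1e-9 absorbs float summation-order noise; a score equal to
the entire null lands at p ≈ 0.5, not 1). Sets below the minimum size
(default 5) after intersection with the measured genes are excluded with a
notice; q is BH across tested sets. Defaults: 10,000 permutations, seed
required for reproducibility.

## Auxiliary estimators

**Lysis bound.** C = c_intra · (dead_fraction · cells/mL/OD · OD ·
V_medium · V_cell)/V_medium with fL→L conversion; defaults 32×10⁶
cells·mL⁻¹·OD⁻¹, 45.54 fL, 1 mL bookkeeping volume. Linear in every
factor. The worked alanine case (6 mM intracellular, 0.04% dead at OD 1)
gives 3.50×10⁻⁶ mM.

**Cost ranking.** The claim "secreted amino acids are biosynthetically
cheap" is operationalized as a one-sided rank-sum test computed by full
enumeration of all C(n,|S|) label assignments (exact under ties via
midranks; n ≤ 20 enumerates in well under a second). The shipped cost
table compiles three literature-derived metrics (respiratory ATP,
fermentative opportunity cost, precursor-inclusive cost); values are
approximate literature compilations and the test is metric-agnostic.

**Proportionality.** `nitrogen_response_fit` is least squares through the
origin; R² = 1 − SS_res/Σy² is reported as-is since a poor through-origin
fit is itself the finding of non-proportionality.

## Synthetic data: what it emulates, what it does not

**Ion tables** use piecewise log-linear archetype geometry (rise to the
phase boundary, fall to the end) with multiplicative log-normal noise —
intensities stay positive and heteroscedastic like FIA-TOF data. Default
grid 0–18 h conditioning (harvest at 18 h) and 24–42 h bacterial phase;
the number and spacing of points per phase is a package choice. Amplitude
default 4 (comfortably above the 2-fold filter), baseline 1000 a.u.,
noise σ = 0.2 on the natural-log scale. Not emulated: isotope patterns,
adduct co-occurrence, detector saturation, batch drift, or correlated
noise across ions — so perfect recovery on noise-free tables shows the
filter logic is right, not that real data will be this clean.

**Toy communities** are built from a carbon source plus per-species
requirement lists: receivers of a designed exchange get an uptake route
but no biosynthesis route for the exchanged metabolite, donors get a
synthesis and secretion route. Before returning, the generator certifies
by exhaustive LP search that every designed exchange appears in every
feasible transfer set, that receivers cannot grow alone in the restricted
medium, and that everyone grows alone in the complete medium. These are
3-species, ~10-reaction models: they certify the enumeration machinery,
not genome-scale model curation.

**Regulation datasets** draw growth uniformly across strains and give
effect-set genes x = ρ·z_g + √(1−ρ²)·ε₁ + σ·ε₂ (expected correlation
ρ/√(1+σ²) ≈ ρ for the default σ = 0.1); the 5-strain default mirrors a
four-knockout-plus-wild-type panel. Real expression data has correlated
genes, batch effects and non-normal noise; the calibration results (null
uniformity, top-ranking of true sets) hold under the generator's
exchangeability, which is exactly what a permutation null assumes.

**Seeding.** Every generator takes one seed; the pipeline fans a global
seed out to per-stage substreams via `numpy.random.SeedSequence.spawn`.
Noise-free generation is bit-identical across reruns.

## Problem sizes

The shipped tests and the acceptance script run at deliberately modest
scale — toy communities with ≤ 12 transfer candidates (where the 2^k
exhaustive oracle is cheap), 10⁴-ion tables, 200-set enrichment panels
with 2,000 permutations over 20 seeds — chosen so the full certification
(MILP vs brute force, classifier vs truth, null calibration) completes in
seconds while exercising every code path at the sizes the statistics need.

## Known limitations

- The bioopt-style model dialect is a compatible simplification; SBML and
  genome-scale models are out of scope (though the formats round-trip and
  `curate_auxotrophies` expresses the published curation recipe).
- Exchange enumeration assumes a single shared well-mixed pool — no
  spatial structure, no dynamics, no dilution.
- The reporter null permutes gene labels, ignoring gene–gene correlation;
  with 5 strains the per-gene correlations themselves are coarse (11
  possible Spearman values), which the exact-p machinery addresses for
  headline claims but the enrichment z-scores inherit.
- The exact Spearman enumeration assumes untied ranks; midranks with ties
  make the p approximate (logged).
- Fold-change calls use single (or pre-merged) series per ion; replicate
  merging upstream of the filter is the caller's responsibility.
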