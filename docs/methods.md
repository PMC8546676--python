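# Methods

## Tracer kinetic model

The package models isotope-tracer incubations with the linear
two-compartment system d[MMHg]/dt = k_m[Hg(II)] − k_d[MMHg], applied
independently to each enriched-isotope pool. Because the system is linear
with a conserved total per pool, the solution is closed-form (exponential
relaxation to the equilibrium share k_m/(k_m+k_d) at rate k_m+k_d); a
numerical ODE integration is kept in the test suite as an independent
oracle, never in the implementation.

Rate constants are estimated from a *single* time point with the
simplified inversions k_m = −ln(1 − P_t/S₀)/t and k_d = −ln(D_t/D₀)/t
(P = product tracer, D = decaying tracer, S₀/D₀ = spikes). These ignore
back-reaction on the newly formed product. The consequence is a known,
testable bias: applied to coupled-model output the k_m estimator is a
lower bound whenever k_d > 0, and the bias is large when k_d·t ≫ 1 (with
k_m = 5.9 × 10⁻³, k_d = 1.78, t = 2 the estimate is ≈ 1.6 × 10⁻³ day⁻¹).
The package exposes both forward models so users can quantify this for
their regime; estimates should be read as *rate potentials* under the
single-time-point protocol, not as unbiased k_m.

Parameters and units: concentrations ng L⁻¹, time days, rate constants
day⁻¹. Defaults mirror the field protocol: spikes of 4 ng L⁻¹ per isotope,
t = 2 d (48-h incubation), triplicates, MMHg detection limit 0.01 ng L⁻¹.

Conventions chosen where the protocol leaves room:

* **Non-detects.** Product ≤ LOD ⇒ non-detect; site means and SE are over
  detected replicates only (n_detected is always reported). An alternative
  policy counting non-detects as zeros is selectable
  (`include_nondetect_as_zero`), defaulting off.
* **Negative k_d.** An apparent tracer gain would give k_d < 0, which the
  decay model cannot represent; it is clamped to 0 with a warning.
* **SE** is sd/√n over the replicates entering the mean.
* **Site comparison** is one-way ANOVA with Tukey HSD pairwise
  comparisons at α = 0.05; Tukey was chosen as the standard post-hoc test
  for all-pairs comparison of site means.
* No isotope-ratio deconvolution: inputs are excess-isotope
  concentrations already.

## Speciation bookkeeping

IHg is THg − MMHg (error if negative); THg is reconstructed as MMHg + IHg
when not measured. Percentages are computed at full precision and rounded
to one decimal only for presentation; small discrepancies against rounded
published concentration tables (e.g. 12.7 vs 12.6% for natural-site
periphyton) are upstream rounding, not model behaviour. Spike fold ratios
divide the spike by the across-site mean ambient concentration,
unrounded.

## HgcA screening

Profile-search scoring is consumed, not re-implemented: the input is a
per-target table of full-sequence bit scores (hmmer `--tblout` layout or
a two-column file). The package's contribution is the classification on
top: score ≥ 100 keeps a candidate, score ≥ 164 together with an exact
match to one of six conserved cap-helix 8-mers marks it *complete*;
candidates ≥ 100 without the motif are *partial* (typically contigs too
short to span the motif region). Motif matching is exact — the motif set
enumerates discrete variants, not a degenerate pattern. Both thresholds
are inclusive. A score ≥ 164 without the motif is kept partial with a
warning rather than trusted as complete. Abundance is 1 × contig mean
coverage per candidate, summed per consensus taxon at the requested rank,
with relative fractions alongside; the sum across taxa always equals the
summed coverage of surviving candidates.

## Consensus taxonomy

Similarity assignment filters hits at E ≤ 1e−20, identity ≥ 40%, query
coverage ≥ 80% (inclusive) and takes the best bit score; exact ties that
disagree resolve to the lowest common ancestor of the tied lineages.
Because the standard 12-column alignment format carries no query-coverage
field, coverage is computed from qstart/qend and the query length taken
from the protein FASTA (a 13th `qcovs` column is used when present).

Clade placement formalises "placed within a distinct clade" as: walk
rootward from the query to the smallest ancestral node containing at
least one reference leaf; assign the rank label if all reference leaves
under that node share it, otherwise leave unassigned. Other query leaves
are ignored throughout, the tree is used as rooted in the Newick (no
re-rooting), and this rule is one reasonable formalisation of the
informal published criterion, validated against exhaustive clade
enumeration on small random trees.

Agreement compares the two assigners at the most specific rank both
reached (family when both are full lineages), with both-unassigned
counting as agreement. On disagreement the similarity label is retained
but flagged *hypothetical* — mirroring how tree-unassigned sequences keep
their alignment-based taxonomy with reduced confidence.

## Community profiling

Counts aggregate by lineage at the requested rank (unassigned → an
explicit "unclassified" taxon) and are normalised per sample. Rare-taxon
lumping merges taxa whose mean fraction across the displayed samples is
strictly below 2% (exactly-2% taxa are kept); a per-sample variant is
available. Bray–Curtis is computed on relative abundances, not raw
counts. PCoA uses Gower double-centering of −D²/2; axes with negative
eigenvalues are dropped and excluded from the explained-variance
denominator, so explained fractions are non-increasing and sum to ≤ 1.
PERMANOVA is one-way, partitioning squared distances into among/within
sums; the p-value uses the +1/+1 convention (minimum 1/1000 at 999
permutations) and the permutation stream is driven by a caller-supplied
seed, making results bit-reproducible. PCoA and PERMANOVA are implemented
in-package to pin these conventions; scikit-bio's implementations serve as
independent cross-checks in the test suite.

## Synthetic data

The generators emulate the study design, not raw reads:

* **Tracer**: coupled-model forward simulation by default (a `simplified`
  mode produces data the estimators invert exactly), multiplicative
  lognormal noise with CV 10% (mean-1 parametrisation — concentrations
  are positive and analytical error scales with level), left-censoring at
  the 0.01 ng L⁻¹ LOD written as `ND` flags, never zeros. Default site
  rates: k_m 2.6/2.9/5.9 × 10⁻³ day⁻¹ and k_d 1.40/2.10/1.80 day⁻¹ for
  natural/flooded/wetland, giving a cross-site mean k_d ≈ 1.77 ± 0.20 and
  a clear natural-vs-flooded contrast.
* **Metagenome fixture**: 16 complete + 8 partial HgcA carriers across
  eight methylator families (Geobacteraceae dominant) plus 50 decoys.
  Decoys are composition-preserving shuffles of true sequences, so
  chance motif hits are possible and counted — a deliberate stress test;
  their scores sit below 100 regardless. Partial carriers are guaranteed
  motif-free. Similarity hits give every carrier an in-family best hit
  plus a weaker out-of-family hit that must not win.
* **Reference tree**: one monophyletic clade per family with queries
  grafted inside; four queries (preferring the families whose assignment
  the consensus flags hypothetical) attach outside all clades, so clade
  assignment leaves them unassigned and overall agreement is 20/24 =
  83.3%.
* **ASV tables**: 27 samples (3 sites × 3 treatments × 3 replicates),
  Dirichlet-multinomial around site-specific phylum compositions
  (Proteobacteria averaging 36.3% across sites, wetland enriched in
  anaerobic methylator families and methanogens), depth 10,000 reads and
  concentration 150 — realistic amplicon-scale values. Treatment labels
  carry no compositional effect, so a treatment PERMANOVA is a true null.

What passing tests on these data do and do not show: they verify the
estimators, classifiers and statistics against known truth and published
desk-scale arithmetic; they do not validate the upstream chemistry,
sequencing, assembly or annotation, nor the biological realism of noise
structure (real periphyton measurements have matrix effects, spatial
heterogeneity and compositional correlations the generators omit).

## Numerical choices and problem sizes

Round-trip and conservation invariants hold to 1e−12. The estimator
calibration check uses 1000 simulated triplicate experiments at 10% CV
(median recovered k_m within 5% of truth). The permutation-test
calibration uses 600–1000 null datasets of 12 samples at 199 permutations
each — the permutation p-value is uniform regardless of the permutation
count, so this measures the same type-I error as 999 permutations at a
fraction of the cost. Clade assignment is validated on 60–80 random trees
of ≤ 12 leaves against exhaustive enumeration.

## Known limitations

* Single-time-point estimation cannot separate k_m from sorption or
  availability kinetics; multi-point time-series fitting and
  transient-availability variants are out of scope.
* The clade-assignment rule is a formalisation of an informal criterion;
  other formalisations (e.g. majority-rule within the clade) would differ
  on mixed clades.
* PERMANOVA is one-way; nested or stratified designs are not modelled.
* The screening consumes external search scores; no profile HMM is built
  or evaluated here.
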