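# Methods

## The multiplicative bias model

Metabarcoding read counts are compositional: sample totals are arbitrary,
so only within-sample proportions carry information.  The model treats the
observed composition of a mock sample as the known composition with each
taxon's proportion multiplied by a taxon-specific efficiency and
re-closed:

    E[observed] = close(expected ⊙ b),    b > 0.

Because closure removes any scalar, `b` is identifiable only up to a
multiplicative constant; all efficiency vectors are geometrically centered
(divided by their geometric mean, so log-entries sum to zero) and read as
"efficiency relative to the average taxon".  The total protocol bias
factorises over workflow steps, `b = b_ext ⊙ b_pcr ⊙ b_seq`, which is what
makes mock communities entering at successive stages informative: insect
pools carry all three factors, DNA pools two, PCR pools one.

Assumptions: bias is multiplicative and consistent across pools of
different composition (no interaction between a taxon's efficiency and the
community around it), replicate samples within a group are exchangeable,
and the expected compositions (individual counts per pool) are exact.

## Estimator

For sample *s* with expected composition `e_s` and observed counts `y_s`,
the compositional error is `center(close(y_s) / close(e_s))`, computed
over the taxa retained by the zero policy.  The group estimate is the
per-taxon geometric mean of these errors over the samples in which the
taxon was expected and observed, re-centered at the end.  This is the
closed form of an ordinary least-squares fit of taxon indicators to the
centered log-ratio errors, chosen for exactness and testability: on
noiseless data built as `close(expected ⊙ B)` it returns `center(B)` to
machine precision, and it is invariant to per-sample depth scaling and to
global rescaling of the true bias.

**Zero policy.**  A taxon expected but observed with zero reads has an
undefined log-ratio.  By default the cell is *excluded* from that sample's
error vector and recorded as a dropout; proportions are re-closed over the
retained subset so compositional invariants continue to hold.  An optional
pseudocount (default 0.5 reads, added before closure) retains all taxa
instead.  Exclusion is the default because dropout in degraded samples is
a qualitative failure better flagged than imputed.  Mixing samples whose
retained subsets differ shifts each sample's centering constant slightly;
in the noiseless limit this residual inconsistency is below 0.005 log
units on the packaged design and is dwarfed by counting noise.

## Bootstrap uncertainty

Uncertainty is estimated by resampling samples (pool replicates) with
replacement within a group — the sample, not the taxon, is the
exchangeable unit — re-running the estimator per replicate (default
1,000).  The log-scale standard error is the standard deviation of the
centered log-efficiency across replicates.

Intervals are **expanded percentile intervals**: with only *n* = 8–16
samples per group, plain 2.5/97.5 percentile intervals of the bootstrap
distribution are systematically narrow (we measured ≈91% coverage at a
nominal 95% on simulated experiments).  The expanded interval (Hesterberg,
*Am. Stat.* 2015) widens the quantile levels to
`Φ(t_{α/2, n−1} · sqrt(n/(n−1)))`, which restored ≈94% coverage in the
same simulations while keeping the percentile form.  The 50% interval is
adjusted the same way.  A group of one sample yields zero standard errors
with a warning.

All bootstrap draws come from a single `numpy` Generator seeded per call;
the replicate index matrix is drawn in one call, so identical seeds give
bit-identical results.

## Partitioning and standard-error propagation

With centered stage estimates `t` (insect pools), `d` (DNA pools), `p`
(PCR pools) over a common taxon set (taxa missing from any stage are
excluded from all components with a warning, and each vector is
re-centered over the common set):

    extraction = center(t / d),  pcr = center(d / p),  sequencing = p.

The re-centered product of the three equals `center(t)` identically — an
invariant tested to 1e−9.  Each component is re-centered after division so
that every reported vector is relative to the same average taxon.

When the three estimates carry equally many bootstrap replicates, the
components are recomputed on paired replicate indices (the stages come
from disjoint sample groups, so pairing arbitrary indices is valid for
independent sums) and SEs/intervals are taken across these component
replicates; the expanded-percentile tail uses the smaller of the
contributing groups' sample counts, which is slightly conservative.
Without aligned replicates, log-variances are added and normal-theory
intervals reported.

DNA and PCR pools were built by destructive extraction and are shared
across the two non-destructive protocols, so the extraction component is
protocol-specific while the PCR and sequencing components differ only by
primer set.

Trajectories start every taxon at 1 and multiply through the components in
workflow order, re-centering after each step; the final step equals the
centered total bias by construction.

## Trait model

Log efficiency is regressed by OLS on: three exoskeleton-hardness
indicators (soft/intermediate/hard), natural-log body volume (volumes span
0.17–26.51 mm³ and efficiencies are multiplicative, so the log scale is
natural; raw volume is a switch), combined primer mismatch, and amplicon
GC fraction.  Mismatch is the *sum* of the forward and reverse
primer-mismatch proportions — the trait table lists both per pair but the
model uses a single mismatch trait, and summation is the simplest rule
that preserves both contributions.

Two encodings are implemented because the categorical parameterisation is
genuinely ambiguous: the default uses all three hardness indicators and no
intercept (every level gets an interpretable multiplicative coefficient);
since the indicators sum to one the column space contains the constant, so
the centered R², adjusted R² and the overall F test against the
intercept-only model apply, with numerator df one less than the number of
columns (5 with six columns).  The alternative is an explicit intercept
with soft as reference.  Neither changes fitted values.

Observations stack the per-run, per-primer bias estimates (taxa × 2
primers × 2 runs), matching the replication structure of the calibration
design; coefficient intervals come from refitting the model to each bias
bootstrap replicate and taking percentile bounds of the exponentiated
coefficients.  Replicate rows with missing taxa are refit on their finite
subset; the procedure is deterministic given the replicates, so no seed
parameter is needed.  Exponentiated coefficients are reported alongside
log-scale estimates: `exp(β)` is the factor by which a unit trait change
multiplies detection efficiency.

Sequence utilities regenerate the molecular traits: mismatch proportion
counts primer positions whose IUPAC degenerate set excludes the template
base (rounded to two decimals, the granularity of the packaged table), and
amplicon length is `end − start` in barcode coordinates, the convention
under which the two packaged primer pairs span 205 bp and 214 bp.

## Richness comparisons

Samples are rarefied to a common depth (default 100,000 reads) by
multivariate-hypergeometric subsampling without replacement, one seeded
draw per sample; samples below the target depth are dropped with a warning
rather than retained, since partial samples would re-introduce the depth
confound.  Group differences in the number of detected taxa are tested
with a one-way ANOVA computed from the standard sums-of-squares
decomposition (all-identical observations report F = 0 with a warning) and
Tukey–Kramer HSD pairwise comparisons whose adjusted p-values come from
the studentized-range distribution; the pairwise table is assembled
directly and cross-checked in the tests against an independent
implementation.

## Synthetic-data generator

The generator emulates the calibration experiment's factor structure:
eight mock pools built from the packaged design table (six pools of 100
individuals and 15 species; two pools of 101 with a 16th species, a
*Bradysia* midge, present only there), sequenced at three workflow entry
points (insect / DNA / PCR pools), with the QuickExtract protocol applied
to pools 1–4 and DNEasy to pools 5–8, two degenerate COI primer pairs and
two replicate runs — 96 samples in all.

Ground-truth step biases are trait-driven: per step,
`log b = X γ + N(0, σ_step²)` per taxon, centered.  The extraction step
uses only the morphological columns (hardness, log volume) since it
precedes amplification; PCR and sequencing use the full per-primer trait
matrix.  Default coefficients encode the qualitative regularities of
non-destructive insect metabarcoding — soft > intermediate > hard
exoskeletons and a positive volume effect at extraction; a strong negative
mismatch and positive GC effect at PCR; small residual effects at
sequencing — at moderate magnitudes (total centered bias spans roughly
30-fold across taxa).  The taxon-level noise default is σ = 0.2 per step.

Counts are multinomial draws at a depth drawn from
`Normal(272,600, 3,762)` — the scale of a MiSeq run delivering ~270k reads
per sample — with optional symmetric-Dirichlet overdispersion and optional
per-cell dropout zeroing applied after the draw (mimicking, qualitatively,
the taxon dropout seen in degraded extracts).  Every sample consumes its
own seed stream derived from the master seed, which makes the invariant
"bias applied at stage *k* affects only samples entering at or before
stage *k*" hold exactly under coefficient toggling, and makes the whole
experiment a pure function of the parameter object.

What the generator does **not** emulate: sequence-level artefacts (reads,
chimeras, ASV inference, classification error), between-run batch effects,
extract degradation over storage (beyond the generic dropout knob),
pipetting error in pool assembly, and any taxon–taxon interaction.
Passing tests therefore demonstrate the statistical machinery recovers
known multiplicative, trait-driven bias under counting noise — not that
real data satisfy the multiplicative model.  Under generator defaults
(no dropout, deep sequencing) every taxon is detected in every sample, so
the richness ANOVA is degenerate by design (F = 0); richness comparisons
become informative when dropout or shallow depths are simulated.

## Numerical choices and problem sizes

* Simplex and centering invariants are enforced to 1e−9; partition
  reconstruction is exact to 1e−9 in log space.
* Noiseless estimator identity holds to 1e−6 over random 16-taxon bias
  vectors (tested over 100 seeds).
* Validation studies use a reduced-depth profile (20,000 ± 500 reads per
  sample, the default trait coefficients, σ = 0.2, 500 bootstrap
  replicates, four replicate experiments) — deep enough that counting
  noise, not depth, limits accuracy, while keeping the full suite fast.
  The trait-CI coverage study uses 200 simulations of 200 parametric
  replicates with response noise σ = 0.3.
* Degenerate inputs fail loudly: empty or all-zero vectors, zero/negative
  entries passed to centering, mismatched taxon sets, unknown pools,
  rank-deficient trait designs (the collinear columns are named), groups
  with no samples.
* Ties in bootstrap quantiles follow `numpy.nanquantile`'s linear
  interpolation; replicate columns that lose a taxon entirely propagate
  NaN and are ignored by nan-aware reductions.

## Known limitations

* The estimator's per-cell log-ratio carries the usual small-count Jensen
  bias (≈ −1/(2·count)); at the default depths this is well below the
  bootstrap standard errors but would matter for very rare taxa at shallow
  depths.  The pseudocount policy mitigates it.
* Mixing samples with different retained taxon subsets (dropout, or taxa
  absent from some pools by design) introduces a small centering
  inconsistency, documented above.
* Bias estimates for taxa present in few pools (the *Bradysia* midge
  appears in two of eight) rest on correspondingly few samples and carry
  wide intervals.
* The pipeline treats replicate runs as exchangeable replicates unless the
  user restricts a group by run; systematic run effects would be absorbed
  into the bootstrap spread, not modelled.
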