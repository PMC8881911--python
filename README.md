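# mockbias

Quantitative taxon-bias analysis for DNA metabarcoding mock communities.

Metabarcoding reports the *relative* abundance of each taxon in a bulk
sample, but every laboratory step — DNA extraction, PCR amplification,
library preparation and sequencing — over- or under-represents some taxa.
`mockbias` estimates that bias from mock communities of known composition,
splits it multiplicatively into per-step components, relates it to insect
traits (body volume, exoskeleton hardness, primer mismatch, amplicon GC
content), and ships a synthetic-data generator with known ground truth so
the whole pipeline can be validated end to end.

It is aimed at entomologists and molecular ecologists running insect
metabarcoding (biosecurity surveillance, biodiversity monitoring) who want
to measure — and potentially correct — the quantitative bias of a
non-destructive extraction workflow.

## The model

For a sample with true composition `x` (proportions over taxa), the
multiplicative bias model says the sequenced composition is, in
expectation,

```
observed  ∝  x ⊙ b,          b = b_extraction ⊙ b_pcr ⊙ b_sequencing
```

where `⊙` is the element-wise product and `b` is a vector of per-taxon
detection efficiencies, identifiable only up to a scalar.  All efficiency
vectors are therefore *geometrically centered* (divided by their geometric
mean): each entry is the efficiency relative to the "average" taxon.

The estimator is the closed form of a least-squares fit on centered
log-ratios: for each sample the *compositional error*
`center(observed / expected)` is computed, and the per-taxon geometric
mean of these errors over the replicate samples of a group is the centered
bias estimate.  Uncertainty comes from bootstrap resampling of samples
(1,000 replicates by default) with small-sample-adjusted (expanded)
percentile intervals.

Mock communities entering the workflow at successive stages isolate the
per-step components: whole-insect pools carry the total bias, pooled
genomic DNA skips extraction, pooled amplicons skip extraction and PCR, so

```
b_extraction = center(b_insect / b_dna),   b_pcr = center(b_dna / b_pcr-pools),
b_sequencing = b_pcr-pools
```

and their re-centered product reconstructs the total exactly.  A log-scale
OLS regression of efficiency on traits (hardness indicators, log body
volume, primer mismatch, amplicon GC) quantifies which traits drive each
component.

## Worked example

Simulate a full two-protocol, two-primer experiment with known truth,
estimate the total bias of the DNEasy insect pools, and partition it:

```python
import mockbias as mb

params = mb.SimulationParams(seed=42, depth_mean=50_000, depth_sd=1_000)
exp = mb.simulate_experiment(params)

pr = "fwhF2-fwhR2n"
total = mb.bootstrap_bias(exp.counts, exp.meta, params.design,
                          {"stage": "insect", "extraction": "dneasy", "primer": pr},
                          n_boot=1000, seed=1)
dna = mb.bootstrap_bias(exp.counts, exp.meta, params.design,
                        {"stage": "dna", "primer": pr}, n_boot=1000, seed=2)
pcr = mb.bootstrap_bias(exp.counts, exp.meta, params.design,
                        {"stage": "pcr", "primer": pr}, n_boot=1000, seed=3)
part = mb.partition_bias(total, dna, pcr, protocol="dneasy", primer=pr)

print(total.to_frame().round(3).head(4))
print(mb.trajectory(part).round(2).loc[
    ["Carpophilus truncatus", "Diuraphis noxia", "Acizzia solanicola"]])
```

prints

```
                        efficiency  se_log  ci_lo  ci_hi  n_dropout
taxon
Carpophilus davidsoni        0.481   0.006  0.475  0.488          0
Carpophilus truncatus        0.388   0.019  0.373  0.410          0
Bactrocera tryoni            3.656   0.008  3.581  3.725          0
Bradysia nr. ocellaris       1.250   0.023  1.167  1.299          0

                       start  extraction   pcr  sequencing
taxon
Carpophilus truncatus    1.0        0.44  0.40        0.39
Diuraphis noxia          1.0        1.27  1.30        1.27
Acizzia solanicola       1.0        0.89  1.48        1.77
```

The first table is the centered total bias of the insect pools: the
hard-bodied beetle *Carpophilus truncatus* yields ~0.4× the reads of the
average taxon, while the large fruit fly *Bactrocera tryoni* is
over-represented ~3.7×, each with a bootstrap standard error (log scale)
and a 95% interval.  The trajectory table tracks each taxon's relative
abundance through the workflow: *C. truncatus* loses most of its signal
already at DNA extraction (1.0 → 0.44) and stays low, whereas the psyllid
*Acizzia solanicola* gains mainly at the PCR step (0.89 → 1.48).

Applying the estimated bias to the known compositions predicts what the
sequencer should report; on this experiment the prediction reduces the
observed-vs-expected RMSE from 5.3 to 0.08 percentage points.

The same analysis runs from the shell:

```sh
mockbias simulate --out data/ --seed 42
mockbias run --counts data/counts.tsv --meta data/meta.tsv \
             --design data/design.tsv --traits data/traits.tsv \
             --n-boot 1000 --seed 1 --out results/
```

which writes `bias_estimates.tsv`, `partition.tsv`, `trajectories.tsv`,
`trait_models.tsv`, `rmse.tsv` and a machine-readable `summary.json`.

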