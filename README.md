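# rateseq

Absolute per-transcript mRNA degradation and synthesis rates from
metabolic-labeling RNA-seq time series.

## The problem

Pulse a culture with a thiolated nucleotide (4tU/4sU), pull down the
labeled RNA at several time points, sequence it, and the labeled fraction
of each transcript rises toward a plateau.  With first-order decay and
zeroth-order synthesis the labeled abundance follows

    Y(t) = Y_eq · (1 − e^(−α(t − t_d)))

where α = α_RNA + α_growth is the total removal rate (degradation plus
dilution by cell division, α_growth = ln 2 / doubling time), Y_eq the
equilibrium labeled level, and t_d a short delay before labeled molecules
are detectable (2 min by default).  Half-life is ln 2 / α_RNA and, at
steady state, synthesis balances removal: k = α · [mRNA].

Sequencing gives relative counts, so each library carries constant-mass
thiolated **spike-ins**: gene counts are divided by spike-in counts,
cross-calibrated between spike-ins with per-replicate scaling factors, and
restored to count scale.  Because the spike-ins' mutual ratios should be
constant over time, a time point where any ratio strays more than a
configurable fold from its median is excluded wholesale — a built-in
detector of failed pull-downs and pipetting artifacts.

Per transcript, both replicates' normalized points are pooled and fit by
weighted nonlinear least squares with 1/Y weights (count variance grows
with the mean, so the plateau must not dominate).  95% CIs come from a
percentile bootstrap that resamples observations and re-estimates α with
Y_eq frozen.  A Wilcoxon–Mann–Whitney test per functional category
(BH-adjusted) asks whether a gene set decays nonrandomly fast or slow.

A seeded simulator generates count matrices with known kinetic truth —
saturating labeled counts, constant-mass spike-ins whose read share
declines as labeling accumulates, negative-binomial overdispersion, and
injectable spike-in artifacts — so the whole pipeline is testable without
any external data.

## Worked example

```sh
rateseq simulate -n 200 --seed 11 -o demo
rateseq all --counts demo/counts.tsv --spikeins demo/spikeins.tsv \
    --config demo/config.yaml --n-bootstrap 250 -o demo_out
```

prints

```
simulated 200 transcripts -> demo
200/200 transcripts fit, 0 time points excluded -> demo_out
```

and `demo_out/estimates.tsv` begins

```
transcript_id  alpha_total  alpha_rna  half_life  ci_low    ci_high    y_eq     ...  converged
gene0000       0.338933     0.332001   2.08778    0.246018  0.481758   2217.26  ...  True
gene0001       0.0678389    0.0609074  11.3803    0.061267  0.0748725  60533.1  ...  True
```

`alpha_total` (per minute) is the fitted labeling rate; `alpha_rna`
subtracts the dilution constant 0.0069 (100-min doubling); `half_life`
(minutes) is ln 2/α_RNA — gene0000 turns over in ~2 min, gene0001 in ~11.
Against the simulator's truth table this run recovers the half-life
distribution with a median fitted half-life of 9.6 min and a median
absolute α error of 26% — the information limit set by the overdispersed
counts (see `docs/methods.md`).  Adding `--abundances` (mRNAs/cell per
transcript) fills the `k_synthesis` columns; `--go-map` adds a per-category
enrichment table.  `rateseq plot --transcript gene0001 ...` draws the data,
the fitted curve and dashed CI-bound curves.

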