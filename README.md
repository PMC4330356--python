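# remethyl

Tile-based analysis of genome-wide DNA methylation loss and recovery after a
transient loss of maintenance methylation, with a synthetic-data simulator of
the underlying inheritance dynamics.

## The problem

DNMT1 copies CpG methylation onto the newly replicated strand at every cell
division. When DNMT1 is switched off, methylation is passively diluted
(halved per division); when it returns, most of the genome is rebuilt by the
combined action of maintenance and de-novo (DNMT3) activity. Two kinds of
sequence do **not** come back: the germline differentially methylated domains
(gDMDs) of imprinted genes, whose unmethylated allele is immune to de novo
methylation, and *gDMD-like* sequences — non-imprinted loci whose methylation
depends solely on uninterrupted maintenance. Finding gDMD-like loci from an
RRBS time course (control → d0, the end of suppression → d21, after
recovery) is the analysis this package implements, for epigenomics
researchers who want the whole chain — simulation, tiling, testing,
trajectory classification, annotation, ranking — as tested, importable code.

## The model

Per locus class, mean methylation *m* evolves per division as

    m' = [ m + m·(ρ + (1−ρ)·δ) + (1−m)·δ·I ] / 2,   I = 1(m ≥ θ)

with maintenance efficiency ρ (0 while DNMT1 is suppressed), de-novo rate δ,
and a de-novo gate θ that keeps fully unmethylated sequences immune to
remethylation. Limits: ρ=δ=0 gives passive halving; ρ=0 with the gate open
gives the closed form m_t = δ + (m₀−δ)/2^t (a retention plateau at δ); the
general fixed point is m* = δ/((1−ρ)(1−δ)+δ). Imprinted gDMDs are simulated
as two alleles (m₀ = 1 and 0) with δ = 0.

The analysis side follows the standard RRBS recipe: 100 bp step-wise tiles
(≥1 CpG, ≥20× coverage in every sample; tile methylation = unweighted CpG
mean; sample level = replicate mean), Fisher's exact test on pooled counts
with Benjamini–Hochberg FDR (q < 0.01) or Welch's t-test (P < 0.05), both
gated on a ±20-percentage-point difference; retention classes at d0;
pattern classification of control→d0→d21 trajectories (P1 full de/re,
P2 partial/full, P3 no recovery, P4 incomplete recovery, STABLE, HYPER);
HOMER-style priority feature annotation, CGI and repeat context; candidate
genes ranked by mean percent methylation loss.

## Worked example

```python
from remethyl.reporting import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=0))      # stock 2 x 5 Mb genome, ~40k CpGs
print(res.matrix.group_means().join(res.true_class)
         .groupby("true_class").mean().round(3))
```

prints (seed 0):

```
                     control     d0    d21
CGI_PROMOTER_UNMETH    0.023  0.019  0.018
GDMD_LIKE              0.896  0.034  0.103
GENIC_BODY             0.801  0.123  0.775
IMPRINTED_GDMD         0.491  0.022  0.019
RE_IAP                 0.945  0.255  0.978
RE_LINE                0.946  0.040  0.979
RE_SATELLITE           0.851  0.332  0.980
RE_SINE                0.900  0.302  0.980
...
```

Reading it: imprinted gDMDs sit at the 50% allele average in control, lose
everything at d0 and never recover; SINE/IAP/satellite repeats retain their
~25–33% de-novo plateau at d0 and rebuild fully; LINE-like repeats fall near
zero but also rebuild; gDMD-like loci recover only partially (0.90 → 0.10)
and are exactly what `res.candidates` surfaces in its top loss bin, flagged
against the known-imprint catalogue. `examples/` holds one short script per
capability; the `remethyl` command exposes the stages
(`make-genome`, `simulate`, `tile`, `diff`, `run`) for shell use.

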