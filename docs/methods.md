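# Methods

## Inheritance model

DNA replication is semiconservative: each daughter duplex keeps one parental
strand with its methylation and one new strand that starts unmethylated.
The new strand gains methylation at a CpG dyad by maintenance (probability
ρ, requiring a methylated template) or de novo (probability δ). Averaging
the two daughters gives the per-division recurrence for locus-mean
methylation m:

    m' = [ m + m·(ρ + (1−ρ)·δ) + (1−m)·δ·I ] / 2

The indicator I implements a de-novo gate: de novo acts only while the locus
retains methylation (m ≥ θ). This encodes the observation that completely
unmethylated gDMD sequences are immune to remethylation — a partially
methylated state appears to be required for de novo/maintenance cooperation.
The gate is evaluated per allele on its current methylation.

Consequences used throughout the tests:

* ρ = δ = 0 → passive halving (m' = m/2);
* ρ = 0, gate open → m' = (m+δ)/2, closed form m_t = δ + (m₀−δ)/2^t with
  plateau δ — the "retention" level a class keeps without DNMT1;
* ρ = 1, δ = 0 → perfect maintenance (m constant);
* general fixed point m* = δ / ((1−ρ)(1−δ) + δ).

Time course: the suppression phase runs `divisions_off = 8` divisions with
ρ = 0 (protein is gone after ~3 of the 6 treatment days at roughly 2
divisions/day, so ~8 divisions happen without maintenance, diluting to
1/256); recovery proceeds at `divisions_per_day_on = 2`. Division counts are
not measured quantities for this cell system and are exposed as
configuration.

Two de-novo rates per class are supported: `delta` during the off phase and
`delta_on` during recovery (default: equal). The split reflects
DNMT3/DNMT1 cooperativity — de-novo efficiency differs with and without
maintenance present — and is needed to reproduce the LINE phenotype
(near-zero retention at d0, yet full recovery by d21), which no single rate
can produce since the d0 plateau *equals* the off-phase δ while recovery
speed is driven by the recovery δ.

### Class defaults

| class | m₀ | ρ_on | δ_off | δ_on | behaviour |
|---|---|---|---|---|---|
| IMPRINTED_GDMD | alleles 1.0/0.0 | 1.0 | 0 | 0 | 50% average; total loss, no recovery |
| GDMD_LIKE | 0.90 | 1.0 | 0.02 | 0.004 | near-total loss, partial recovery (~0.10) |
| RE_LINE | 0.95 | 1.0 | 0.03 | 0.25 | near-zero at d0, full recovery |
| RE_SINE | 0.90 | 1.0 | 0.30 | 0.30 | ~30% retention, full recovery |
| RE_IAP | 0.95 | 1.0 | 0.25 | 0.25 | ~25% retention, full recovery |
| RE_SATELLITE | 0.85 | 1.0 | 0.33 | 0.33 | ~33% retention, full recovery |
| GENIC_BODY | 0.80 | 0.966 | 0.12 | 0.12 | steady state ≈ m₀, recovers to ≈0.78 |
| INTERGENIC | 0.75 | 0.960 | 0.10 | 0.10 | steady state ≈ m₀, recovers to ≈0.70 |
| CGI_PROMOTER_UNMETH | 0.005 | 1.0 | 0.25 | 0.25 | below the gate: stays unmethylated |

For classes that sit below full methylation at steady state (genic,
intergenic) ρ_on is set slightly below 1 so that the recurrence's fixed
point equals the class's initial methylation; with ρ_on = 1 any δ > 0 would
drive recovery to 1.0 and mislabel these classes as gaining methylation.
The retention plateaus of SINE/IAP/satellite (δ between 0.25 and 0.33) match
the ~22–35% range this experimental system shows; gDMD-like recovery
(δ_on = 0.004) reproduces partial-but-incomplete remethylation, placing
those genes in the top loss bin next to the imprints.

A small HYPER-prone set (1% of intergenic loci; m₀ = 0.10, δ_on = 0.35)
models the minority of tiles that *gain* methylation across the transient
suppression. The mechanism of such gains is not established; the class
exists so the hyper branch of the pipeline is exercised, not as a
mechanistic claim.

Gate threshold θ defaults to 0.01. It must lie below the smallest off-phase
plateau of a recovering class (gDMD-like: δ = 0.02), otherwise the gate
closes mid-suppression and extinguishes the class's recovery entirely; 0.01
also keeps the unmethylated CGI promoters (m₀ = 0.005) immune, which is the
gate's purpose.

## Noise model

Coverage per CpG is negative-binomial (mean 30, dispersion 5; variance
mean + mean²/dispersion), chosen so most tiles pass the 20×-per-sample
filter while a realistic minority fails it. Methylated reads are binomial
in the coverage, with a clamped Gaussian per-CpG jitter (sd 0.05) on the
class-level fraction. Imprinted loci split coverage binomially between the
two alleles and draw counts per allele. Replicates default to control 3 /
d0 3 / d21 4.

## Synthetic genome

Coordinate-only (no nucleotide sequence — nothing downstream needs it):
2 × 5 Mb chromosomes, ~4,000 loci (including 15 imprinted and 75 gDMD-like
genes, mirroring the catalogue sizes of the experiment modelled), ~40,000
CpGs, all placements seeded. Loci are non-overlapping with a minimum
inter-locus gap of 1,200 bp — deliberately larger than the ±1,000 bp
promoter/TTS annotation windows, so a locus's tiles can never be captured
by a neighbouring gene's windows and gene-level attribution on the truth
set stays unambiguous. Genic loci expand into 5'UTR/exon/intron/3'UTR
blocks plus promoter-TSS and TTS windows; gDMD/CGI loci contribute a single
promoter window around their midpoint.

What the simulation does **not** emulate: sequence composition and true
RRBS fragment selection (CpG sites are uniform within loci), linked
hemimethylation and strand asymmetry, active demethylation, overlapping
genes, chromatin state, and between-replicate batch structure beyond
i.i.d. noise. Tests passing on this generator therefore validate the
analysis logic and its statistical behaviour under a known truth — not
performance on the full complexity of real bisulfite data.

## Analysis choices

* **Tiling**: "step-wise" 100 bp windows are non-overlapping and aligned to
  multiples of the width. Tile methylation is the *unweighted* mean of CpG
  fractions. The 20× rule is interpreted as the tile's mean CpG coverage in
  every sample; a stricter every-CpG-≥20× variant is available
  (`cov_rule="each_cpg"`).
* **Differential**: the count recipe pools replicate reads per group and
  applies a two-sided Fisher exact test with BH-FDR at q < 0.01 — exact and
  equivalent to a two-group no-covariate logistic model; the t recipe is
  Welch at P < 0.05. Both additionally require |Δ| ≥ 20 percentage points;
  a significant p with a smaller difference is reported stable. Tiles with
  zero within-group variance but distinct means are flagged and decided by
  the effect-size gate alone.
* **States/retention**: HIGH > 0.80, LOW < 0.20, INTERMEDIATE inclusive in
  between (an exact partition). Retention of "original levels" is the ratio
  m_d0/m_control among tiles that lost ≥ 0.20 absolute; the absolute
  40–74% band is reported separately since both readings are informative.
  Zero-control tiles are excluded (undefined ratio).
* **Patterns**: thresholds low = 0.20, partial_hi = 0.75, recovery tolerance
  = 0.20. The gain rule (HYPER: m_d21 ≥ m_control + 0.20) is evaluated
  first, then STABLE, then P1–P4; the classification is total — every
  triple receives exactly one label, verified on a grid.
* **Merging**: hypomethylated tiles merge into consecutive regions when
  separated by at most 500 bp (inclusive); a linear pass verified against a
  union-find oracle.
* **Annotation**: any-overlap with fixed priority promoter-TSS > TTS >
  5UTR > 3UTR > exon > intron > noncoding > intergenic, ties broken by
  longest overlap; windows ±1,000 bp around TSS/TTS; CGI membership is any
  overlap; repeat proximity threshold 1,000 bp (distance 0 iff overlapping).
* **Ranking**: per tile, loss% = 100·(m_control − m_d21)/m_control; per
  gene, the mean over its tiles; bins [85,100], [70,85), [50,70), [20,50),
  [0,20). The imprint flag comes from a supplied catalogue (the simulator's
  truth here; a real run would pass a published imprint list).
* **Reporting**: fractions in [0,1] internally; percentages only at the
  reporting surface, rounded half away from zero (this single rule
  reproduces every verifiable printed ratio the package emulates, e.g.
  5063/7423 → 68%, 3688/9884 → 37.3%). Every (count, total, percent)
  triple in a report is re-checked against the rule at generation time.

## Parameter fitting

`fit_dynamics` least-squares fits (ρ, δ, m₀) to an observed trajectory
(≥3 timepoints), with ρ = 0 fixed during the off phase, a single δ for both
phases and the gate open — the identifiable reduced model. Multi-start
(12 corners) local optimisation with tight tolerances recovers
model-generated trajectories to machine precision; on default-noise
simulations pooling 5,000 CpGs the absolute errors on δ and ρ are well
below 0.05. A constant-zero trajectory is degenerate (δ = 0, ρ carries no
information) and is flagged rather than fitted; ρ is likewise reported but
not asserted when the generating ρ is 0, since trajectories that never
rebuild contain no maintenance signal.

## Problem sizes and determinism

The stock genome (2 × 5 Mb, ~40k CpGs, 10 samples) runs the full pipeline
in a few seconds; tests use a further-reduced genome where class-level
rates are not being measured. All randomness flows from explicit seeds
(genome layout, simulation, and every analysis stage is deterministic given
its inputs); reports regenerate byte-identically under a fixed
configuration.

## Known limitations

Fisher on pooled counts ignores replicate overdispersion, so its q-values
are anti-conservative on real data relative to the ±20-point gate, which in
practice dominates the calls (the Welch recipe is the replicate-aware
alternative). The per-class trajectory is deterministic — within-class
heterogeneity enters only through observation noise, not through locus-level
rate variation. Repeat proximity statistics on the stock genome are muted
because the minimum inter-locus gap exceeds the 1 kb proximity threshold
(a trade-off for unambiguous gene attribution; supply a custom genome with
`min_gap < 1000` to exercise proximity structure).
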