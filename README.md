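# nucleofind

Nucleosome position detection from strand-specific short-read data.

`nucleofind` locates individual nucleosomes in MNase mononucleosome
sequencing experiments: chromatin is digested with micrococcal nuclease,
the ~150 bp protected fragments are end-sequenced, and the resulting short
reads are mapped back to the genome. Each nucleosome then leaves a
distinctive strand-specific footprint in the read **5′-start** counts — a
peak of forward-strand starts just upstream, a peak of reverse-strand
starts just downstream, and a read-depleted stretch of bound DNA in
between. Generic peak callers built for transcription-factor ChIP-seq blur
this structure; `nucleofind` models it explicitly, which lets it separate
closely spaced (even overlapping) nucleosomes at base-pair resolution and
operate at low coverage.

## The model

Only the 5′-most coordinate of each read on its strand is used. For a
candidate binding-region start *i* with binding length *b* and support
length *s*, three region counts are taken:

- *X*<sub>fwd</sub>(*i*): forward-strand starts in `[i − s, i − 1]`
- *X*<sub>bind</sub>(*i*): both-strand starts in `[i, i + b − 1]`
- *X*<sub>rev</sub>(*i*): reverse-strand starts in `[i + b, i + b + s − 1]`

Each count is assumed Poisson and compared against a **robust local
background rate** λ̃<sub>bg</sub>(*i*), estimated per strand from a large
window (2*w*<sub>bg</sub> + 1 bp, default 2001 bp) and capped at a Poisson
quantile of the adjacent non-overlapping window so that isolated artefact
peaks cannot inflate it. The comparison is a two-Poisson likelihood-ratio
statistic

W = 2 { x₀(ln x₀ − ln t₀) + x₁(ln x₁ − ln t₁) + (x₀+x₁)(ln[t₀+t₁] − ln[x₀+x₁]) },

asymptotically χ²₁ under equal rates. The support counts are first
**cross-truncated** (each strand's count capped at a Poisson quantile of
its partner's) so that a one-sided pile-up without a matching partner peak
scores weakly. Signed square roots of the three W values — positive when
the region deviates in the nucleosome-like direction (enriched supports,
depleted binding region) — are summed into the nucleosome score

S(*i*) = S<sub>fwd</sub>(*i*) + S<sub>bind</sub>(*i*) + S<sub>rev</sub>(*i*).

Because truncation couples the terms, significance is not taken from the
N(0, 3) asymptotics: instead an **empirical null** S ~ N(μ̄, σ) is fitted,
with μ̄ the median of valid scores and σ the maximum-likelihood scale of a
truncated half-normal fitted to below-median deviations (lowest τ percent
excluded). Upper-tail p-values are corrected by Benjamini–Hochberg (or an
adaptive variant) and positions with q ≤ FDR are reported greedily by
descending score with a minimum start separation.

Defaults (*b* = 128, *s* = 17, *w*<sub>bg</sub> = 1000, γ = 0.9, τ = 5,
FDR = 0.05) target mononucleosome data where only the most stable
particles protect the full 147 bp; `--b 147 --s 10` restores the canonical
footprint. See `docs/methods.md` for the full account.

## Worked example

Simulate 200 kb of chromatin (stable, phased, fuzzy and nucleosome-free
regions; ~20 reads per nucleosome with 20% uniform background), then call
nucleosomes:

```bash
nucleofind simulate --genome-length 200000 --n-reads 20000 --seed 1 --out-prefix sim
# INFO nucleofind: 20000 reads from 979 planted dyads

nucleofind call sim.reads.bed sim.sizes.tsv --out-prefix run
# INFO nucleofind: 475 predictions (null mu=-0.233 sigma=1.860)

head -4 run.predictions.tsv
# chrom  start  dyad  score               p                      q
# sim1   29     93    8.434816827911002   1.589209495496014e-06  0.0004042079523544323
# sim1   34     98    6.836802819654746   7.235426333640394e-05  0.006705655983950155
# sim1   39     103   6.788326162857101   8.035063315702265e-05  0.007215290329131475
```

Each row is one called nucleosome: `start` is the binding-region start,
`dyad` = start + ⌊b/2⌋ is the reported nucleosome centre, `score` is S,
and `p`/`q` are its empirical-null tail probability and FDR-adjusted
value. The first three rows are overlapping calls 5 bp apart — alternative
positions of one well-supported nucleosome, which the default
`--min-sep 5` deliberately permits; `--non-overlapping` collapses them.
The run also writes `run.scores.bedgraph` (the S track), a BED6 version of
the calls, and `run.config.json` with the fully resolved parameters.

Downstream analyses: `nucleofind motif` (position-specific dinucleotide
χ² profile around called dyads, given a genome FASTA), `nucleofind phase`
(TSS/TES phasing profiles from a GFF3), and `nucleofind sweep` (treatment
vs control prediction counts over a (b, s) grid with the Pareto-optimal
front marked).

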