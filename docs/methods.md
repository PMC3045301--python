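# Methods

This note documents the statistical model, the defaults and why they are
set where they are, the numerical choices, what the simulator does and
does not emulate, and the known limitations.

## Read representation

Only the 5′ end of each mapped read on its strand carries information
about fragment boundaries: the leftmost aligned base for forward-strand
reads, `start + length − 1` for reverse-strand reads. All internal
coordinates are 0-based; BED is read/written 0-based half-open and GFF3 is
converted from 1-based inclusive on input. Duplicate reads are kept by
default (`--dedup` collapses identical chrom/strand/5′ triples). Reads on
unknown chromosomes or with out-of-bounds 5′ ends are skipped, logged and
counted, so total counts reconcile.

## Background model

Read 5′ starts are modelled as Poisson with a locally varying rate. The
raw estimate at position *i* is the window count
λ̂(i) = Σ<sub>|j−i|≤w</sub> Y(j), per strand, with windows truncated at
chromosome ends. Large isolated peaks (PCR stacks, collapsed repeats)
would inflate λ̂ for a whole window length, so the robust track caps each
value using the adjacent non-overlapping window to its left: λ̃(i) is the
largest integer j ≤ λ̂(i) with P[X ≤ j | λ = pred] ≤ γ<sub>bg</sub>,
applied only when the predecessor estimate is positive.

Choices that the rule itself leaves open, fixed here:

- the predecessor is the **robust** estimate at i − (2w+1), computed in a
  left-to-right scan, so one extreme peak cannot poison its right
  neighbourhood through the raw track; the first 2w+1 positions of each
  chromosome have no predecessor and are left untruncated;
- if no integer satisfies the bound (tiny predecessor rate), λ̃ = 0;
- the background window is centred on the candidate binding-region start
  for all three region comparisons — it is ≫ b, so off-centre effects are
  negligible.

Two quantitative properties of this rule are worth knowing. Because the
cap is derived from a noisy *estimate* rather than the true rate, the
fraction of positions it touches on homogeneous data is roughly twice
(1 − γ) — about 0.20 at γ = 0.9 and λ ≈ 100 per window, matching the
exactly computable iid probability P[X > cap(Y)] — and each touch pulls
the estimate down slightly, giving a deliberate conservative bias of
~2–3% in the mean robust rate at that scale (the tests verify both
against exact Poisson expectations). Estimates in regions containing real
nucleosomes are likewise biased upward by the signal itself; both effects
make scores conservative rather than anti-conservative.

## Scoring

For each candidate start *i* (every position where all three regions fit),
counts are extracted by cumulative-sum differences (exact integers). The
two-Poisson comparison uses the likelihood-ratio statistic W (see README);
its implementation uses `xlogy` for the 0·ln 0 = 0 convention, clamps
−1e−9 < W < 0 rounding residues to zero, and returns an exact 0 whenever
x₁t₀ = x₀t₁ (the estimated rates coincide, so the alternative collapses
onto the null). Undefined cases (x₀ = x₁ = 0) propagate as NaN.

Region specifics:

- **supports**: x₁ = the cross-truncated estimate λ̃<sub>sup</sub>
  (capped at the γ<sub>sup</sub> Poisson quantile of the partner strand's
  count, feasible set {j : 0 < j ≤ x}), t₁ = s, against the same-strand
  robust background over t₀ = 2w<sub>bg</sub>+1;
- **binding**: x₁ = the raw both-strand count, t₁ = b, against the *sum*
  of the two strand backgrounds over t₀ = 2(2w<sub>bg</sub>+1), since the
  binding count pools strands;
- all enrichment/depletion comparisons are per-bp rates (equivalently
  φ̂ vs 1) — the raw quantities live on windows of different lengths.

The region score is the **signed square root** ±√W (positive for
enriched supports / depleted binding region, with equality counting as
the null-consistent sign). The signed root is what makes each region
score asymptotically N(0, 1) given W ~ χ²₁; a `signed_root=False` switch
exposes ±W itself for comparison. A position is valid only with ≥ 1 read
in each support region, positive robust background on both strands, and
both truncated support estimates defined; invalid positions carry NaN and
are excluded everywhere downstream.

*b* and *s* are free positive lengths (the default *b* = 128 is even, so
no odd-length constraint is imposed); the reported dyad is
start + ⌊b/2⌋.

## Significance

The empirical null S ~ N(μ̄, σ) uses μ̄ = median of valid scores and a
maximum-likelihood σ from the deviations μ̄ − S of scores between the τth
and 50th percentiles, fitted as a half-normal truncated to that deviation
interval. The 1-D likelihood is maximized with bounded Brent iteration
(tolerance 1e−8, bounds a factor 10³ around the untruncated MLE).
Degenerate inputs — fewer than `min_scores` (default 1000) valid scores,
or a (near-)constant score band — raise instead of returning a bogus
scale. τ defaults to 5 (exclude the lowest 5% as binding-region pile-up
outliers); a τ in (0, 1) is read in the retained-fraction convention
(0.95 keeps 95%, the same cut) since both conventions circulate. Scores
above the median never enter the fit.

p-values are upper tails of the fitted normal; q-values are
Benjamini–Hochberg (via statsmodels), optionally scaled by
π̂₀ = min(1, 2·mean(p > 0.5)) in the `adaptive` mode — a deterministic
median-based estimator of the true-null proportion, kept simple on
purpose; BH is the default.

Discrete calls: among positions with q ≤ FDR (default 0.05), a greedy
pass in descending score order (ties to the leftmost start) accepts a
position unless an accepted start on the same chromosome lies within
`min_sep` bp. The default `min_sep = 5` deliberately admits overlapping
calls — alternative positions of one nucleosome across the cell
population — while `--non-overlapping` sets `min_sep = b` for analyses
(like the dinucleotide profile) that need disjoint nucleosome sequences.
The extraction rule is this package's own plumbing; the upstream method
it models does not publish one.

## Simulator

The simulator emulates an MNase mononucleosome experiment on a synthetic
chromosome. Features tile the genome end-to-end: **stable** nucleosomes
(one dyad per 200 bp spacing unit, jitter SD 2 bp), **phased** arrays
(5 kb regions, dyads every 200 bp, jitter SD growing 10 → 20 bp with
distance from the array anchor), **fuzzy** regions (5 kb, jitter SD
40 bp) and **nucleosome-free** regions (150 bp, no dyads). The default
kind weights 0.288 : 0.342 : 0.133 : 0.237 are proportional to the
feature tallies of a published genome-scale Arabidopsis simulation; the
region lengths come from the same study's per-kind genome coverage. Each
signal read picks a dyad uniformly, jitters it by a rounded
Normal(0, spread), draws a fragment length ~ round(Normal(150, 10)), and
places the fragment as [c − ⌈L/2⌉, c + ⌈L/2⌉ − 1] (even lengths exactly
centred: a 150 bp fragment on dyad c spans [c−75, c+74], so forward 5′
starts sit at c−75 and reverse 5′ ends at c+74; odd lengths put the
extra base upstream). One fragment end is reported as a 36 bp read on the
corresponding strand (fair coin); background reads start uniformly on a
uniform strand; off-genome draws are redrawn. All sampling flows from one
integer-seeded generator, so equal seeds give byte-identical output.

What it does **not** emulate: sequence content (no FASTQ, base errors or
mappability structure), MNase's A/T cleavage bias, chromosome-scale
covariates of real backgrounds, or inter-feature correlations. Tests that
pass on this generator therefore demonstrate the statistical machinery
under its stated Poisson/Normal assumptions, not robustness to every
artefact of real libraries.

## Problem sizes used in the checks

The end-to-end checks run on a 1 Mb chromosome with the default feature
mix (~5,000 nucleosomes of which ~100–130 are stable), 20 reads per
nucleosome and 20% background (~120k reads) — large enough for stable
detection statistics while keeping a full run in seconds. Background-only
false-positive behaviour is measured on 50 replicates of 1 Mb at 0.05
reads/bp. Oracle comparisons use 1,000 random configurations (LRT,
step-up, Pareto), exhaustive grids to 50 (truncation rules), and 10⁴–10⁵
draws (null asymptotics, scale recovery, dinucleotide null).

## Known limitations

- **Low-coverage null miscalibration.** Validity conditions on ≥ 1 read
  per support region; at very sparse coverage (around 0.05 reads/bp with
  the default geometry, i.e. ~0.4 expected reads per support window) the
  surviving score distribution is strongly discrete and right-skewed, and
  the symmetric N(μ̄, σ) null fitted from its lower half underestimates
  the upper tail. On background-only data at that depth the caller emits
  on the order of tens of clustered spurious loci per Mb at FDR 0.05;
  at 0.25 reads/bp the same pipeline emits none. Results at coverages
  below ~0.1 reads/bp should be treated as rankings rather than
  calibrated discoveries.
- **Contaminated null at extreme sparsity/purity.** If nearly every valid
  position overlaps a real nucleosome (e.g. a handful of isolated
  nucleosomes on an otherwise empty chromosome), the median-based null is
  estimated from signal and the half-normal fit degenerates; the caller
  then reports nothing rather than something miscalibrated.
- **Single-sample background.** The background rate comes from the same
  sample; regions dense in nucleosomes get conservative scores. A control
  sample is only used for parameter selection (the sweep), not for
  calling.
- The dinucleotide expectation uses the relative abundances supplied by
  the caller; the `motif` command computes them from the forward strand
  of the reference FASTA.
- Repeatability normalises total correlation (in bits — the ratio is
  base-invariant) by the value after sorting each detection vector
  descending, the count-preserving arrangement that maximises repeats.
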