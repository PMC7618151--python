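# Methods

## Model and estimation chain

### Data and classification

The unit of observation is a crossover-informative Hi-C read pair: both
mates map to the same chromosome, each covers at least one phased
heterozygous site with a base matching one of the donor alleles, and all
covered sites agree on the pair's status. A pair is reduced to its two
outermost SNP observations; interior SNPs serve only the consistency
check, and a read whose SNPs match different haplotypes invalidates the
whole pair (a contiguous gamete fragment cannot legitimately switch
haplotype within ~150 bp). Pairs whose two reads fall in different
haplotype blocks are dropped: the relative phase of two blocks is
undefined, so their status would be a coin flip. The insert size `d` is
the distance between the outermost SNPs, not the alignment ends, because
every downstream quantity (prior, density spreading, coverage) concerns
the genomic interval actually interrogated for a crossover.

### Likelihoods

Each end's haplotype assignment flips if exactly one of base-calling
error (probability `b`, from the base quality) or phase error
(probability `p`, from the phasing quality) occurred; assuming
independence, `e = b(1−p) + p(1−b)`. For an observed C pair a true
crossover yields the observation when both ends are correct or both
flipped:

    lc = (1−e1)(1−e2) + e1·e2        ln = e1(1−e2) + e2(1−e1)

Observed N pairs are fixed at `lc = 0, ln = 1`. This deliberately
one-sided convention can only lose true crossovers (never invent them),
and the loss is uniform along the chromosome, so it scales the map
without distorting its shape.

### False-positive correction

Errors unaccounted for by quality scores (miscalled variants,
mismapping, gene-conversion tracts) produce false C pairs at a rate
roughly independent of insert size, while true crossovers accumulate
linearly with `d`. Two insert-size regimes therefore separate signal
from noise:

- baseline rate, long pairs (`d > long_threshold`, default 1 Mb):
  `r* = Σ lc (long C pairs) / Σ d (all long pairs)` — crossovers per bp
  per gamete (Morgans/bp);
- correction factor, short pairs (`d < short_threshold`, default 1 kb):
  `f = (Σ lc − r*·Σ d) / n_short`, sums over short C pairs, `n_short`
  the count of **all** short informative pairs, clamped to [0, 1).

The denominator choice matters: dividing by the count of short C pairs
would force `f ≈ 1` whenever short C pairs exist (each has `lc ≈ 1`),
whereas dividing by all short pairs makes `f` the per-pair probability
that an informative pair is falsely classified C — the quantity the
simulator's planted flip rate realises, and the one the recovery tests
confirm (`tests/test_acceptance.py::test_error_rate_recovery`).

### Posterior crossover probability

With a uniform-rate prior `pc = min(r*·d, 1)`:

    P = (lc − f)·pc / [(lc − f)·pc + (ln + f)·(1 − pc)]

`lc − f` is floored at zero. The `f` correction is applied only to
observed-C pairs: it models the excess probability of a *false positive
C call*, which has no analogue for N pairs. Long N pairs
(`d > double_xover_min_d`, default = long threshold) first receive the
double-crossover adjustment `lc = pd, ln = 1 − pd` with
`pd = λ²e^(−λ)/2`, `λ = r*·d` (the expected crossover count on the
insert — a rate times a length; interference justifies ignoring doubles
on short inserts), and then enter the same posterior formula without
the `f` subtraction. A zero denominator returns posterior 0 with a
warning.

### Landscape construction

The chromosome is partitioned at every outermost-SNP coordinate.
Effective coverage `N_j` counts pairs spanning interval `j` (half-open
spans, event +1/−1 bookkeeping). The initial map spreads each posterior
uniformly over its insert:

    rate_j = Σ_{i ∋ j} (P_i / d_i) / N_j      [Morgans/bp; stored ×100 as cM/bp]

One EM pass then redistributes each pair's mass along its span in
proportion to the current interval masses (`w_ij ∝ rate_j·len_j`,
uniform fallback for zero-mass spans) and re-normalises:
`rate_j = Σ_i w_ij / (N_j·len_j)`. Mass is conserved exactly: each
pair's weights sum to `P_i`, so the coverage-weighted map total equals
`Σ P_i` after every pass (and the genetic length itself under uniform
coverage — tested to 1e-9 relative).

**Why only two EM passes by default.** In bulk gamete Hi-C each
crossover is observed by (at most) one ligation product, so C pairs
share no localisation signal: the redistribution likelihood is maximised
by piling mass onto coincidental span overlaps and low-coverage pockets.
That maximiser is formally correct and scientifically useless — on
simulated data the 2 kb truth correlation decays monotonically with
iteration count while the per-interval-change criterion never triggers.
Two passes keep the sharpening that genuine coverage asymmetries support
(e.g. mass shifting away from intervals whose extra coverage is all
non-crossover) while leaving fine-scale structure intact; the
iteration count and tolerance (`em_max_iter=2`, `em_tol=1e-4` on the
maximum relative per-interval change) are user-adjustable, and data in
which crossovers are multiply observed (e.g. single-cell-derived pairs)
would warrant raising the cap.

### Heuristics

- **Imbalanced SNPs**: a SNP bounding ≥ `c_min` C pairs (default 2) and
  ≤ `n_max` N pairs (default 0) is removed together with its pairs,
  iteratively until stable — such sites are characteristic of variant
  calling/phasing artifacts and otherwise seed false rate spikes.
- **Edge trimming**: effective coverage decays toward chromosome ends;
  intervals outside the first/last position where coverage reaches
  `min_cov` (default 10% of the chromosome's length-weighted median
  coverage — no published number exists, and a fraction of the median
  adapts across datasets) are excluded from estimation and output.
  Interior dips are never trimmed; they reflect SNP deserts, not the
  systematic edge effect.

### Uncertainty and comparison

The bootstrap resamples the (imbalance-filtered) pair list with
replacement and reruns everything from `r*` onward; replicate maps are
evaluated on the union grid of their boundaries restricted to the
intersection of retained spans, giving a mean map and a percentile
2.5/97.5 envelope (closed intervals). Δ(r) regions between two
bootstrapped maps are the maximal runs of intervals where the envelopes
are disjoint (touching bounds intersect); optional mean-normalisation
divides each map and its envelope by its length-weighted mean rate so
only shape differences remain. The acceptance script reports the Δ(r)
fraction between two maps simulated from the *same* truth as the
comparison's false-discovery floor.

## Simulator

`simulate_pairs` draws insert sizes from an empirical distribution
(resampling the observed `d` values of a real pairs file, or the
built-in log-uniform 300 bp–5 Mb synthetic profile), places the left
endpoint uniformly, sets the true status to C with the Haldane
probability `(1 − e^(−2Δ_M))/2` of the map distance between the
endpoints (correct saturation at 1/2 for multi-Morgan inserts, rather
than a linear cM/100 rule), flips the observed status with the
configured error rate, and stops when the mean spanning coverage
`Σd/L` reaches the target. Simulated observations carry near-zero
quality errors (1e-6) so the planted flip rate is the only error
source.

What it emulates: the insert-size profile, the coverage budget, and a
status-error process that is symmetric and position-independent. What it
does not: SNP spacing (endpoints are continuous positions, not
restricted to a het grid), correlated errors from mismapping in
repetitive regions, somatic-cell contamination, gene-conversion tracts,
crossover interference between pairs, and reference/assembly errors.
Passing simulation tests therefore demonstrates the estimator chain is
correct and well-calibrated under its own error model — not that real
libraries are free of structured artifacts (the imbalanced-SNP filter
exists precisely because they are not).

Study conditions used by the test suite and `scripts/acceptance.py`,
chosen once: a 30 Mb chromosome (10 Mb where runtime matters more than
span) with an amplitude-modulated sawtooth landscape — five 0-to-peak
ramps whose height grows linearly along the chromosome (gradient 0.8),
normalised to a 3 cM/Mb mean, fish-like in both scale and total length.
The modulation guarantees genuine truth variance at both the 2 kb and
5 Mb evaluation scales; a pure sawtooth whose period matches the bin
size would make large-scale correlations degenerate. Effective
coverages 500–3000× and error rates 0.5–5% bracket the regimes where
bulk-gamete libraries operate; 5–10 replicates per setting keep each
run under a minute per setting on one CPU.

## Numerical choices

- Rates are held in Morgans/bp internally; the `RecombinationMap.rate`
  field is cM/bp and TSV output is cM/Mb, 1-based inclusive coordinates.
- Diff-array cumulative sums are floored at zero after accumulation
  (floating cancellation can leave −1e-20 residues that would otherwise
  trip the nonnegativity invariant).
- Correlation binning uses full windows only and treats a relative
  standard deviation below 1e-9 as zero variance (undefined
  correlation, reported as missing).
- Clamps: `f ∈ [0, 1)`, `lc − f ≥ 0`, `pc ≤ 1`, phase error ≤ 0.5 —
  small-sample estimates must not produce probabilities outside [0, 1].
- HapCUT2 phase quality is stored phred-scaled with two decimals capped
  at Q100, so a round trip preserves `phase_err` to printed precision
  (exact zero reads back as 1e-10).
- Bootstrap and simulation randomness flow from a single
  `numpy.random.Generator`; identical seeds give byte-identical output
  files.

## Open choices made here

- The per-end flip-error composition `e = b(1−p) + p(1−b)` assumes base
  and phase errors independent; it is isolated in
  `xovermap.infopairs.flip_error` for easy replacement.
- `f` is estimated per chromosome, like `r*` (a single model object
  carries both), since repetitive content — the main error source —
  varies strongly between chromosomes.
- Trio phasing reports `phase_err = 0` for phased sites: Mendelian
  transmission with one informative parent is deterministic given
  correct genotypes, and genotype errors are not modelled here.
- Pipeline order: classify → imbalance filter → `r*` (raw likelihoods)
  → `f` → double-crossover adjustment → posteriors → coverage/edge trim
  → initial map → EM.

## Limitations

- Diploid donors only; hemizygous regions (degenerate Y, inversions in
  one haplotype) cannot be phased or mapped.
- Absolute map lengths are conservative: the N-pair convention converts
  quality-score uncertainty into uniformly distributed false negatives,
  and edge trimming removes subtelomeric recombination from the total.
- The mean per-bp rate carries a systematic bias of several percent
  whose sign depends on the landscape and insert profile (Haldane
  saturation pulls the linear `r*` estimator down; status errors push
  it up); the acceptance script reports it per coverage setting.
- No gene-conversion tract detection; non-crossover events contribute
  only as short-insert noise absorbed by `f`.
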