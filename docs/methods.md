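# Methods

## The per-molecule chromatin state model

Each sequenced molecule carries a set of called m6A positions (both strands)
and an average per-base quality score from consensus calling.  Reads below an
average quality of 90 are discarded: low-quality consensus reads are also the
ones in which m6A calling collapses, so they would contribute spurious
footprints.

The caller scans each read with a sliding window (default 25 bp — wide enough
to contain several adenines, short relative to a nucleosome-depleted region;
window sizes 15–30 bp give closely similar output and a dedicated test
asserts < 5 percentage-point spread in the called nucleosomal fraction).
Window coordinates are Watson-strand based: the adenine count N of a window
is the A+T count of its Watson sequence (equal to the adenines on both
strands of the duplex), and m6A on either strand projects onto the same base
pair.  For a window with n adenines and k called m6A the null is
X ~ Binomial(n, p_exp) with

    p_exp = clamp(k(N) · m + β(N), 1e-6, 1 − 1e-6)

where m is the read's overall methylated-adenine fraction and (k(N), β(N))
come from the calibration table.  P(X ≤ k) is the nucleosomal (hypo-
methylation) p-value, P(X ≥ k) the accessible one; both tails include the
observed count.  Windows with fewer than 3 adenines (below the smallest
calibrated N) are untestable and stay ambiguous, as do edge bases without a
complete centred window.

Benjamini–Hochberg adjustment is applied per read, separately for the two
tails (they test different alternatives, so they form two families), over
testable windows only.  BH is implemented directly (sort, p·m/rank, suffix
minimum, cap at 1) so that it is bit-for-bit the step-up definition.  The
central base of a window becomes accessible when adj P(X ≥ k) < 0.853 and
nucleosomal when adj P(X ≤ k) < 0.918 (defaults; see threshold calibration);
if both pass, the smaller adjusted p wins and an exact tie stays ambiguous.

### Boundary resolution

Most ambiguity sits at accessible↔nucleosomal boundaries, where the sliding
window mixes the two states.  Rules, applied in order on each read:

1. at each accessible→nucleosomal transition, ambiguous bases among the 12 nt
   downstream of the last accessible base become accessible;
2. symmetrically, nucleosomal→accessible transitions extend nucleosomal;
3. a base claimed by both extensions would be nucleosomal (with rule order
   and the gap cap below, the two extensions cannot in fact collide; the
   nucleosomal-precedence write is retained);
4. remaining ambiguous runs shorter than one window (25 bp) that touch a
   nucleosomal run become nucleosomal — a run shorter than a window cannot
   independently support an accessible call.

Two refinements make the operation well defined and idempotent, which the
rules as stated alone are not: an extension fires only when the ambiguous gap
between the two differently-labelled called runs is at most 2·12 = 24 bp (the
widest boundary ambiguity a 25-bp sliding window can create — larger gaps are
not boundary artefacts and stay ambiguous), and an extension never reaches
past the next called run (otherwise a distant accessible run could relabel
the single ambiguous base between two nucleosomal runs, stranding 1-bp
"footprints").  Boundary resolution never flips a called base between
accessible and nucleosomal; it only consumes ambiguous bases.  Idempotence on
arbitrary label tracks is property-tested.

## Calibration

Single-molecule m6A calling is biased against AT-rich contexts.  On a fully
accessible control (purified DNA treated with the methyltransferase), the
mean window methylation is linear in the read's overall methylation for each
window adenine count N, with slope falling as N grows.  The fit follows the
binned design: control reads with overall methylation in the closed interval
[0.07, 0.41] (the well-populated range of real controls) are grouped by their
methylation rounded to 1%; windows are binned by N; cell means over (N, bin)
cells with at least 5 windows are fitted by ordinary least squares per N.
Rows with fewer than 2–3 usable cells are filled by linear interpolation from
neighbouring N and flagged.  A poly(A) profile (mean called fraction of
adenines by maximal same-strand A-run length, runs ≥ 8 pooled) quantifies the
run-length bias separately.

### Threshold calibration

The control contains no nucleosomes, so every nucleosomal-labelled base on it
is a false positive.  `calibrate_thresholds` scans a candidate grid and
returns the largest nucleosomal threshold whose control false-positive
fraction stays below the target (default 1%).  Because maximising a threshold
subject to an estimated constraint is a winner's-curse selection, the
constraint is applied to the estimate plus 3 standard errors computed across
reads (reads, not bases, are the sampling units — false calls arrive in
within-read bursts).  The accessible threshold is calibrated symmetrically on
simulated fully protected reads (uniform detection at the intra-nucleosome
rate, ~1%): a truly protected molecule is the only sound truth set for a
false *accessible* call, which the accessible control cannot provide.  The
two thresholds couple through the conflict rule, so they are calibrated
sequentially (nucleosomal first, with the accessible threshold at its
default) and the final pair is re-checked.  Window scans and BH adjustment
are computed once per read; the grid search re-runs only the cheap state
assignment, bisecting on the monotone false-positive fraction.

## Synthetic data generator

The generator emulates a methylase-footprinted yeast-like genome:

* **Genome** — random sequence at 60% AT; optionally with block-wise
  compositional heterogeneity (local AT content ~ Normal(mean, sd) per
  300-bp block) as in real genomes, which is what populates extreme window
  AT counts (N near 5 or 23 is vanishingly rare in an i.i.d. 60% sequence).
  Non-overlapping genes of 600–1500 bp with ≥ 250 bp intergenic gaps provide
  the TSS annotation.
* **Chromatin** — 147-bp nucleosome footprints tiled between promoter
  nucleosome-depleted regions (default 120 bp upstream of each TSS), linkers
  max(5, Normal(18, 5)) bp; each molecule shifts the whole template by
  Normal(0, jitter_sd) (default 15 bp), the knob behind cell-to-cell
  positional heterogeneity.  Setting `nucleosomal_fraction` derives the
  linker mean so the footprints cover that genome fraction.
* **Methylation** — each read draws a target overall methylated fraction
  (default lognormal, median 0.11, σ = 0.5, matching ~11 ± 6% in real data).
  Nucleosomal positions are detected at 1%; accessible positions at the rate
  solving the mass balance f = nf·q + (1 − nf)·p_acc for the read's true
  nucleosomal fraction nf (clipped into [q, 0.99] in read mode; an error in
  the window-level test, where the design must be exactly solvable).
  Optional AT-count and poly(A) multipliers reproduce the calling biases.
* **Quality** — constant 99 by default; quality filtering is exercised by
  dedicated fixtures rather than the main scenarios.

Everything is driven by integer-seeded generators; identical seeds give
byte-identical outputs.

What the generator does **not** emulate: sequencing errors, alignment
artefacts, kinetic signal, transcription-factor footprints, dinucleosomes or
genuine biological heterogeneity structure beyond a single per-molecule
shift.  Passing tests therefore demonstrate that the statistics behave as
designed under the model's own assumptions, not that those assumptions hold
for any particular real dataset.

The window-level in-silico validation draws independent 25-bp windows (AT
count ~ Binomial(25, 0.6)) per condition over overall methylation {5, 10,
15}% × nucleosomal fraction {60, 70, 80}% with 1% nucleosome methylation,
scores the caller's lower-tail statistic against truth, and reports ROC AUC
plus a confusion table at the default thresholds.  AUC degrades at 5%
methylation relative to 10% and 15%, the model's known low-methylation limit.

## Aggregation

Phasing: for each selected gene (non-overlapping, ≥ 200 bp long, TSS ≥ 200 bp
from the nearest upstream gene boundary on either strand), nucleosome density
at strand-oriented offsets ±400 bp from the TSS is the fraction of covering
molecules labelled nucleosomal at that base; the profile is the unweighted
mean over genes with coverage.

Heterogeneity: molecules fully covering TSS ± 300 bp with at least one
accessible base in the window (excluding molecules with too few m6A to
segment) are encoded as 601-long vectors (accessible 0, ambiguous 0.5,
nucleosomal 1, 5′→3′ of the gene).  The per-gene score is the mean Pearson
correlation over all unordered molecule pairs; pairs containing a constant
vector have no defined correlation and are skipped (counted and reported).
Genes with fewer than 6 qualifying molecules are omitted.  Histograms use
fixed 0.05-wide bins over [−1, 1].

## Problem sizes and numerical choices

* Acceptance-style checks run at desk scale: the false-positive control uses
  10,000 1-kb control reads (half for calibration, half held out); the
  calibration-linearity check uses 150,000 reads on a compositionally
  heterogeneous 300-kb genome (chosen by power analysis — the minimum-R²
  statistic at N = 5 needs roughly that many windows to resolve 0.99), with
  read methylation uniform over [0.05, 0.45] to spread information evenly
  across the fit range, as in any calibration-curve design; the in-silico
  validation uses the standard 9 × 100,000-window design; footprint recovery
  uses 400 2-kb nuclei reads; heterogeneity monotonicity uses 50 genes × 20
  molecules at jitter {0, 20, 40} bp.
* p_exp is clamped to [1e-6, 1 − 1e-6]: the binomial test needs p in (0, 1)
  and the linear calibration can predict outside it.
* Binomial tails come from scipy (`binom.cdf` / `binom.sf`), verified against
  direct pmf summation to 1e-10.
* The caller is fully deterministic; all randomness lives in the simulator
  behind explicit seeds.

## Known limitations

* Footprints shorter than a nucleosome (transcription-factor scale) are not
  called as a separate class; at realistic calling efficiency they are not
  reliably detectable by this statistic.
* The called footprint length distribution is biased slightly short of
  147 bp (mode typically 134–146) because linker methylation erodes footprint
  edges — the same behaviour seen on real data.
* On a uniformly methylated molecule (a fully accessible control), both
  tests are null everywhere, so most bases stay ambiguous rather than being
  labelled accessible: the model detects *contrast* within a molecule, not
  absolute accessibility.
* Per-read BH with the permissive default thresholds means the presence of a
  strong footprint family in a read lowers the bar for moderate windows in
  the same read; this is inherent to the within-read adjustment design.
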