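# Methods

## Background and scope

Chromothripsis is a one-off mitotic catastrophe: tens of double-strand
breaks cluster on one or a few chromosomes, the fragments are lost or
re-joined in essentially random order and orientation, and the
surviving derivative chromosome shows a copy-number profile that
oscillates between two or three states. In SNP-array data it has
classically been defined by *at least ten switches in segmental copy
number between two or three states*; sequencing-era work refined this
into six criteria (breakpoint clustering, state oscillation,
interspersed loss/retention of heterozygosity, single-allele
involvement, randomness of fragment joins, and walkability of the
derivative chromosome), of which at least three must hold.

`shatterscan` implements this detection logic for segmented,
allele-aware copy-number profiles plus optional SV-join tables, a
generative simulator of chromothriptic versus progressively rearranged
genomes with full ground truth, and the cohort-level bookkeeping
(event tallies, burden comparisons, incidences, common deleted
regions, gene annotation, an FDR/fold-change gate) used to summarize a
T-ALL cohort of 103 cases in which 12 immature adult cases carried
chromothriptic chromosomes. Expression modelling, fusion discovery,
and variant calling are out of scope.

## Data model and conventions

Coordinates are 0-based, half-open everywhere; readers can convert
1-based input through a dialect object. A segment carries total copy
number (diploid baseline 2) and an LOH flag; `cn == 2` with LOH is
copy-neutral LOH. Profiles are maximal: adjacent segments never share
the same (cn, LOH) state, so "one event" is well defined as one
maximal non-diploid (or cnLOH) segment. A junction is a pair of
fragment ends ("head" = lower-coordinate end, "tail" = higher); joins
are stored in canonical coordinate order (ties broken head before
tail) and typed by concatenating the side initials, so a deletion-like
junction reads TH and a tandem-gain junction HT.

Segments shorter than `min_segment_bp` (default 100 kb, a typical
SNP-array reporting threshold) can be dropped on read; the exact
platform filters of the source study are not published, so this is a
declared default, not an inference.

## Switch counting

`count_state_changes` finds the maximal window containing every
non-diploid segment of a chromosome, extends it by one flanking
segment on each side, and counts adjacent pairs with different total
copy number. The flank extension makes the transitions into and out of
the affected region count — a lone deletion in a diploid background
scores 2 — which is the only reading consistent with the worked
examples the definition is calibrated against (a 2/1/2 profile has 2
switches; 21 alternating segments have 20). cnLOH transitions leave
copy number unchanged and are never switches; whether the original
criterion counted them is unknowable from the published text, so the
conservative literal reading was chosen. The reported span is the
first-to-last non-diploid segment, i.e. the breakpoint-bounded
affected region.

## Calling modes

`snpa_only` (the cohort default, because array data exist for all
cases while sequencing confirmation existed only for a subset) flags a
chromosome iff `n_switches >= 10` and the window holds at most 3
distinct copy-number states. `full` mode evaluates the six criteria
and requires at least `min_criteria = 3`:

* **C1 clustering** — Monte-Carlo Kolmogorov–Smirnov test of the
  profile's internal state-change breakpoints against uniform
  placement over the chromosome; p is estimated from ≥ 10,000 uniform
  replicates of the same size (with an add-one correction) and the
  criterion passes when p < 0.01, i.e. uniformity is rejected. Fewer
  than 3 breakpoints fail automatically at p = 1. The KS distance was
  chosen because it is distribution-free and honest at the small
  breakpoint counts involved (10–50).
* **C2 oscillation** — at most 3 states, the two most frequent states
  covering ≥ 50% of window segments, and ≥ 10 switches.
* **C3 interspersed LOH** — ≥ 3 alternations of the LOH flag along the
  window (threshold configurable; the source criterion is
  qualitative).
* **C4 single allele** — ≥ 80% of joins on the modal haplotype;
  unlabeled joins make the criterion abstain (fail, flagged "no
  data") rather than guess.
* **C5 join randomness** — goodness-of-fit of the HH/HT/TH/TT counts
  against the uniform multinomial: exact by full enumeration of
  outcome vectors up to 60 joins, Monte-Carlo beyond. Chromothripsis
  predicts randomness, so the criterion passes when uniformity is
  *not* rejected (p ≥ 0.05). Fewer than 8 joins abstain. The discrete
  exact test's attained level at 40 joins is 0.049.
* **C6 derivative walk** — fragment ends are graph nodes, fragments
  mandatory edges, joins connecting edges. Because each end may carry
  at most one join (violations raise an error naming the end), node
  degree is ≤ 2 and components are simple paths or cycles, each fully
  traversable by a walk alternating fragment and join edges; a cycle
  is a circular derivative (ring chromosomes occur in this disease).
  Coverage is the largest fraction of joins in one component, and the
  criterion passes at ≥ 0.9. When fragments are not supplied they are
  inferred by splitting retained (cn ≥ 2) segments at join breakends.

Evaluation is per chromosome; inter-chromosomal joins contribute to
C4–C6 of both partners. A case is positive iff any chromosome is
flagged.

## Simulator

`shatter_chromosome` places a contiguous shatter region (span
calibrated to the observed 50–218 Mb) uniformly on the chromosome,
cuts it into `n_fragments` at uniformly drawn breakpoints, loses each
fragment independently with `loss_prob` (at least two must survive;
bounded resampling otherwise), and permutes/flips the survivors
uniformly. Lost fragments become cn 1 (and, being single-copy, LOH);
retained ones stay cn 2 with LOH drawn at `loh_fraction` (default 0.5,
a free parameter — the study reports interspersed LOH without rates);
an optional `dup_prob` emits cn 3 so profiles honor the two-to-three
state range. Joins connect consecutive retained fragment ends in
derivative order on a single haplotype. Retained plus lost fragments
tile the region exactly; outside it the chromosome is untouched.

`simulate_progressive` scatters `n_events` non-overlapping events
(size log-uniform 100 kb–10 Mb, chromosome weighted by length, class
mix defaulting to the 536/225/69 loss/gain/cnLOH proportions of the
study's 830-event tally). Deletions and tandem gains emit their
signature junctions, so negative cases have structured, non-random
join types. Negatives that by chance pile ≥ 5 events on one chromosome
(≥ 10 switches) are kept, so specificity is measured honestly.

`simulate_cohort` derives per-case RNGs from the master seed
(deterministic, byte-identical reruns). Every case draws a background
burden from the chromothripsis-negative law — Poisson(mean 5)
truncated at 14, matching the reported negative-case median of 5 and
range 0–14. Positives additionally shatter 1–4 chromosomes (the
7/3/1/1 multiplicity pattern of the 12 observed positives), each with
a target of 10–23 segmental CNA realised as an alternating
retained/lost fragment layout (2m+1 fragments for m CNA) injected
through the shatter configuration's mask hook; independent per-fragment
loss would only match the observed CNA range after resampling, which
would distort the loss process it conditions on. Background events are
excluded from chromothriptic chromosomes so truth labels stay crisp.

Separate stratum-level burden laws support the burden comparison: the
immature (ETP/near-ETP) stratum draws from a negative binomial
(r = 2.5, mean 13) truncated at 79 — median exactly 11 — and the
non-ETP stratum from the Poisson law above. These reproduce the
reported stratum medians of 11 vs 5 and give the Welch t test
essentially full power at the study's 39 vs 59 group sizes, mirroring
the reported p = 0.0003.

What the simulator does not emulate: subclonality and tumor purity,
replication-based mechanisms with more than three states
(chromoanasynthesis), platform noise in segment boundaries, wavy
baselines, and germline CNV contamination. Passing tests therefore
show the criteria machinery is correct and calibrated on clean
segmentations, not that the caller is robust to noisy real-world
segmentation.

## Cohort statistics

Tallies count one event per maximal segment and are additive over any
case partition. Burden comparisons default to Welch's t (the study
says only "unpaired t test"); Student's t and the rank-sum test are
available, the latter exact by full midrank enumeration when the
pooled size allows (the exact path handles ties; the asymptotic
Mann–Whitney takes over beyond ~200,000 assignments). Incidences
return the exact fraction plus truncated and rounded one-decimal
renderings, because the study prints truncated percentages (12/103 as
11.6%, 12/39 as 30%); comparisons should use the exact fraction. The
common deleted region is the plain intersection of per-case deletion
intervals. Gene annotation uses ≥ 1 bp overlap of half-open
intervals. The expression-style gate applies Benjamini–Hochberg over
the full p-value vector (the field default where only "FDR" is
stated) and keeps |fold change| ≥ 2 with q < 0.05.

The packaged positive-case table transcribes the 12 positive cases
once (chromothriptic chromosome sets parsed from their `arr(...)cth`
strings, compound deletion tokens split on hyphens for gene tallies;
the 6q14-q15 region is detected through its resident genes CASP8AP2,
GRIK2, SEC63, FYN).

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 103 (the study
design), 39 (the immature stratum), and 200 × 40 cases for the
sensitivity/specificity guarantee; calibration runs use 1,000 trials
over 10,000-replicate Monte-Carlo nulls — sizes at which every
statistical check is stable at the asserted 2-SE tolerances while the
whole suite stays in the tens of seconds. Monte-Carlo p-values use the
add-one correction (never exactly zero). Sex chromosomes are carried
through I/O but excluded from default burden simulation and statistics
(their handling in the source cohort is unstated). Known limitations:
no subclonal calling, no timing inference, no support for more than
one join per fragment end (a deliberate restriction that keeps the
derivative walk exact rather than heuristic).
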