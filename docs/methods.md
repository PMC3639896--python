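# Methods

## Duplex model and rule engine

A candidate target site is evaluated as an ungapped, full-length, antiparallel
duplex: miRNA position *i* (1-based from the 5′ end) pairs with site position
*L − i + 1* of the transcript window (both sequences stored 5′→3′). Each
position takes one of three states — Watson–Crick match, G:U wobble, or
mismatch; `N` never pairs and is always a mismatch. The weighted score is
`S = n_mismatch + 0.5 · n_GU`, and a site is accepted iff

| rule | default | quantity |
|---|---|---|
| total | S ≤ 4.0 | G:U-weighted score |
| contiguous | run ≤ 2 | longest run of consecutive positional mismatches |
| seed | ≤ 1 | positional mismatches at miRNA positions 1–9 |
| central | = 0 | positional mismatches at positions 10–11 |

Design choices made where the convention was genuinely open:

* **G:U in the positional rules.** A wobble is penalized at half weight in S
  but, by default, does not count as a "mismatched nucleotide" for the
  run/seed/central rules. This matches common plant target-prediction
  practice, where wobbles are tolerated positionally but penalized globally.
  The alternative reading is one flag away
  (`RuleConfig(gu_counts_in_positional_rules=True)`); the verdict engine
  recomputes all positional quantities from the pairing states under
  whichever configuration it is given.
* **Interpretation of the total rule.** "Total mismatches ≤ 4" is read as the
  weighted score S ≤ 4.0, consistent with assigning G:U a fractional score:
  3 mismatches + 2 wobbles (S = 4.0) passes, 4 mismatches + 1 wobble
  (S = 4.5) fails.
* **Position numbering** is from the miRNA 5′ end (the standard seed
  convention).
* **No gaps or bulges.** The rules count mismatches only, so the alignment is
  ungapped and full-length; thermodynamic (ΔG) evaluation and site
  accessibility are out of scope.

Score arithmetic uses increments of 0.5, which are exact in binary floating
point, so boundary comparisons (S ≤ 4.0 at exactly 4.0) need no tolerance.

## Scanner

`scan_pair` enumerates every window (0-based, half-open, forward/sense strand
only — inputs are oriented mRNA contigs), prefilters all windows with a
vectorized numpy pass (pair-class lookup table over the encoded window
matrix), and passes survivors through `score_duplex`/`evaluate_rules`, so the
rule engine remains the single authority on acceptance. All overlapping sites
are reported; a `best_per_pair` option keeps the lowest-score site per
(miRNA, transcript) pair, ties broken by smallest start. Because "potential
targets" can be counted per site or per transcript, summaries always report
both, labeled.

`oracle_scan` is a deliberately naive per-window, per-position
reimplementation sharing only the base-pair classifier with the fast path.
The test suite holds the two equivalent on 1,000+ seeded random pairs and
exhaustively (every window, membership ⟺ verdict) on transcripts ≤ 500 nt.

## Expression conventions

* Abundances are per-library transcripts per million (values sum to 10⁶).
  Note this normalization is composition-sensitive: strong one-sided
  regulation shifts all observed folds toward the regulated side's total (no
  TMM-style correction is applied, since the convention modeled here is plain
  per-million scaling).
* Fold change is elicited/nonelicited. Zero in the control with a positive
  elicited abundance gives the **ND** sentinel ("n.d."), which counts as
  up-regulated everywhere but carries an explicit flag; zero in both gives
  **UNDEFINED** and the record is excluded from calling.
* Differential calling: up iff fold ≥ 2 (or ND) and p ≤ 0.05; down iff
  fold ≤ 0.5 and p ≤ 0.05. All threshold comparisons are inclusive ("no less
  than"). Statistical testing is *not* performed here — the study's exact
  test belongs to an external framework — so the p column is consumed as
  input (either raw or adjusted; the output records whether the criterion was
  applied, and it is skipped when no column is supplied).
* Pathway summaries count members at the fourfold bar (fold ≥ 4 up, ≤ 1/4
  down, ND counting as up) among DE members only; classification is
  increased / decreased / mixed / none, members may belong to several
  pathways, and unresolvable member ids are tallied as missing.

## Integration

Hits are aggregated to the (miRNA, transcript) level — expression direction
is a transcript property — keeping the site count and best (minimum) score.
Patterns: opposite directions are *complementary*, same directions
*concordant*, anything involving "unchanged" (or missing expression, which
defaults to unchanged with a flag) *indeterminate*. miRNA directions are an
input table, as in the original workflow where they came from a separate
small-RNA study; the labels describe expression patterns only and carry no
claim of validated regulation.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing process: no read-level simulation, no assembly or
quantification noise, and i.i.d. background sequence with configurable
composition (expected spurious-hit rates are not analytically controlled;
tests compare against the oracle rather than assuming zero background hits).

* **Planted sites** start from the miRNA's reverse complement; listed miRNA
  positions are rewritten into mismatches (lexicographically first
  mismatching base, for determinism) or wobbles (requires G or U in the
  miRNA). Scoring the planted window reproduces the planted position sets
  exactly, and the ledger's `expected_pass` is evaluated through the rule
  engine itself.
* **Decoys** violate exactly one named rule and satisfy the other three,
  verified through the rule engine at construction; generation fails
  explicitly when a miRNA is too short or lacks the G/U bases a construction
  needs.
* **Counts** are gamma-Poisson (negative binomial, var = μ + φμ²) with
  per-gene nonelicited means drawn log-uniform from (20, 2000) at a nominal
  depth of 10⁵ per library, dispersion φ = 0.1, and planted fold tiers
  {1×: 140, 2×: 20, 4×: 20, ND: 20} over 200 genes by default. The ND tier
  has mean zero in the control library. Each gene also carries the exact-test
  p-value of its *planted* mean shift (Fisher's exact test on the rounded
  expected counts against the library depths), for use as the optional p
  column: fold-1 genes get p = 1 exactly, planted shifts at these depths are
  strongly significant.
* **Tier-recovery evaluation** runs the DE caller on the generator's true
  (expected) abundances with these exact-test p-values. This is deliberate:
  the 2× tier sits exactly on the inclusive "no less than twofold" boundary,
  so with observed counts symmetric multiplicative noise would put half of
  those genes below threshold no matter the depth — the true-abundance route
  is what makes the 2× tier a genuine test of boundary inclusivity.
  Recovery from *observed* NB counts is exercised separately at the 4× tier
  with low dispersion (0.01–0.02) and a small regulated fraction (10% of
  genes), where the per-million composition shift and sampling noise leave a
  comfortable margin.
* **The full synthetic study** (defaults: 10 miRNAs of 21 nt, 100 transcripts
  of 300–1500 nt, 60 planted sites, 12 decoys = 3 per rule) plants 5
  complementary and 3 concordant miRNA:target pairs, each with one perfect
  site and a strong planted fold (8× up or 1/8 down, means 200–2000,
  dispersion 0.01) so direction calls are unambiguous for any seed; the
  remaining 52 sites belong to direction-neutral miRNAs on fold-1 transcripts
  and therefore only ever produce indeterminate pairs, keeping the planted
  pattern counts exactly recoverable. Null genes have p = 1 by construction,
  so they can never be called DE regardless of count noise.

## Determinism and I/O

All randomness flows through a single seeded generator per entry point; the
same seed yields byte-identical FASTA/TSV/JSON outputs. Tables are
tab-separated with a header and `.` for missing values (annotation text may
contain commas); files are written atomically (temp + rename) so failed runs
leave no partial artifacts. FASTA input is normalized to the RNA alphabet
(T→U) with the original alphabet recorded.

## Problem sizes

The test suite and the acceptance script run the scanner/oracle equivalence
at 1,000 random pairs (miRNAs 18–24 nt, transcripts 200–2000 nt), exhaustive
window verification on transcripts ≤ 500 nt, the planted-site study at 100
transcripts / 60 sites / 12 decoys, and count simulation at 200 genes —
sizes chosen so every property is checked at full strength while the whole
suite stays fast on a single CPU. The vectorized scanner handles
transcriptome-scale inputs (tens of thousands of contigs) in minutes.

## Known limitations

* No gapped alignment, translational-inhibition vs cleavage classification,
  thermodynamic scoring, or degradome validation.
* No dispersion estimation or multiple-testing correction: p-values are
  inputs, and normalization is plain per-million (composition-sensitive).
* Antisense scanning is out of scope (inputs are oriented contigs).
* The synthetic generator's background is i.i.d.; real transcriptomes have
  repeat structure and composition bias that may change spurious-hit rates.
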