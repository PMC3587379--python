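# Methods

## Coordinate convention

Promoter positions are quoted TSS-relative with the TSS at +1 and no
position 0, so a window of −200..+100 spans 300 bp (200 upstream + 100
downstream bases, endpoints inclusive).  Internally all coordinates are
0-based half-open.  Input sequences are uppercased over {A,C,G,T,N};
other characters are rejected, and any analysis window containing N is
skipped (features) or yields a missing value (profiles) because every
downstream formula assumes a four-letter alphabet.

## DNA duplex stability

Duplex stability is the sum of unified nearest-neighbor standard free
energies ΔG°₃₇ (kcal/mol) over the overlapping dinucleotide steps of the
top strand.  The ten canonical step values (AA/TT −1.00, AT/TA −0.88,
TA/AT −0.58, CA/GT −1.45, GT/CA −1.44, CT/GA −1.28, GA/CT −1.30,
CG/GC −2.17, GC/CG −2.24, GG/CC −1.84) are closed under reverse
complement to all 16 dinucleotides, which also makes the step sum
strand-symmetric.  Sliding profiles use a 15-nt window and report the pure
step sum: initiation/terminal corrections are constants for fixed-length
windows and cancel when windows are compared, so they are exposed only as
an option on `duplex_delta_g` for standalone thermodynamic use.  Profile
values are anchored at the window start; peak-location checks use the
window midpoint, since anchoring is otherwise arbitrary.  Less negative
ΔG means a less stable duplex; promoters show a stability maximum just
upstream of the TSS where the AT-rich TATA region sits.

## Composition features and over-represented words

Positional k-mer profiles (k = 1, 2, 3; 20-bp window, step 1) average the
within-window occurrence rate of each of the 84 k-mers across TSS-aligned
records.  Their Pearson clustering into an adenine-anchored and a
guanine-anchored group is a diagnostic of the two dominant compositional
trends around mammalian TSSs; it does not feed the classifier (no
principled mapping from cluster membership to a feature is available), so
the classifier's NC block uses window-wide k-mer rates instead.

Over-representation is measured by a binomial-approximation Z-score:
occurrences are pooled over all windows (n), compared with N·p where N is
the pooled number of scanned positions and p the word's probability under
a background model, giving z = (n − Np)/√(Np(1−p)).  Because a
genome-wide background is not available at desk scale, p comes from a
Markov model (order 0–2, default 0) fitted to a user-supplied background
sequence set — the closest estimable surrogate.  Two deliberate
simplifications: word self-overlap is not variance-corrected, and the
normal approximation is only calibrated when Np is not minuscule; with
long oligos on small inputs a single occurrence can exceed z = 5, so the
6–12-mer annotation track should be read against the expected counts it
reports.  A word with background probability 0 but nonzero count is
flagged and reported with an infinite z sentinel.

The classifier's OR block uses the 100 highest-z hexamers of the training
promoters (ties broken alphabetically); selection is per training set, and
within cross-validation per training fold, so no information leaks from
held-out records.

## CpG islands

Islands use the classic criteria — length ≥ 500 bp, G+C ≥ 0.5, CpG
observed/expected ≥ 0.6 with obs/exp = (#CG · length)/(#C · #G) — found by
seeding every passing minimum-length window (1-bp step), merging
overlapping seeds, and trimming a merged region from whichever end better
restores the criteria in the rare case the merged region itself fails.  N
counts as neither C nor G and breaks CpG dinucleotides.  Island presence
(≥ 1 bp overlap with the candidate window, padded by 500 bp at prediction
time) routes sequences between the two classifier branches.

## PWM scanning

Matrix scoring is the information-weighted min-max scheme: I(i) =
Σ_b f(i,b)·ln(4f(i,b)) per position, Current = Σ I(i)·f(i, siteᵢ), score =
(Current − Min)/(Max − Min) with Max/Min substituting the per-position
best/worst base.  The matrix score uses all positions; the core score uses
the five consecutive positions with maximal summed information (leftmost
on ties).  Both strands are scanned — the reverse strand by scoring the
reverse complement of each window at the same forward coordinate.  Default
cutoffs are core ≥ 1.0 and matrix ≥ 0.7.  A fully uniform matrix has
Max = Min; its score is defined as 1.0 with a warning, since every site is
equally consistent with it.  TRANSFAC-format count matrices receive a
pseudocount of 0.01·(row total + 1)/4 per cell before renormalisation,
which keeps information vectors finite while perturbing well-populated
matrices negligibly.  The bundled TATA/CCAAT/GC box matrices are synthetic
smoothed-consensus profiles (TATAWAW, CCAAT, GGGCGG); box searches default
to conventional upstream windows (TATA −100..−1, CCAAT/GC −200..−1) with
relaxed cutoffs (0.85/0.8), all overridable.

## Classifier

Positives are the window sequences of training records; negatives are
same-length windows drawn uniformly from the same record with zero overlap
with the positive window, one per record, keeping classes balanced.
Features are z-standardised (fit on training data only) and fed to an
RBF-kernel SVM; when C/γ are not given they are chosen by an inner 3-fold
grid search over C ∈ 2^{−3,−1,…,7}, γ ∈ 2^{−9,−7,…,1} (powers-of-four
steps keep the search affordable at desk scale).  Cross-validation splits
at the record level (a record's positive and negative share a fold, fold
sizes differ by ≤ 1) and re-fits background model, hexamer selection and
scaling inside each fold.  The decision threshold is the SVM boundary
(score 0), adjustable on the model bundle.  Feature families are
individually selectable (OR+NC, OR+DS, NC+DS, OR+NC+DS) for ablations.
The fused default is OR+NC+DS.  At prediction time the window slides with
a configurable stride (default 10 bp); positive windows are merged into
maximal regions keeping the best score and the branch that produced it.

## Co-occurrence mining

Each promoter maps to the set of matrix ids with ≥ 1 scan hit (promoters
with no hits are retained as empty transactions).  Frequent itemsets are
mined levelwise with candidate join-and-prune; rules A ⇒ B are emitted for
frequent A ∪ B with confidence support(A∪B)/support(A) above threshold.
Support/confidence accept percent (90) or fraction (0.9) inputs; defaults
are 0.9/0.9.  Significance uses the hypergeometric upper tail with
summation limit min(T, k), computed through the survival function in
log-space, with an exact rational-arithmetic path for small inputs.  Only
itemsets of size ≥ 2 are scored ("combinations"); the background must be
scanned with the same cutoffs, and when an itemset is absent from the
background k is clamped to t so the tail is defined (the fully enriched
worst case).  Raw p-values are reported; Benjamini–Hochberg adjustment is
opt-in.

## Synthetic data

The generator's defaults are the study conditions used throughout the
tests: background GC 0.41; TATA cassette sampled from TATAWAW at per-base
strength 0.9 planted at −31..−25; eight promoter-typical hexamers embedded
at rate 0.8 within −200..+100; for WITH_CPG records a 700-bp i.i.d.
segment with P(C) = P(G) = 0.33 spanning the TSS (G+C ≈ 0.66, CpG obs/exp
≈ 1, comfortably above the island thresholds); and a −45..−15 stability
dip written as a TA-repeat with 5% per-base noise — TA/AT steps carry the
weakest nearest-neighbor energies, so the dip reliably hosts the global ΔG
maximum, which plain AT-enrichment does not guarantee against random
AT-runs in 6-kb flanks.  Planted elements are placed by rejection sampling
(100 attempts) so they never overwrite one another.  Gene groups embed one
consensus site of every co-set TF jointly with probability 0.9 in observed
promoters (500 bp), decoy TFs at 0.3, and each TF independently at 0.05 in
the background panel.

What the generator does *not* emulate: repeat elements, isochore
structure, positional preferences of real TFBSs, correlated k-mer usage,
or the human–mouse conservation filtering used to assemble real training
sets.  Passing tests therefore demonstrate correct recovery of planted
structure under the stated noise model, not field performance on genomic
sequence.

## Problem sizes and numerics

Cross-validation benchmarks use 200 records per CpG class (6001 bp each),
the null-calibration check uses ~10⁵ scanned hexamer positions, and
co-occurrence recovery uses 10 observed vs 100 background promoters —
sizes chosen so the full suite and the acceptance script each run in well
under a minute of compute while keeping binomial/SVM asymptotics in their
calibrated regimes.  Ties are resolved deterministically everywhere
(leftmost core window, alphabetical hexamers, lexical itemset ordering),
and all stochastic steps flow from explicit seeds, so repeated runs are
byte-identical.

## Known limitations

* The classifier is trained and validated on synthetic data only; absolute
  metric values reflect the generator's effect sizes, not performance on
  genomic sequence.
* The Z-score machinery ignores word self-overlap and small-count
  skew (see above).
* The CpG detector implements the classic threshold rule, not a
  probabilistic island model.
* JASPAR matrices must be converted to the TRANSFAC text dialect by the
  user; only that dialect is parsed.
* Tandem repeats, homology search against known promoters and
  cross-species conservation display are out of scope.
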