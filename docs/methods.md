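# Methods

## Model and estimators

A document is an ordered sequence of lexical tokens; its empirical word
distribution P assigns each distinct token the relative frequency
p_i = c_i / N.  All entropies are plug-in estimates of this distribution in
bits (log base 2): Shannon H = −Σ p_i log₂ p_i at α = 1, Rényi
H_α = (1/(1−α)) log₂ Σ p_i^α elsewhere, with H₀ = log₂(vocabulary size)
and H_∞ = −log₂ p_max as the spectrum's endpoints.  α = 1 is handled by
explicit substitution with Shannon entropy (a guard band |α−1| < 1e-9 also
routes there) rather than by numerical limiting, which would suffer
catastrophic cancellation.  0·log 0 is defined as 0 and zero-count tokens
never enter a table, so every p_i is strictly positive.

The plug-in estimator is negatively biased at finite N (for Shannon,
approximately (V−1)/(2N ln 2)).  No bias correction is applied on the main
analysis path: all comparisons are between documents processed under one
common scheme, so a shared bias cancels in direction, and corrected values
would no longer be the quantities practitioners report.  A Miller–Madow
correction is available as a diagnostic (`miller_madow_correction`).

The default α grid is 0 to 2 in steps of 0.1; reported tables use the
reduced set {0, 0.5, 1, 1.5}, which spans vocabulary-size-dominated and
frequency-dominated orders while staying in the regime where group
differences are detectable.

## Preprocessing

Tokens are NFC-normalized (case preserved) and entries consisting solely
of whitespace or Unicode punctuation/symbol characters (categories P*, S*)
are dropped; numerals and Latin-script tokens are retained by default, with
a configurable drop-list.  Segmentation of raw text is delegated to a
pluggable adapter and the pipeline consumes pre-segmented token files, so
results are reproducible from the token files regardless of segmenter
version.  A document left with no lexical tokens is an error, not an empty
table.

## Paired analysis

Per pair and per α the difference Δ = H(guardian) − H(minor) is computed on
identical grids.  The Wilcoxon signed-rank test discards zero differences
(Wilcoxon's method, matching common statistical-package defaults rather
than Pratt's), midranks tied magnitudes, and for n ≤ 25 computes the exact
two-sided p-value from the conditional null distribution of W⁺ given the
observed ranks — a rank-sum convolution equivalent to enumerating all 2ⁿ
sign assignments, with p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1.  Larger
samples use the normal approximation with tie correction and a 0.5
continuity correction.  Significance is two-sided at 0.05 with no
multiplicity correction across α values (the α values are a sensitivity
sweep of one hypothesis, not independent endpoints); a Holm adjustment can
be applied downstream if desired.

Discrimination between the two versions by a single entropy feature is
computed as the rank (Mann–Whitney) AUC by pair counting.  A logistic
regression on one feature yields a score monotone in that feature, so its
ROC and AUC are identical to the feature's own; pair counting gives that
value exactly without an optimizer.  The reported cutoff maximizes
Youden's J = sensitivity + specificity − 1 over midpoints between adjacent
distinct pooled values (±∞ included), classifying value ≥ threshold as the
guardian class and breaking J-ties toward the lowest threshold.  No
threshold-selection rule is canonical; Youden's J is the package's choice,
stated as such.

## Length control

Plug-in entropy grows with document length, so the subsampling experiment
draws a fixed sample of 1000 tokens from each document, computes the
spectrum, and averages over 100 iterations before testing.  Mode matters:
subsampling m tokens WITHOUT replacement from a document of n ≥ m i.i.d.
tokens is distributionally exactly a fresh length-m document from the same
source, so it removes the length effect exactly; resampling WITH
replacement from a short document under-represents its rare types (a
singleton survives with probability 1 − (1 − 1/n)^m < 1) and leaves a
residual artifact at low α.  The default mode is therefore "auto": without
replacement whenever n ≥ sample size, with replacement only for shorter
documents; pure modes are available.  The draw is realized as counts
(multivariate hypergeometric / multinomial), which is equivalent to
token-by-token sampling and much faster.  One root seed spawns a
per-document substream keyed by document id, so adding or removing a
document never perturbs the other documents' draws.

## Grade benchmarking

Unpaired comparisons of a target document set against each grade corpus use
the two-sided rank-sum (Mann–Whitney) test — exact for small tie-free
samples, midrank normal approximation with continuity and tie correction
otherwise — chosen for consistency with the rank-based paired analysis.
The grade band is the set of grades with p > 0.05.  Band membership is
absence of evidence for a difference, not demonstrated equivalence: small
reference corpora can land in the band for lack of power, so an empty band
reports the nearest grade by absolute median difference with an
above/below flag, and equivalence testing (TOST) is the appropriate
stricter alternative when a calibrated margin exists.

## Sections and technical terms

Section boundaries are supplied editorially via the manifest as token
spans; there is no automatic section detection.  Per-section spectra obey
the same α-monotonicity as whole documents, and the section table reports
the pair-averaged Δ per (section, α).

Technical-term density is TT = matched token occurrences / total tokens,
counting occurrences (not distinct terms), so TT is the probability that a
randomly chosen token position belongs to a technical term.  Matching is
exact on normalized tokens; multi-token terms are matched as greedy longest
contiguous n-grams (n ≤ 4), each match contributing its token length to the
numerator.  Its association with tail-sensitive entropy is measured by
Spearman rank correlation across documents.

## Synthetic corpora

The generator draws documents i.i.d. from a truncated Zipf–Mandelbrot
distribution p_i ∝ (i + q)^(−s), i = 1…V — the classical rank-frequency
model of natural-language word frequencies — over a synthetic token
namespace ("w1"…"wV"); word-level entropy depends only on the frequency
profile, not the glyphs.  Defaults: exponent s = 1.1 and shift q = 2, a
mildly flattened near-Zipfian head typical of word-frequency fits.  The
paired default emulates the study pattern: 17 pairs, guardian vocabulary
2000 / length 6000 vs minor vocabulary 800 / length 1700, with four
proportional sections (15/35/30/20% of tokens).  Grade corpora use
(documents, vocabulary, length range) of (45, 250, 130–240),
(36, 800, 420–800), (23, 1600, 850–1600) for grades 2/6/9, giving strictly
increasing generator entropy and the short-text regime of graded readers.
All generator entropies are available in closed form (`true_entropy`) for
recovery tests.

What the generator does NOT emulate: word-order dependence (tokens are
i.i.d., real text has burstiness — a topic word recurs in clumps, inflating
variance of frequency estimates), section-specific vocabularies, shared
boilerplate between pair members, and segmentation noise.  Passing tests
therefore certify the estimators, the tests, and the pipeline plumbing
under a realistic frequency profile; they do not certify effect sizes on
real consent forms, where between-pair correlation and burstiness will
widen the spread of Δ.

## Problem sizes and numerical choices

The simulation-based checks run at the study's own scale (17 pairs, the
generator lengths above, 50-seed replication for pattern-reproduction
checks, 100/1000 random instances for oracle checks), which keeps the full
suite under a minute on one core while leaving the statistical conclusions
stable across seeds.  Exact tests switch to asymptotics at n > 25 (signed
rank) and n > 20 or ties (rank sum).  Entropy oracle agreement is asserted
at 1e-9 bits; α-grid monotonicity at 1e-9; probability normalization at
1e-12.  Degenerate inputs are defined, not special-cased away: a
single-type document has a flat zero spectrum, identical value lists give
AUC 0.5, and an all-zero delta vector is a reported error since the signed
rank statistic is undefined.

## Known limitations

- Entropies are word-level only; character-level entropy, n-gram structure
  and cross-entropy against language models are out of scope.
- The shipped term lexicon is a synthetic demonstration set; real analyses
  must supply a domain lexicon.
- Grade banding inherits the non-equivalence caveat above.
- No confidence intervals for AUC are provided.
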