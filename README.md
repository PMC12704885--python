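# entroread

Entropy-based lexical readability analysis of word-segmented document
corpora — built for comparing paired document versions (a simplified
edition against its original, e.g. minor-version vs guardian-version
informed consent forms) and for benchmarking document sets against
grade-level reference corpora.

Readability formulas built on syllable counts do not transfer to Chinese
text, and documents full of fragmentary structures (lists, eligibility
criteria) defeat sentence-based measures.  What does transfer is the word
frequency distribution: richer, more even vocabularies are harder to read.
`entroread` quantifies this with the Rényi entropy family of the empirical
word distribution *P* = (p₁, …, pₙ), in bits:

- Shannon entropy (α = 1): H(P) = −Σᵢ pᵢ log₂ pᵢ
- Rényi entropy of order α ≥ 0, α ≠ 1: H_α(P) = (1/(1−α)) · log₂ Σᵢ pᵢ^α
- Hartley entropy (α = 0): H₀ = log₂ n — pure vocabulary size
- min-entropy (α → ∞): H_∞ = −log₂ p_max — the most frequent word only

The spectrum over α ∈ [0, 2] is non-increasing; low orders emphasise
lexical richness, high orders emphasise the dominant words.  On top of the
spectrum the package provides:

- **paired comparison**: guardian-minus-minor entropy differences Δ per α,
  exact Wilcoxon signed-rank tests, sign counts, and single-feature ROC
  discrimination (rank AUC with Youden-J cutoffs);
- **length control**: entropy is length-sensitive, so a fixed-size
  subsampling experiment (1000 tokens × 100 iterations, averaged) separates
  genuine vocabulary differences from document-length artifacts;
- **grade banding**: rank-sum comparison of a target document set against
  grade-2/6/9 reference corpora, reporting the set of grades it is
  statistically indistinguishable from;
- **section profiles** and **technical-term density** (TT = matched token
  occurrences / total tokens) with its Spearman correlation to high-order
  entropy;
- a **synthetic corpus generator** with Zipf–Mandelbrot word frequencies
  (pᵢ ∝ (i+q)^(−s)) and closed-form true entropies, so every stage of the
  pipeline is testable without any confidential source documents.

## Worked example

Generate 17 synthetic document pairs in which the guardian version is
longer (6000 vs 1700 tokens) and lexically richer (vocabulary 2000 vs 800),
then run the paired analysis (see `examples/02_paired_comparison.py`):

```
signed-rank results per alpha (positive = guardian richer):
 alpha  p_value  n_positive  n_negative  n_zero  w_statistic method
   0.0 0.000015          17           0       0        153.0  exact
   0.5 0.000015          17           0       0        153.0  exact
   1.0 0.000015          17           0       0        153.0  exact
   1.5 0.000015          17           0       0        153.0  exact
```

All 17 guardian-minus-minor differences are positive at every order and the
exact two-sided signed-rank p-value is 2/2¹⁷ ≈ 1.5e-5: the simplified
versions use a measurably narrower vocabulary.  The companion length
control (`examples/03_length_control.py`) shows the converse: when both
versions share one generator and only lengths differ, the raw α = 0 gap is
positive in all pairs (a pure length artifact), while after 1000-token
subsampling the test is non-significant (p ≈ 0.49).  Grade banding
(`examples/04_grade_band.py`) places targets drawn from the grade-6
generator in band `['grade6']` at every α, with p < 0.001 against grades 2
and 9.

Each script in `examples/` is a narrative demo of one capability; the
`entroread` command (`synth`, `ingest`, `entropy`, `compare`,
`random-experiment`, `grade-band`, `run`) exposes the same operations for
shell use, e.g.:

```
entroread synth --out corpus --seed 4
entroread run --config run.yaml --out results/
```

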