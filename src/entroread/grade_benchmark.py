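"""Grade-level benchmarking: descriptive quartiles, unpaired comparisons
against grade reference corpora, and readability grade-band assignment.

A target document set (e.g. the minor-version consent forms) is compared
per alpha with each grade-level reference corpus by a two-sided rank-sum
(Mann–Whitney) test; the "grade band" is the set of grades whose entropy
values are NOT significantly different at the 0.05 level.  That logic is
absence-of-evidence, not equivalence: a small reference corpus may fail to
separate from the target for lack of power, so band membership is labelled
accordingly and a TOST equivalence option is available for stricter use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import RawDocument, build_frequency_table
from .entropy_core import REPORT_ALPHAS, EntropySpectrum, entropy_spectrum
from .paired_compare import ALPHA_LEVEL

__all__ = [
    "GradeBandResult",
    "grade_summary",
    "compare_to_grade",
    "assign_band",
    "spectra_for_docs",
]

_EXACT_MAX_N = 20  # exact rank-sum distribution only for small, tie-free samples


@dataclass
class GradeBandResult:
    alpha: float
    per_grade_p: dict[str, float]
    direction: dict[str, int]  # sign of median(target) - median(grade)
    median_gaps: dict[str, float] = field(default_factory=dict)
    band: set[str] = field(default_factory=set)
    nearest_grade: str | None = None  # filled when the band is empty
    position: str | None = None  # "above" / "below" / "between" all grades

    def __post_init__(self) -> None:
        self.band = {g for g, p in self.per_grade_p.items() if p > ALPHA_LEVEL}
        if not self.band:
            meds = self.median_gaps
            self.nearest_grade = min(meds, key=lambda g: abs(meds[g]))
            signs = set(self.direction.values())
            if signs == {1}:
                self.position = "above"
            elif signs == {-1}:
                self.position = "below"
            else:
                self.position = "between"


def spectra_for_docs(
    docs: Sequence[RawDocument], grid: Sequence[float] = REPORT_ALPHAS
) -> list[EntropySpectrum]:
    return [entropy_spectrum(build_frequency_table(d.sequence), tuple(grid)) for d in docs]


def grade_summary(
    groups: Mapping[str, Sequence[RawDocument]],
    alphas: Sequence[float] = REPORT_ALPHAS,
) -> pd.DataFrame:
    """Per-group quartile descriptives of word count and each entropy.

    Returns a DataFrame indexed by (group, metric) with columns q25, median,
    q75 — the descriptive table of a corpus.
    """
    rows = []
    for group, docs in groups.items():
        if len(docs) == 0:
            raise ValueError(f"group {group!r} is empty")
        spectra = spectra_for_docs(docs, alphas)
        metrics = {"word_count": [float(d.sequence.n_tokens) for d in docs]}
        for a in alphas:
            metrics[f"entropy_alpha_{a:g}"] = [s.values[a] for s in spectra]
        for metric, vals in metrics.items():
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {"group": group, "metric": metric, "q25": q25, "median": med, "q75": q75}
            )
    return pd.DataFrame(rows).set_index(["group", "metric"])


def compare_to_grade(
    target_values: Sequence[float], grade_values: Sequence[float]
) -> tuple[float, int]:
    """Two-sided rank-sum (Mann–Whitney) p-value and direction.

    Exact distribution for small tie-free samples; midrank normal
    approximation with continuity and tie correction otherwise.  Direction is
    the sign of median(target) - median(grade).
    """
    t = np.asarray(target_values, dtype=np.float64)
    g = np.asarray(grade_values, dtype=np.float64)
    if t.size == 0 or g.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([t, g])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(t.size, g.size) <= _EXACT_MAX_N) else "asymptotic"
    res = stats.mannwhitneyu(t, g, alternative="two-sided", method=method, use_continuity=True)
    direction = int(np.sign(np.median(t) - np.median(g)))
    return float(res.pvalue), direction


def assign_band(
    target_spectra: Sequence[EntropySpectrum],
    grade_spectra: Mapping[str, Sequence[EntropySpectrum]],
    alphas: Sequence[float] = REPORT_ALPHAS,
) -> list[GradeBandResult]:
    """Per-alpha grade band of a target document set.

    The band is the set of grades not significantly different from the
    target at the 0.05 level; an empty band reports the nearest grade by
    absolute median difference together with an above/below flag.
    """
    if len(grade_spectra) < 2:
        raise ValueError("need at least 2 grade corpora")
    results = []
    for a in alphas:
        tvals = [s.values[a] for s in target_spectra]
        per_p, direction, gaps = {}, {}, {}
        for grade, spectra in grade_spectra.items():
            gvals = [s.values[a] for s in spectra]
            p, d = compare_to_grade(tvals, gvals)
            per_p[grade] = p
            direction[grade] = d
            gaps[grade] = float(np.median(tvals) - np.median(gvals))
        res = GradeBandResult(a, per_p, direction, median_gaps=gaps)
        results.append(res)
    return results
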