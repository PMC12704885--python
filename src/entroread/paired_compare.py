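"""Paired guardian-minus-minor analysis: signed-rank tests, sign counts,
single-feature ROC discrimination and rank correlation.

The signed-rank test is implemented in-package because the analysis needs an
exact conditional null distribution under midranks and zero-discard (the
Wilcoxon convention): zero differences are removed, absolute differences are
midranked, and for n_used <= 25 the two-sided p-value is computed from the
exact distribution of W+ over all 2^n sign assignments (via a rank-sum
convolution, equivalent to full enumeration).  Larger samples use the normal
approximation with tie correction and continuity correction.

Discrimination between groups by a single entropy feature uses the rank
(Mann–Whitney) AUC: a logistic regression on one feature produces a score
monotone in that feature, so its ROC — and therefore its AUC — is identical
to the feature's own; pair counting computes it exactly without an optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .entropy_core import EntropySpectrum

__all__ = [
    "PairedDelta",
    "SignedRankResult",
    "RocResult",
    "paired_deltas",
    "signed_rank_test",
    "sign_counts",
    "rank_auc",
    "youden_threshold",
    "spearman_rho",
    "EXACT_MAX_N",
]

#: largest n_used for which the exact signed-rank distribution is used
EXACT_MAX_N = 25

ALPHA_LEVEL = 0.05  # two-sided significance level used in reports


@dataclass
class PairedDelta:
    """Guardian-minus-minor entropy difference for one pair at one alpha."""

    pair_id: str
    alpha: float
    h_guardian: float
    h_minor: float

    @property
    def delta(self) -> float:
        return self.h_guardian - self.h_minor


@dataclass
class SignedRankResult:
    n_used: int  # pairs remaining after zero removal
    w_statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_positive: int
    n_negative: int
    n_zero: int
    method: str  # "exact" or "normal_approx"


@dataclass
class RocResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    positive_class: str = "guardian"


def paired_deltas(
    spectra: Mapping[str, tuple[EntropySpectrum, EntropySpectrum]],
) -> list[PairedDelta]:
    """Per-(pair, alpha) differences from pair_id -> (minor, guardian) spectra.

    Both members of every pair must share an identical alpha grid.
    """
    offenders = [pid for pid, (m, g) in spectra.items() if m.grid != g.grid]
    if offenders:
        raise ValueError(f"mismatched alpha grids for pairs: {sorted(offenders)}")
    out = []
    for pid, (minor, guardian) in spectra.items():
        for a in minor.grid:
            out.append(PairedDelta(pid, a, guardian.values[a], minor.values[a]))
    return out


def _exact_two_sided_p(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """Exact two-sided p for W+ given integer (doubled) midranks.

    Convolves the sign-assignment generating polynomial; identical to
    enumerating all 2^n assignments.  Two-sided p = 2 * min(P(W+ <= w),
    P(W+ >= w)), capped at 1.
    """
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:-r] if r else dist
        dist = 0.5 * (dist + shifted)
    lower = dist[: doubled_w + 1].sum()
    upper = dist[doubled_w:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def signed_rank_test(deltas: Sequence[float]) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test with zero-discard and midranks."""
    d = np.asarray(deltas, dtype=np.float64)
    n_zero = int((d == 0).sum())
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("no nonzero differences")
    ranks = stats.rankdata(np.abs(nz))  # midranks; doubled they are integers
    w_plus = float(ranks[nz > 0].sum())
    n_used = nz.size
    if n_used <= EXACT_MAX_N:
        doubled = np.rint(2 * ranks).astype(np.int64)
        p = _exact_two_sided_p(doubled, int(round(2 * w_plus)))
        method = "exact"
    else:
        mu = n_used * (n_used + 1) / 4.0
        var = n_used * (n_used + 1) * (2 * n_used + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= ((tie_counts**3 - tie_counts) / 48.0).sum()
        z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        method = "normal_approx"
    return SignedRankResult(n_used, w_plus, p, n_pos, n_neg, n_zero, method)


def sign_counts(deltas: Sequence[float]) -> tuple[int, int, int]:
    """(positive, negative, zero) counts of a delta vector."""
    d = np.asarray(deltas, dtype=np.float64)
    return int((d > 0).sum()), int((d < 0).sum()), int((d == 0).sum())


def rank_auc(minor_values: Sequence[float], guardian_values: Sequence[float]) -> float:
    """AUC for classifying guardian (positive) vs minor by a single feature.

    Mann–Whitney pair counting: (#{g > m} + 0.5 #{g == m}) / (n_g * n_m).
    """
    m = np.asarray(minor_values, dtype=np.float64)
    g = np.asarray(guardian_values, dtype=np.float64)
    if m.size == 0 or g.size == 0:
        raise ValueError("both value lists must be non-empty")
    diff = g[:, None] - m[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def youden_threshold(
    minor_values: Sequence[float],
    guardian_values: Sequence[float],
    positive_class: str = "guardian",
) -> RocResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Classifies value >= threshold as the positive (guardian) class.
    Candidate thresholds are midpoints between adjacent distinct pooled
    values plus -inf / +inf; on ties in J the lowest threshold wins.
    """
    m = np.asarray(minor_values, dtype=np.float64)
    g = np.asarray(guardian_values, dtype=np.float64)
    if m.size == 0 or g.size == 0:
        raise ValueError("both value lists must be non-empty")
    pooled = np.unique(np.concatenate([m, g]))
    candidates = np.concatenate([[-np.inf], (pooled[:-1] + pooled[1:]) / 2.0, [np.inf]])
    best = None
    for t in candidates:
        sens = float((g >= t).mean())
        spec = float((m < t).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return RocResult(rank_auc(m, g), float(t), sens, spec, positive_class)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation on midranks with two-sided p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("undefined correlation: constant input vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_test_table(
    deltas: Iterable[PairedDelta], alphas: Sequence[float] | None = None
):
    """Signed-rank summary per alpha (the headline paired-comparison table).

    Returns a pandas DataFrame with columns alpha, p_value, n_positive,
    n_negative, n_zero, w_statistic, method.
    """
    import pandas as pd

    by_alpha: dict[float, list[float]] = {}
    for d in deltas:
        by_alpha.setdefault(d.alpha, []).append(d.delta)
    rows = []
    for a in sorted(by_alpha):
        if alphas is not None and a not in alphas:
            continue
        res = signed_rank_test(by_alpha[a])
        rows.append(
            {
                "alpha": a,
                "p_value": res.p_value,
                "n_positive": res.n_positive,
                "n_negative": res.n_negative,
                "n_zero": res.n_zero,
                "w_statistic": res.w_statistic,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def roc_table(
    spectra_minor: Sequence[EntropySpectrum],
    spectra_guardian: Sequence[EntropySpectrum],
    alphas: Sequence[float],
):
    """Per-alpha AUC / threshold / sensitivity / specificity table."""
    import pandas as pd

    rows = []
    for a in alphas:
        m = [s.values[a] for s in spectra_minor]
        g = [s.values[a] for s in spectra_guardian]
        roc = youden_threshold(m, g)
        rows.append(
            {
                "alpha": a,
                "auc": roc.auc,
                "threshold": roc.threshold,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        )
    return pd.DataFrame(rows)
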