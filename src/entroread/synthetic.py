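"""Synthetic corpora with Zipf–Mandelbrot word-frequency structure.

Natural-language word frequencies follow a rank-frequency power law
p_i ∝ (i + q)^(-s); generating documents as i.i.d. draws from a truncated
Zipf–Mandelbrot distribution reproduces the heavy-tailed frequency profiles
the entropy analysis is sensitive to, while leaving every generating
entropy available in closed form for recovery tests.  Tokens are a
synthetic namespace ("w1" ... "wV"): word-level entropy depends only on the
frequency profile, not on the glyphs.

Defaults emulate the study conditions: 17 minor/guardian pairs where the
guardian version is longer (6000 vs 1700 tokens) and lexically richer
(vocabulary 2000 vs 800), and grade-reference corpora whose generator
entropy and document length both increase with grade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
import zlib

import numpy as np
import pandas as pd

from .corpus_io import Group, RawDocument, TokenSequence
from .section_profile import SECTION_LABELS, TermLexicon

__all__ = [
    "ZipfMandelbrotParams",
    "PairedCorpusSpec",
    "GradeCorpusSpec",
    "zipf_probabilities",
    "true_entropy",
    "sample_document",
    "generate_paired_corpus",
    "generate_grade_corpus",
    "inject_terms",
    "demo_lexicon",
    "write_corpus",
]

#: proportional section split (introduction, procedures, risk_benefit, rights_other)
_SECTION_FRACTIONS = (0.15, 0.35, 0.30, 0.20)


@dataclass(frozen=True)
class ZipfMandelbrotParams:
    """Truncated Zipf–Mandelbrot distribution p_i ∝ (i+q)^(-s), i = 1..V.

    exponent s ≈ 1 and a small shift q are classical for word frequencies;
    s = 0 is allowed (uniform) so null configurations are expressible.
    """

    vocab_size: int
    exponent: float = 1.1
    shift: float = 2.0

    def __post_init__(self) -> None:
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")


def zipf_probabilities(params: ZipfMandelbrotParams) -> np.ndarray:
    """Normalized, non-increasing probability vector of length V."""
    ranks = np.arange(1, params.vocab_size + 1, dtype=np.float64)
    w = (ranks + params.shift) ** (-params.exponent)
    return w / w.sum()


def true_entropy(params: ZipfMandelbrotParams, alpha: float) -> float:
    """Exact entropy (bits) of the generating distribution at order alpha."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = zipf_probabilities(params)
    if alpha == 0:
        return float(np.log2(p.size))
    if abs(alpha - 1.0) < 1e-9:
        return float(-(p * np.log2(p)).sum())
    return float(np.log2((p**alpha).sum()) / (1.0 - alpha))


def _rng_for(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def sample_document(
    params: ZipfMandelbrotParams,
    length: int,
    rng: np.random.Generator,
    doc_id: str = "doc",
) -> TokenSequence:
    """An i.i.d. document of ``length`` tokens drawn from the generator."""
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = rng.choice(params.vocab_size, size=length, p=zipf_probabilities(params))
    return TokenSequence(doc_id, [f"w{i + 1}" for i in idx])


def _proportional_sections(n_tokens: int) -> list[tuple[str, tuple[int, int]]]:
    bounds = np.rint(np.cumsum((0.0,) + _SECTION_FRACTIONS) * n_tokens).astype(int)
    return [
        (label, (int(bounds[i]), int(bounds[i + 1])))
        for i, label in enumerate(SECTION_LABELS)
    ]


@dataclass
class PairedCorpusSpec:
    """Generator configuration for paired minor/guardian corpora."""

    n_pairs: int = 17
    minor_params: ZipfMandelbrotParams = ZipfMandelbrotParams(800)
    guardian_params: ZipfMandelbrotParams = ZipfMandelbrotParams(2000)
    minor_length: int = 1700
    guardian_length: int = 6000
    with_sections: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.minor_length < 1 or self.guardian_length < 1:
            raise ValueError("lengths must be >= 1")


def generate_paired_corpus(spec: PairedCorpusSpec) -> list[RawDocument]:
    """n_pairs minor/guardian documents with pair ids and optional sections.

    Deterministic in spec.seed; each document draws from its own substream,
    so changing n_pairs does not perturb earlier documents.
    """
    docs = []
    for k in range(1, spec.n_pairs + 1):
        pid = f"p{k:02d}"
        for group, params, length in (
            (Group.MINOR, spec.minor_params, spec.minor_length),
            (Group.GUARDIAN, spec.guardian_params, spec.guardian_length),
        ):
            doc_id = f"{pid}_{group.value}"
            seq = sample_document(params, length, _rng_for(spec.seed, doc_id), doc_id)
            sections = _proportional_sections(seq.n_tokens) if spec.with_sections else []
            docs.append(RawDocument(doc_id, group, seq.tokens, pair_id=pid, sections=sections))
    return docs


#: grade corpora emulate short, progressively richer reference texts
_DEFAULT_GRADE_SPECS: dict[str, tuple[int, ZipfMandelbrotParams, tuple[int, int]]] = {
    "grade2": (45, ZipfMandelbrotParams(250, 1.0, 2.0), (130, 240)),
    "grade6": (36, ZipfMandelbrotParams(800, 1.0, 2.0), (420, 800)),
    "grade9": (23, ZipfMandelbrotParams(1600, 1.0, 2.0), (850, 1600)),
}


@dataclass
class GradeCorpusSpec:
    """Per-grade (n_docs, params, length_range) generator configuration."""

    grades: dict[str, tuple[int, ZipfMandelbrotParams, tuple[int, int]]] = field(
        default_factory=lambda: dict(_DEFAULT_GRADE_SPECS)
    )
    seed: int = 0


def generate_grade_corpus(spec: GradeCorpusSpec) -> dict[str, list[RawDocument]]:
    """Grade-labelled reference documents, deterministic in spec.seed."""
    corpora: dict[str, list[RawDocument]] = {}
    for grade, (n_docs, params, (lo, hi)) in spec.grades.items():
        docs = []
        for k in range(1, n_docs + 1):
            doc_id = f"{grade}_{k:03d}"
            rng = _rng_for(spec.seed, doc_id)
            length = int(rng.integers(lo, hi + 1))
            seq = sample_document(params, length, rng, doc_id)
            docs.append(RawDocument(doc_id, Group(grade), seq.tokens))
        corpora[grade] = docs
    return corpora


def inject_terms(
    seq: TokenSequence,
    lexicon: TermLexicon,
    rate: float,
    rng: np.random.Generator,
) -> TokenSequence:
    """Independently replace each token by a uniform lexicon term w.p. rate."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0 or lexicon.size == 0:
        return TokenSequence(seq.doc_id, list(seq.tokens))
    terms = sorted(lexicon.terms)
    mask = rng.random(seq.n_tokens) < rate
    picks = rng.integers(0, len(terms), size=seq.n_tokens)
    tokens = [terms[picks[i]] if mask[i] else tok for i, tok in enumerate(seq.tokens)]
    return TokenSequence(seq.doc_id, tokens)


def demo_lexicon(n_terms: int = 50) -> TermLexicon:
    """A demonstration technical-term lexicon in its own token namespace."""
    return TermLexicon(frozenset(f"term{j}" for j in range(1, n_terms + 1)))


def write_corpus(
    docs: Sequence[RawDocument] | Mapping[str, Sequence[RawDocument]],
    out_dir: str | Path,
    meta: dict | None = None,
) -> Path:
    """Write token files, section files and a TSV manifest readable by
    :func:`entroread.corpus_io.read_corpus`; returns the manifest path."""
    if isinstance(docs, Mapping):
        docs = [d for group_docs in docs.values() for d in group_docs]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in docs:
        token_file = f"{doc.doc_id}.tokens.txt"
        (out_dir / token_file).write_text("\n".join(doc.tokens) + "\n", encoding="utf-8")
        section_file = ""
        if doc.sections:
            section_file = f"{doc.doc_id}.sections.tsv"
            pd.DataFrame(
                [
                    {"label": label, "start": start, "stop": stop}
                    for label, (start, stop) in doc.sections
                ]
            ).to_csv(out_dir / section_file, sep="\t", index=False)
        rows.append(
            {
                "doc_id": doc.doc_id,
                "path": token_file,
                "group": doc.group.value,
                "pair_id": doc.pair_id or "",
                "section_file": section_file,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if meta is not None:
        (out_dir / "corpus_meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return manifest
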