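"""Corpus ingestion: documents, manifests, token filtering and frequency tables.

The analysis pipeline is deliberately segmenter-free: it consumes either
pre-segmented token streams (one token per line, or whitespace-delimited) or
raw text routed through a pluggable segmentation adapter.  Word segmentation
of Chinese text is environment-dependent, so keeping it behind an adapter
makes every downstream number reproducible from the token files alone.
"""

from __future__ import annotations

import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "RawDocument",
    "TokenSequence",
    "FrequencyTable",
    "filter_tokens",
    "build_frequency_table",
    "read_corpus",
    "read_token_file",
    "write_frequency_table",
    "read_frequency_table",
    "register_segment_adapter",
    "get_segment_adapter",
]


class Group(str, Enum):
    """Document group labels used throughout the analysis."""

    MINOR = "minor"
    GUARDIAN = "guardian"
    GRADE2 = "grade2"
    GRADE6 = "grade6"
    GRADE9 = "grade9"
    OTHER = "other"


class CorpusError(ValueError):
    """Raised for malformed manifests, documents or token streams."""


@dataclass
class TokenSequence:
    """An ordered sequence of lexical tokens for one document."""

    doc_id: str
    tokens: list[str]

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass
class RawDocument:
    """One document with its group label, optional pairing and sections.

    ``sections`` is an ordered list of ``(label, (start, stop))`` token spans
    (half-open, on the filtered token sequence); spans must be disjoint and
    within bounds.
    """

    doc_id: str
    group: Group
    tokens: list[str]
    pair_id: str | None = None
    sections: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        prev_stop = None
        for label, (start, stop) in self.sections:
            if not (0 <= start <= stop <= len(self.tokens)):
                raise CorpusError(
                    f"{self.doc_id}: section {label!r} span ({start}, {stop}) "
                    f"out of bounds for {len(self.tokens)} tokens"
                )
            if prev_stop is not None and start < prev_stop:
                raise CorpusError(f"{self.doc_id}: overlapping section spans at {label!r}")
            prev_stop = stop

    @property
    def sequence(self) -> TokenSequence:
        return TokenSequence(self.doc_id, self.tokens)

    def section_sequence(self, label: str) -> TokenSequence:
        for sec_label, (start, stop) in self.sections:
            if sec_label == label:
                return TokenSequence(f"{self.doc_id}:{label}", self.tokens[start:stop])
        raise KeyError(f"{self.doc_id}: no section {label!r}")

    @property
    def section_labels(self) -> list[str]:
        return [label for label, _ in self.sections]


@dataclass
class FrequencyTable:
    """Token multiplicities and the empirical distribution they induce.

    ``probs`` returns relative frequencies p_i = count_i / N; every p_i is
    strictly positive because zero-count tokens never enter a table.
    """

    counts: dict[str, int]
    doc_id: str = ""

    def __post_init__(self) -> None:
        if not self.counts:
            raise CorpusError("empty frequency table")
        if any(c <= 0 for c in self.counts.values()):
            raise CorpusError("frequency table counts must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def vocab_size(self) -> int:
        return len(self.counts)

    @property
    def probs(self) -> dict[str, float]:
        n = self.total
        return {tok: c / n for tok, c in self.counts.items()}

    def prob_vector(self) -> np.ndarray:
        """Probabilities as a dense vector (token order = insertion order)."""
        c = np.fromiter(self.counts.values(), dtype=np.float64, count=len(self.counts))
        return c / c.sum()

    def count_vector(self) -> np.ndarray:
        return np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))

    @property
    def tokens(self) -> list[str]:
        return list(self.counts)


def _is_lexical(token: str) -> bool:
    # lexical = at least one character that is neither whitespace nor in a
    # Unicode punctuation (P*) or symbol (S*) category
    for ch in token:
        if ch.isspace():
            continue
        if unicodedata.category(ch)[0] in ("P", "S"):
            continue
        return True
    return False


def filter_tokens(
    tokens: Iterable[str],
    doc_id: str = "",
    extra_drop: Iterable[str] = (),
) -> TokenSequence:
    """Drop punctuation-only / whitespace-only entries, keep lexical tokens.

    Tokens are NFC-normalized (case preserved) so that counting is identical
    across platforms.  ``extra_drop`` adds exact token strings to remove, e.g.
    for configurable numeral or Latin-script drop-lists.

    Raises :class:`CorpusError` if nothing lexical remains.
    """
    drop = set(extra_drop)
    kept = []
    for tok in tokens:
        norm = unicodedata.normalize("NFC", tok)
        if norm in drop:
            continue
        if _is_lexical(norm):
            kept.append(norm)
    if not kept:
        raise CorpusError(f"document {doc_id or '<anonymous>'} has no lexical content")
    return TokenSequence(doc_id, kept)


def build_frequency_table(seq: TokenSequence) -> FrequencyTable:
    """Exact token multiplicities of a non-empty token sequence."""
    if seq.n_tokens == 0:
        raise CorpusError(f"document {seq.doc_id}: empty token sequence")
    return FrequencyTable(dict(Counter(seq.tokens)), doc_id=seq.doc_id)


# ---------------------------------------------------------------------------
# segmentation adapters

_SEGMENT_ADAPTERS: dict[str, Callable[[str], list[str]]] = {}


def register_segment_adapter(name: str, fn: Callable[[str], list[str]]) -> None:
    """Register a raw-text -> token-list segmentation adapter."""
    _SEGMENT_ADAPTERS[name] = fn


def get_segment_adapter(name: str) -> Callable[[str], list[str]]:
    if name in _SEGMENT_ADAPTERS:
        return _SEGMENT_ADAPTERS[name]
    if name == "whitespace":
        return str.split
    if name == "jieba":  # optional third-party segmenter, loaded lazily
        import jieba  # type: ignore

        return lambda text: list(jieba.cut(text))
    raise CorpusError(f"unknown segmentation adapter {name!r}")


register_segment_adapter("whitespace", str.split)


# ---------------------------------------------------------------------------
# manifest and file I/O

MANIFEST_COLUMNS = ["doc_id", "path", "group", "pair_id", "section_file"]


def read_token_file(path: Path) -> list[str]:
    """One token per line; blank lines ignored."""
    text = Path(path).read_text(encoding="utf-8")
    return [line for line in text.splitlines() if line.strip()]


def _read_sections(path: Path, doc_id: str) -> list[tuple[str, tuple[int, int]]]:
    """Section file: TSV with columns label, start, stop (half-open spans)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    if not {"label", "start", "stop"} <= set(df.columns):
        raise CorpusError(f"{path}: section file needs columns label, start, stop")
    return [(r.label, (int(r.start), int(r.stop))) for r in df.itertuples()]


def read_corpus(
    manifest_path: str | Path,
    pretokenized: bool = True,
    segment_adapter: str = "whitespace",
    require_pairing: bool = False,
    extra_drop: Iterable[str] = (),
) -> list[RawDocument]:
    """Read a TSV manifest (doc_id, path, group, pair_id, section_file) and
    its referenced documents, applying token filtering.

    Paths in the manifest are resolved relative to the manifest's directory.
    With ``require_pairing``, every minor/guardian document must carry a
    pair_id and every pair_id must map to exactly one minor and one guardian.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CorpusError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = {"doc_id", "path", "group"} - set(df.columns)
    if missing_cols:
        raise CorpusError(f"{manifest_path}: missing manifest columns {sorted(missing_cols)}")

    seen: set[str] = set()
    docs: list[RawDocument] = []
    for idx, row in enumerate(df.itertuples(), start=2):  # header is line 1
        doc_id = row.doc_id
        if doc_id in seen:
            raise CorpusError(f"{manifest_path} line {idx}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        path = base / row.path
        if not path.exists():
            raise CorpusError(f"{manifest_path} line {idx}: file not found: {path}")
        try:
            if pretokenized:
                raw = read_token_file(path)
            else:
                raw = get_segment_adapter(segment_adapter)(path.read_text(encoding="utf-8"))
        except UnicodeDecodeError as exc:
            raise CorpusError(f"{manifest_path} line {idx}: {path} is not valid UTF-8") from exc
        seq = filter_tokens(raw, doc_id=doc_id, extra_drop=extra_drop)
        pair_id = getattr(row, "pair_id", "") or None
        sections: list[tuple[str, tuple[int, int]]] = []
        section_file = getattr(row, "section_file", "")
        if section_file:
            sections = _read_sections(base / section_file, doc_id)
        docs.append(RawDocument(doc_id, Group(row.group), seq.tokens, pair_id, sections))

    if require_pairing:
        validate_pairing(docs)
    return docs


def validate_pairing(docs: Sequence[RawDocument]) -> dict[str, tuple[RawDocument, RawDocument]]:
    """Check minor/guardian pairing; return pair_id -> (minor, guardian)."""
    pairs: dict[str, dict[Group, RawDocument]] = {}
    offenders = []
    for doc in docs:
        if doc.group not in (Group.MINOR, Group.GUARDIAN):
            continue
        if not doc.pair_id:
            offenders.append(f"{doc.doc_id} ({doc.group.value}) has no pair_id")
            continue
        slot = pairs.setdefault(doc.pair_id, {})
        if doc.group in slot:
            offenders.append(f"pair {doc.pair_id}: duplicate {doc.group.value} member")
        slot[doc.group] = doc
    for pid, members in pairs.items():
        for g in (Group.MINOR, Group.GUARDIAN):
            if g not in members:
                offenders.append(f"pair {pid}: missing {g.value} member")
    if offenders:
        raise CorpusError("invalid pairing: " + "; ".join(sorted(offenders)))
    return {pid: (m[Group.MINOR], m[Group.GUARDIAN]) for pid, m in pairs.items()}


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    """TSV with columns token, count, prob (counts round-trip exactly)."""
    n = table.total
    df = pd.DataFrame(
        {
            "token": list(table.counts),
            "count": list(table.counts.values()),
            "prob": [c / n for c in table.counts.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | Path, doc_id: str = "") -> FrequencyTable:
    df = pd.read_csv(path, sep="\t", dtype={"token": str, "count": np.int64})
    return FrequencyTable(dict(zip(df["token"], df["count"].astype(int))), doc_id=doc_id)
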