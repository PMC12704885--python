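"""End-to-end analysis runs: ingest -> entropy -> comparisons -> report.

The orchestrator contains no computation of its own; every report table is
produced by exactly one module operation, and a run record (config echo,
seed, package version, timestamps) makes deterministic stages re-runnable
bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .corpus_io import Group, RawDocument, build_frequency_table, read_corpus, validate_pairing
from .entropy_core import DEFAULT_GRID, REPORT_ALPHAS, entropy_spectrum
from .grade_benchmark import assign_band, grade_summary, spectra_for_docs
from .length_control import SubsampleConfig, run_random_experiment
from .paired_compare import paired_deltas, paired_test_table, roc_table
from .section_profile import read_lexicon, section_delta_table, tt_density
from .synthetic import (
    GradeCorpusSpec,
    PairedCorpusSpec,
    ZipfMandelbrotParams,
    demo_lexicon,
    generate_grade_corpus,
    generate_paired_corpus,
)

__all__ = ["AnalysisReport", "run_full_analysis", "load_config"]

_GRADE_GROUPS = (Group.GRADE2, Group.GRADE6, Group.GRADE9)

_KNOWN_KEYS = {
    "seed",
    "alphas",
    "full_sweep",
    "manifest",
    "pretokenized",
    "synthetic",
    "subsample",
    "lexicon",
    "skip",
}
_KNOWN_SYNTH_KEYS = {
    "n_pairs",
    "minor_vocab",
    "guardian_vocab",
    "minor_length",
    "guardian_length",
    "exponent",
    "shift",
    "grades",
}
_KNOWN_SUBSAMPLE_KEYS = {"sample_size", "iterations", "mode"}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class AnalysisReport:
    """All analysis tables of one run, plus the run record.

    Tables that a configuration skips are present as None with the reason in
    ``skipped``.
    """

    descriptives: pd.DataFrame | None = None
    paired_tests: pd.DataFrame | None = None
    roc: pd.DataFrame | None = None
    section_deltas: pd.DataFrame | None = None
    random_experiment: pd.DataFrame | None = None
    grade_bands: pd.DataFrame | None = None
    tt_table: pd.DataFrame | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    run_record: dict[str, Any] = field(default_factory=dict)

    _TABLES = (
        "descriptives",
        "paired_tests",
        "roc",
        "section_deltas",
        "random_experiment",
        "grade_bands",
        "tt_table",
    )

    def write(self, out_dir: str | Path) -> None:
        """Write every table as TSV plus the run record as JSON.

        Files are written to a temporary name and renamed into place so a
        crash never leaves a truncated table behind.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df = getattr(self, name)
            if df is None:
                continue
            _atomic_write(out_dir / f"{name}.tsv", df.to_csv(sep="\t", index=False))
        record = dict(self.run_record)
        record["skipped"] = self.skipped
        _atomic_write(out_dir / "run_record.json", json.dumps(record, indent=2, default=str))


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def load_config(path_or_mapping: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load and validate a run configuration (YAML file or mapping)."""
    if isinstance(path_or_mapping, (str, Path)):
        config = yaml.safe_load(Path(path_or_mapping).read_text(encoding="utf-8"))
    else:
        config = dict(path_or_mapping)
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for sub, known in (("synthetic", _KNOWN_SYNTH_KEYS), ("subsample", _KNOWN_SUBSAMPLE_KEYS)):
        bad = set(config.get(sub) or {}) - known
        if bad:
            raise ValueError(f"unknown {sub} configuration keys: {sorted(bad)}")
    if "manifest" not in config and "synthetic" not in config:
        raise ValueError("configuration needs either 'manifest' or 'synthetic'")
    return config


def _build_corpus(config: Mapping[str, Any], seed: int) -> list[RawDocument]:
    if "manifest" in config:
        return read_corpus(config["manifest"], pretokenized=config.get("pretokenized", True))
    synth = dict(config.get("synthetic") or {})
    zm = lambda v: ZipfMandelbrotParams(  # noqa: E731
        v, synth.get("exponent", 1.1), synth.get("shift", 2.0)
    )
    paired_spec = PairedCorpusSpec(
        n_pairs=synth.get("n_pairs", 17),
        minor_params=zm(synth.get("minor_vocab", 800)),
        guardian_params=zm(synth.get("guardian_vocab", 2000)),
        minor_length=synth.get("minor_length", 1700),
        guardian_length=synth.get("guardian_length", 6000),
        seed=seed,
    )
    docs = generate_paired_corpus(paired_spec)
    if synth.get("grades", True):
        grade_docs = generate_grade_corpus(GradeCorpusSpec(seed=seed))
        for group_docs in grade_docs.values():
            docs.extend(group_docs)
    return docs


def run_full_analysis(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run every analysis stage a configuration requests.

    Stages: descriptives, paired tests, ROC, section deltas, the fixed-size
    subsampling experiment, grade bands, and technical-term densities.  A
    stage whose inputs are absent (no pairs, no grade corpora, no sections,
    no lexicon) is recorded as skipped with the reason; any other stage
    failure aborts the run with a stage-named error.
    """
    config = load_config(config)
    seed = int(config.get("seed", 0))
    alphas = tuple(config.get("alphas", REPORT_ALPHAS))
    grid = DEFAULT_GRID if config.get("full_sweep", False) else alphas
    skip = set(config.get("skip") or ())
    report = AnalysisReport()
    report.run_record = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "alphas": list(alphas),
        "entroread_version": __version__,
        "started": _dt.datetime.now().isoformat(timespec="seconds"),
    }

    def _stage(name, fn):
        if name in skip:
            report.skipped[name] = "skipped by configuration"
            return
        try:
            fn()
        except BaseException as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    docs = _build_corpus(config, seed)
    by_group: dict[Group, list[RawDocument]] = {}
    for d in docs:
        by_group.setdefault(d.group, []).append(d)
    minors = by_group.get(Group.MINOR, [])
    guardians = by_group.get(Group.GUARDIAN, [])
    pairs = validate_pairing(docs) if minors or guardians else {}

    def descriptives():
        groups = {g.value: ds for g, ds in by_group.items()}
        report.descriptives = grade_summary(groups, alphas).reset_index()

    def paired():
        if not pairs:
            report.skipped["paired_tests"] = "no minor/guardian pairs in corpus"
            return
        spectra = {
            pid: (
                entropy_spectrum(build_frequency_table(m.sequence), grid),
                entropy_spectrum(build_frequency_table(g.sequence), grid),
            )
            for pid, (m, g) in pairs.items()
        }
        report.paired_tests = paired_test_table(paired_deltas(spectra), alphas)

    def roc():
        if not pairs:
            report.skipped["roc"] = "no minor/guardian pairs in corpus"
            return
        sm = spectra_for_docs([m for m, _ in pairs.values()], alphas)
        sg = spectra_for_docs([g for _, g in pairs.values()], alphas)
        report.roc = roc_table(sm, sg, alphas)

    def sections():
        sectioned = {pid: mg for pid, mg in pairs.items() if mg[0].sections and mg[1].sections}
        if not sectioned:
            report.skipped["section_deltas"] = "no sectioned pairs in corpus"
            return
        report.section_deltas = section_delta_table(sectioned, alphas).reset_index()

    def random_experiment():
        if not pairs:
            report.skipped["random_experiment"] = "no minor/guardian pairs in corpus"
            return
        sub = dict(config.get("subsample") or {})
        sub_config = SubsampleConfig(
            sample_size=sub.get("sample_size", 1000),
            iterations=sub.get("iterations", 100),
            mode=sub.get("mode", "auto"),
            seed=seed,
        )
        seq_pairs = {pid: (m.sequence, g.sequence) for pid, (m, g) in pairs.items()}
        report.random_experiment = run_random_experiment(seq_pairs, grid, sub_config)

    def grade_bands():
        grade_groups = {
            g.value: by_group[g] for g in _GRADE_GROUPS if by_group.get(g)
        }
        if len(grade_groups) < 2 or not minors:
            report.skipped["grade_bands"] = "needs minor documents and >= 2 grade corpora"
            return
        target = spectra_for_docs(minors, alphas)
        grade_spectra = {g: spectra_for_docs(ds, alphas) for g, ds in grade_groups.items()}
        rows = []
        for res in assign_band(target, grade_spectra, alphas):
            for grade in sorted(res.per_grade_p):
                rows.append(
                    {
                        "alpha": res.alpha,
                        "grade": grade,
                        "p_value": res.per_grade_p[grade],
                        "direction": res.direction[grade],
                        "in_band": grade in res.band,
                        "nearest_grade": res.nearest_grade or "",
                        "position": res.position or "",
                    }
                )
        report.grade_bands = pd.DataFrame(rows)

    def tt():
        lexicon_cfg = config.get("lexicon")
        if lexicon_cfg is None:
            report.skipped["tt_table"] = "no lexicon configured"
            return
        lexicon = demo_lexicon() if lexicon_cfg == "demo" else read_lexicon(lexicon_cfg)
        rows = [
            {"doc_id": d.doc_id, "group": d.group.value, "tt": tt_density(d.sequence, lexicon)}
            for d in docs
        ]
        report.tt_table = pd.DataFrame(rows)

    _stage("descriptives", descriptives)
    _stage("paired_tests", paired)
    _stage("roc", roc)
    _stage("section_deltas", sections)
    _stage("random_experiment", random_experiment)
    _stage("grade_bands", grade_bands)
    _stage("tt_table", tt)

    report.run_record["finished"] = _dt.datetime.now().isoformat(timespec="seconds")
    if out_dir is not None:
        report.write(out_dir)
    return report
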