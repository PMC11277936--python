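"""Deterministic rule-based labeling of free-text radiology reports.

Decides pneumothorax presence from report text and classifies positives as
large or small — the task an external LLM labeler performs in production
pipelines. The rule engine is a NegEx-style keyword matcher: a disease
mention counts only outside the forward scope of a negation cue, size is
decided first by a parsed apex-to-cupola measurement against the ACCP 3 cm
rule and otherwise by a size-adjective lexicon near the mention. An
external labeler (e.g. an LLM endpoint) can be plugged in through
``ExternalLabeler``; no network code is bundled.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Protocol

import pandas as pd

__all__ = [
    "ReportLabel",
    "Lexicon",
    "load_default_lexicon",
    "extract_label",
    "parse_size_measurement",
    "label_corpus",
    "ExternalLabeler",
    "SIZE_THRESHOLD_CM",
]

SIZE_THRESHOLD_CM = 3.0  # ACCP rule: large >= 3 cm apex-to-cupola

_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?|[a-zA-Z]+")
_SENTENCE_RE = re.compile(r"[.;!?]\s+|\n")


@dataclass(frozen=True)
class ReportLabel:
    id: str
    present: bool
    size_class: str  # large | small | unspecified | none
    matched_rule: str
    measurement_cm: float | None = None

    def __post_init__(self) -> None:
        if (self.size_class == "none") != (not self.present):
            raise ValueError("size_class must be 'none' iff present is False")


class ExternalLabeler(Protocol):
    """Contract for a pluggable labeler (e.g. an LLM): text in, label out."""

    def __call__(self, report_id: str, text: str) -> ReportLabel: ...


@dataclass(frozen=True)
class Lexicon:
    mentions: frozenset[tuple[str, ...]]
    negations: frozenset[tuple[str, ...]]
    size_large: frozenset[tuple[str, ...]]
    size_small: frozenset[tuple[str, ...]]

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "Lexicon":
        cats: dict[str, set[tuple[str, ...]]] = {
            "mention": set(), "negation": set(),
            "size_large": set(), "size_small": set(),
        }
        for raw in lines:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            term, _, cat = line.rpartition("\t")
            if cat not in cats:
                raise ValueError(f"unknown lexicon category {cat!r}")
            cats[cat].add(tuple(term.lower().split()))
        return cls(
            mentions=frozenset(cats["mention"]),
            negations=frozenset(cats["negation"]),
            size_large=frozenset(cats["size_large"]),
            size_small=frozenset(cats["size_small"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        return cls.from_lines(Path(path).read_text().splitlines())


def load_default_lexicon() -> Lexicon:
    text = resources.files("pneumocl.data").joinpath("lexicon.txt").read_text()
    return Lexicon.from_lines(text.splitlines())


_DEFAULT: Lexicon | None = None


def _default_lexicon() -> Lexicon:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_default_lexicon()
    return _DEFAULT


def _sentences(text: str) -> list[list[str]]:
    return [
        [t.lower() for t in _TOKEN_RE.findall(sent)]
        for sent in _SENTENCE_RE.split(text)
        if sent.strip()
    ]


def _match_at(tokens: list[str], i: int, terms) -> tuple[str, ...] | None:
    for term in terms:
        if tuple(tokens[i : i + len(term)]) == term:
            return term
    return None


def _scan_sentence(tokens: list[str], lex: Lexicon):
    """Return (mention index, negated?, blocking cue) for each mention.

    Negation scope is forward-only, from the cue to the end of the
    sentence — the simple NegEx convention.
    """
    neg_from: int | None = None
    cue: tuple[str, ...] | None = None
    out = []
    i = 0
    while i < len(tokens):
        term = _match_at(tokens, i, lex.negations)
        if term is not None and neg_from is None:
            neg_from, cue = i, term
            i += len(term)
            continue
        if _match_at(tokens, i, lex.mentions):
            negated = neg_from is not None and i > neg_from
            out.append((i, negated, cue if negated else None))
        i += 1
    return out


def parse_size_measurement(
    text: str, lexicon: Lexicon | None = None, window: int = 6
) -> float | None:
    """First lesion measurement near a pneumothorax mention, in cm.

    A number followed by a ``cm``/``mm`` unit token counts only when it
    lies within ``window`` tokens of a mention in the same sentence (so a
    cardiac or unrelated measurement elsewhere in the report is ignored);
    mm values are converted to cm. Absence is a value, not an error.
    """
    lex = lexicon or _default_lexicon()
    for tokens in _sentences(text):
        mention_idx = [i for i, _, _ in _scan_sentence(tokens, lex)]
        if not mention_idx:
            continue
        for i, tok in enumerate(tokens[:-1]):
            if not re.fullmatch(r"\d+(?:\.\d+)?", tok):
                continue
            unit = tokens[i + 1]
            if unit not in ("cm", "mm"):
                continue
            if min(abs(i - m) for m in mention_idx) <= window:
                value = float(tok)
                return value / 10.0 if unit == "mm" else value
    return None


def extract_label(
    text: str, lexicon: Lexicon | None = None, report_id: str = ""
) -> ReportLabel:
    """Label one report: presence, size class, and the rule that fired.

    Size priority: a parsed measurement against the 3 cm rule beats a size
    adjective (measurements are the guideline-grounded signal); a positive
    with neither is ``unspecified``.
    """
    if not text or not text.strip():
        raise ValueError("empty report text")
    lex = lexicon or _default_lexicon()
    sentences = _sentences(text)
    positive_sents: list[list[str]] = []
    pos_mentions: list[tuple[list[str], int]] = []
    negated_cue: tuple[str, ...] | None = None
    for tokens in sentences:
        for i, negated, cue in _scan_sentence(tokens, lex):
            if negated:
                negated_cue = negated_cue or cue
            else:
                positive_sents.append(tokens)
                pos_mentions.append((tokens, i))
    if not pos_mentions:
        rule = (
            f"negation:{' '.join(negated_cue)}" if negated_cue else "no-mention"
        )
        return ReportLabel(report_id, False, "none", rule)

    # priority 1: a measurement in a sentence with a non-negated mention
    cm = parse_size_measurement(
        ". ".join(" ".join(t) for t in positive_sents), lex
    )
    if cm is not None:
        size = "large" if cm >= SIZE_THRESHOLD_CM else "small"
        return ReportLabel(report_id, True, size, f"measurement:{cm}cm", cm)

    # priority 2: size adjective within 6 tokens of a non-negated mention
    for tokens, m in pos_mentions:
        lo, hi = max(0, m - 6), m + 7
        for j in range(lo, min(hi, len(tokens))):
            for cat, terms in (("large", lex.size_large), ("small", lex.size_small)):
                term = _match_at(tokens, j, terms)
                if term is not None:
                    return ReportLabel(
                        report_id, True, cat, f"adjective:{' '.join(term)}"
                    )
    return ReportLabel(report_id, True, "unspecified", "mention-only")


def label_corpus(
    reports: Iterable[dict] | str | Path,
    lexicon: Lexicon | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label a JSONL corpus (path or iterable of {"id", "text"} records).

    Returns the per-report label table and a count summary. Duplicate ids
    are an error; malformed records are skipped with a warning and
    counted. Conservation: large + small + unspecified == present.
    """
    if isinstance(reports, (str, Path)):
        def _iter():
            with open(reports) as fh:
                for line in fh:
                    if line.strip():
                        try:
                            yield json.loads(line)
                        except json.JSONDecodeError:
                            yield {"__bad__": line}
        records = _iter()
    else:
        records = iter(reports)

    lex = lexicon or _default_lexicon()
    rows = []
    seen: set[str] = set()
    skipped = 0
    for rec in records:
        if not isinstance(rec, dict) or "id" not in rec or "text" not in rec:
            warnings.warn("skipping unreadable report record")
            skipped += 1
            continue
        rid = str(rec["id"])
        if rid in seen:
            raise ValueError(f"duplicate report id {rid!r}")
        seen.add(rid)
        try:
            label = extract_label(rec["text"], lex, report_id=rid)
        except ValueError:
            warnings.warn(f"skipping unreadable report {rid!r}")
            skipped += 1
            continue
        rows.append(
            {
                "id": rid, "present": label.present,
                "size_class": label.size_class,
                "matched_rule": label.matched_rule,
                "measurement_cm": label.measurement_cm,
            }
        )
    table = pd.DataFrame(
        rows, columns=["id", "present", "size_class", "matched_rule", "measurement_cm"]
    )
    n_present = int(table["present"].sum()) if len(table) else 0
    summary = {
        "total": len(table),
        "present": n_present,
        "absent": len(table) - n_present,
        "large": int((table["size_class"] == "large").sum()) if len(table) else 0,
        "small": int((table["size_class"] == "small").sum()) if len(table) else 0,
        "unspecified": int((table["size_class"] == "unspecified").sum()) if len(table) else 0,
        "skipped": skipped,
    }
    return table, summary
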