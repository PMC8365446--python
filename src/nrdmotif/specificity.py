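"""Phosphate-specificity classification of apical-loop motifs.

A small, data-driven lexicon maps apical-loop motifs to predicted
substrate phosphorylation level: NDP (ribonucleoside diphosphate
reducer), NTP (triphosphate reducer) or UNKNOWN.  The default lexicon is
shipped with the package (``data/lexicon.yaml``) and can be replaced by
any YAML file of the same shape, since new motif variants are expected
to accrue as more enzymes are characterised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import yaml
from sklearn.base import BaseEstimator

from .anchor import MotifCall

__all__ = [
    "LexiconPattern",
    "SpecificityLabel",
    "MotifCensus",
    "load_lexicon",
    "default_lexicon",
    "classify_motif",
    "census",
    "SpecificityClassifier",
]

LABELS = ("NDP", "NTP", "UNKNOWN")


@dataclass(frozen=True)
class LexiconPattern:
    pattern_id: str
    regex: str
    label: str

    def __post_init__(self):
        if self.label not in ("NDP", "NTP"):
            raise ValueError(f"pattern label must be NDP or NTP, got {self.label!r}")
        re.compile(self.regex)  # fail fast on bad patterns


@dataclass(frozen=True)
class SpecificityLabel:
    """Classification outcome for one motif."""

    label: str
    matched_pattern: str | None
    motif: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"bad label {self.label!r}")
        if (self.label == "UNKNOWN") != (self.matched_pattern is None):
            raise ValueError("UNKNOWN iff no pattern matched")


@dataclass(frozen=True)
class MotifCensus:
    """Counts and fractions of motif patterns over a sequence set."""

    total: int
    per_pattern_counts: dict
    per_label_counts: dict
    per_label_fractions: dict

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "per_pattern_counts": dict(self.per_pattern_counts),
            "per_label_counts": dict(self.per_label_counts),
            "per_label_fractions": dict(self.per_label_fractions),
        }


def load_lexicon(path) -> list[LexiconPattern]:
    """Load a motif lexicon from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_lexicon(doc)


def _parse_lexicon(doc: dict) -> list[LexiconPattern]:
    pats = [LexiconPattern(p["id"], p["regex"], p["label"])
            for p in doc["patterns"]]
    if not pats:
        raise ValueError("empty lexicon")
    return pats


def default_lexicon() -> list[LexiconPattern]:
    """The packaged NrdJ apical-loop lexicon."""
    text = resources.files("nrdmotif").joinpath("data/lexicon.yaml").read_text()
    return _parse_lexicon(yaml.safe_load(text))


_DEFAULT = None


def _lexicon_or_default(lexicon):
    global _DEFAULT
    if lexicon is not None:
        return lexicon
    if _DEFAULT is None:
        _DEFAULT = default_lexicon()
    return _DEFAULT


def classify_motif(motif: str, lexicon: Sequence[LexiconPattern] | None = None
                   ) -> SpecificityLabel:
    """Classify an apical-loop motif as NDP, NTP or UNKNOWN.

    Matching is case-insensitive, anchored to the full motif, first
    pattern wins.  An empty or unrecognised motif is UNKNOWN.
    """
    lexicon = _lexicon_or_default(lexicon)
    m = str(motif).upper()
    for pat in lexicon:
        if re.fullmatch(pat.regex, m, flags=re.IGNORECASE):
            return SpecificityLabel(label=pat.label,
                                    matched_pattern=pat.pattern_id, motif=m)
    return SpecificityLabel(label="UNKNOWN", matched_pattern=None, motif=m)


def _as_motif_and_flag(item):
    if isinstance(item, MotifCall):
        return item.motif, item.coverage_flag
    if isinstance(item, SpecificityLabel):
        return item.motif, "FULL"
    return str(item), "FULL"


def census(calls: Iterable, lexicon: Sequence[LexiconPattern] | None = None
           ) -> MotifCensus:
    """Tabulate motif patterns and specificity labels over a set of calls.

    ``calls`` may hold :class:`MotifCall` objects or bare motif strings.
    PARTIAL and UNMAPPED calls are counted as UNKNOWN regardless of their
    residual motif content, since their extraction is not trusted.
    """
    lexicon = _lexicon_or_default(lexicon)
    per_pattern: dict[str, int] = {}
    per_label = {lab: 0 for lab in LABELS}
    total = 0
    for item in calls:
        motif, flag = _as_motif_and_flag(item)
        total += 1
        if flag != "FULL":
            per_label["UNKNOWN"] += 1
            continue
        lab = classify_motif(motif, lexicon)
        per_label[lab.label] += 1
        if lab.matched_pattern is not None:
            per_pattern[lab.matched_pattern] = \
                per_pattern.get(lab.matched_pattern, 0) + 1
    fractions = {lab: (per_label[lab] / total if total else 0.0)
                 for lab in LABELS}
    return MotifCensus(total=total, per_pattern_counts=per_pattern,
                       per_label_counts=per_label,
                       per_label_fractions=fractions)


class SpecificityClassifier(BaseEstimator):
    """Rule-based classifier mapping motifs to {NDP, NTP, UNKNOWN}.

    The lexicon is fixed at construction (``fit`` only validates it), so
    the classifier is a pure function of its input: same motif, same
    label.
    """

    def __init__(self, lexicon: Sequence[LexiconPattern] | None = None):
        self.lexicon = lexicon

    def fit(self, X=None, y=None):
        self.lexicon_ = _lexicon_or_default(self.lexicon)
        return self

    def predict(self, X: Iterable) -> list[SpecificityLabel]:
        """Classify motif strings or :class:`MotifCall` objects.

        Non-FULL calls classify as UNKNOWN.
        """
        lexicon = getattr(self, "lexicon_", None) or _lexicon_or_default(self.lexicon)
        out = []
        for item in X:
            motif, flag = _as_motif_and_flag(item)
            if flag != "FULL":
                out.append(SpecificityLabel("UNKNOWN", None, motif))
            else:
                out.append(classify_motif(motif, lexicon))
        return out
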