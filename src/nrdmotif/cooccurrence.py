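"""Per-genome co-occurrence of NrdJ phosphate specificities.

Many prokaryotic genomes encode two or more class II ribonucleotide
reductases.  Given the predicted specificity of each copy, a genome is
categorised by whether its copies agree (NTP_ONLY / NDP_ONLY) or differ
(MIXED); the headline statistic is the percentage of multi-copy genomes
that are MIXED.  Copies whose motif could not be classified (UNKNOWN)
are dropped before the multi-copy threshold is applied, so a genome with
one classified and one unclassifiable copy counts as single-copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .specificity import SpecificityLabel

__all__ = [
    "GenomeRecord",
    "CooccurrenceSummary",
    "categorize_genome",
    "summarize_cooccurrence",
]

CATEGORIES = ("SINGLE", "MIXED", "NTP_ONLY", "NDP_ONLY", "UNDETERMINED")


@dataclass(frozen=True)
class GenomeRecord:
    """A genome identifier with the specificity labels of its NrdJ copies.

    Identical duplicate sequences count as separate copies: the unit is
    the gene occurrence, not the distinct sequence.
    """

    genome_id: str
    labels: tuple

    def __post_init__(self):
        labs = tuple(l.label if isinstance(l, SpecificityLabel) else str(l)
                     for l in self.labels)
        if not labs:
            raise ValueError(f"genome {self.genome_id}: empty label list")
        bad = [l for l in labs if l not in ("NDP", "NTP", "UNKNOWN")]
        if bad:
            raise ValueError(f"genome {self.genome_id}: bad labels {bad}")
        object.__setattr__(self, "labels", labs)


def categorize_genome(g: GenomeRecord) -> str:
    """Categorise one genome by the specificities of its NrdJ copies.

    UNKNOWN labels are dropped first; fewer than two remaining classified
    copies gives SINGLE (UNDETERMINED if none remain); both NDP and NTP
    present gives MIXED; otherwise NTP_ONLY or NDP_ONLY.
    """
    known = [l for l in g.labels if l != "UNKNOWN"]
    if not known:
        return "UNDETERMINED"
    if len(known) < 2:
        return "SINGLE"
    kinds = set(known)
    if kinds == {"NDP", "NTP"}:
        return "MIXED"
    return "NTP_ONLY" if kinds == {"NTP"} else "NDP_ONLY"


@dataclass(frozen=True)
class CooccurrenceSummary:
    n_genomes_total: int
    n_multi: int
    n_mixed: int
    n_ntp_only: int
    n_ndp_only: int
    n_single: int
    n_undetermined: int
    #: percentage of multi-copy genomes that are MIXED (None if no multi)
    pct_mixed: float | None

    @property
    def pct_mixed_rounded(self) -> int | None:
        return None if self.pct_mixed is None else round(self.pct_mixed)

    def as_dict(self) -> dict:
        return {
            "n_genomes_total": self.n_genomes_total,
            "n_multi": self.n_multi,
            "n_mixed": self.n_mixed,
            "n_ntp_only": self.n_ntp_only,
            "n_ndp_only": self.n_ndp_only,
            "n_single": self.n_single,
            "n_undetermined": self.n_undetermined,
            "pct_mixed": self.pct_mixed,
            "pct_mixed_rounded": self.pct_mixed_rounded,
        }


def summarize_cooccurrence(genomes: Iterable[GenomeRecord]
                           ) -> CooccurrenceSummary:
    """Aggregate genome categories into the co-occurrence summary.

    The category counts MIXED + NTP_ONLY + NDP_ONLY partition the
    multi-copy genomes; the summary is invariant to genome order.
    """
    counts = {c: 0 for c in CATEGORIES}
    total = 0
    for g in genomes:
        counts[categorize_genome(g)] += 1
        total += 1
    n_multi = counts["MIXED"] + counts["NTP_ONLY"] + counts["NDP_ONLY"]
    pct = 100.0 * counts["MIXED"] / n_multi if n_multi else None
    return CooccurrenceSummary(
        n_genomes_total=total,
        n_multi=n_multi,
        n_mixed=counts["MIXED"],
        n_ntp_only=counts["NTP_ONLY"],
        n_ndp_only=counts["NDP_ONLY"],
        n_single=counts["SINGLE"],
        n_undetermined=counts["UNDETERMINED"],
        pct_mixed=pct,
    )
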