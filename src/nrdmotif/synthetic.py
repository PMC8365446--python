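"""Synthetic inputs for the whole pipeline.

Four generators, all deterministic under a fixed seed:

* protein families carrying planted apical-loop motifs on a fixed
  NrdJ-like backbone, with background substitution and indel noise;
* per-genome NrdJ sets with chosen copy numbers and specificity
  categories (deterministic-count or sampled assignment);
* phylogenies whose tips carry binary specificity states evolved under
  single- or multiple-origin scenarios;
* noisy saturation-kinetics datasets from a Michaelis–Menten or
  substrate-inhibition forward model.

The backbone is a fixed 150-residue synthetic sequence with the apical
loop at residues 66–69 (P-A-G-R in the reference state, the numbering of
the triphosphate-specific model enzyme) and a distal-loop annotation at
50–53.  Mutational noise never touches the loop spans ±2 residues, so
the planted ground truth stays well-defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchor import AMINO_ACIDS, ReferenceAnchor
from .kinetics import mm_rate, si_rate

__all__ = [
    "BACKBONE",
    "APICAL_SPAN",
    "DISTAL_SPAN",
    "reference_anchor",
    "FamilySpec",
    "GenomeSpec",
    "TreeScenario",
    "AssaySpec",
    "generate_family",
    "generate_genomes",
    "generate_tree_states",
    "simulate_assay",
]

#: fixed 150-residue synthetic NrdJ-like backbone; apical loop at 66–69
#: (PAGR) inside a conserved proline-context scaffold, distal loop 50–53
BACKBONE = (
    "EQMITAIVLDYLVVLSTALHQLLGVTDHFVGGAESTATAISFLPVFDRV"
    "TSLDTRQSMNWEKVTGPAGRWNEDLVQMRRLFTKNIMTDIGVCDVTAYP"
    "QIRVGIRDFYNQTRMAKRSTNIQDPGFVPGDPSFETYRLEKHLGTLQNVMGR"
)

APICAL_SPAN = (66, 69)
DISTAL_SPAN = (50, 53)

#: mutation exclusion window around each loop span, in residues
PROTECT_MARGIN = 2


def reference_anchor() -> ReferenceAnchor:
    """The synthetic backbone as an annotated reference (loop = PAGR)."""
    return ReferenceAnchor(reference_id="synthetic_ref", sequence=BACKBONE,
                           apical_span=APICAL_SPAN, distal_span=DISTAL_SPAN)


def _check_fractions(fractions: Mapping[str, float], name: str):
    if not fractions:
        raise ValueError(f"{name}: empty")
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name}: fractions sum to {total}, expected 1")
    for k, f in fractions.items():
        if f < 0:
            raise ValueError(f"{name}: negative fraction for {k!r}")


def _deterministic_counts(fractions: Mapping, n: int) -> dict:
    """Largest-remainder allocation of n items to the given fractions."""
    keys = list(fractions)
    raw = [n * float(fractions[k]) for k in keys]
    counts = [int(math.floor(x)) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(keys)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts))


@dataclass(frozen=True)
class FamilySpec:
    """Specification of a motif-planted protein family.

    ``motif_fractions`` maps motif strings (length 4 or 5) to the
    fraction of family members carrying each; counts are allocated
    deterministically (largest remainder), so zero-noise families hit
    the fractions exactly.
    """

    n_sequences: int
    motif_fractions: Mapping[str, float]
    background_length: int = len(BACKBONE)
    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        _check_fractions(self.motif_fractions, "motif_fractions")
        for m in self.motif_fractions:
            if len(m) not in (4, 5):
                raise ValueError(f"motif {m!r} must have length 4 or 5")
        for nm in ("substitution_rate", "indel_rate"):
            r = getattr(self, nm)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{nm} must be in [0, 1], got {r}")
        if self.background_length < len(BACKBONE):
            raise ValueError(
                f"background_length must be >= {len(BACKBONE)} "
                "(the backbone length)")


def _protected_positions(loop_start: int, loop_end: int) -> set[int]:
    """0-based positions where mutations are forbidden (loops ±margin)."""
    prot = set()
    for lo, hi in ((loop_start, loop_end),
                   (DISTAL_SPAN[0] - 1, DISTAL_SPAN[1] - 1)):
        prot.update(range(lo - PROTECT_MARGIN, hi + PROTECT_MARGIN + 1))
    return prot


def _mutate_sequence(seq: list[str], protected: set[int],
                     sub_rate: float, indel_rate: float,
                     rng: np.random.Generator,
                     tracked: int) -> tuple[str, int]:
    """Apply substitutions then single-residue indels outside ``protected``.

    Returns the mutated sequence and the new 0-based index of the
    residue originally at ``tracked``.
    """
    aa = AMINO_ACIDS
    n = len(seq)
    if sub_rate > 0:
        hits = np.nonzero(rng.random(n) < sub_rate)[0]
        for i in hits:
            if int(i) in protected:
                continue
            old = seq[i]
            choices = aa.replace(old, "")
            seq[i] = choices[rng.integers(len(choices))]
    if indel_rate > 0:
        out: list[str] = []
        new_tracked = tracked
        shift = 0
        events = rng.random(n)
        kinds = rng.random(n)
        ins_res = rng.integers(0, len(aa), size=n)
        for i in range(n):
            if events[i] < indel_rate and i not in protected:
                if kinds[i] < 0.5:
                    # deletion of residue i
                    if i < tracked:
                        shift -= 1
                    continue
                out.append(aa[ins_res[i]])  # insertion before residue i
                if i <= tracked:
                    shift += 1
            out.append(seq[i])
        seq = out
        new_tracked = tracked + shift
        return "".join(seq), new_tracked
    return "".join(seq), tracked


def _embed_motif(motif: str) -> tuple[list[str], int, int]:
    """Backbone with the apical loop replaced by ``motif``.

    Returns (sequence chars, 0-based loop start, 0-based loop end).
    """
    lo, hi = APICAL_SPAN
    chars = list(BACKBONE[:lo - 1]) + list(motif) + list(BACKBONE[hi:])
    return chars, lo - 1, lo - 2 + len(motif)


def generate_family(spec: FamilySpec
                    ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate a motif-planted family and its ground-truth table.

    Returns ``(sequences, truth)`` where ``sequences`` is a list of
    ``(id, protein)`` pairs and ``truth`` has columns ``seq_id, motif,
    start, end`` (1-based planted loop coordinates after indels).
    Mutations never alter the planted motif or its ±2 flanks.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _deterministic_counts(spec.motif_fractions, spec.n_sequences)
    motifs = [m for m, c in counts.items() for _ in range(c)]
    rng.shuffle(motifs)

    seqs, rows = [], []
    for k, motif in enumerate(motifs):
        motif = motif.upper()
        chars, m0, m1 = _embed_motif(motif)
        protected = _protected_positions(m0, m1)
        mutated, new_start = _mutate_sequence(
            chars, protected, spec.substitution_rate, spec.indel_rate,
            rng, tracked=m0)
        sid = f"fam{spec.seed}_{k:05d}"
        seqs.append((sid, mutated))
        rows.append({"seq_id": sid, "motif": motif,
                     "start": new_start + 1,
                     "end": new_start + len(motif)})
    truth = pd.DataFrame(rows)
    return seqs, truth


CATEGORY_KEYS = ("MIXED", "NTP_ONLY", "NDP_ONLY")

#: motifs used when planting category-consistent genomes
NDP_MOTIF = "PNSP"
NTP_MOTIF = "PAGR"


@dataclass(frozen=True)
class GenomeSpec:
    """Specification of a synthetic multi-genome NrdJ collection.

    ``copy_number_distribution`` maps copy number k (>= 1) to its
    probability; ``specificity_mix`` maps the multi-copy categories to
    probabilities.  With ``assignment="deterministic"`` both are turned
    into exact largest-remainder counts, reproducing printed count
    tables exactly; ``"sample"`` draws them at random.
    """

    n_genomes: int
    copy_number_distribution: Mapping[int, float]
    specificity_mix: Mapping[str, float]
    assignment: str = "deterministic"
    substitution_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not self.copy_number_distribution:
            raise ValueError("copy_number_distribution is empty")
        for k in self.copy_number_distribution:
            if int(k) < 1:
                raise ValueError(f"copy number {k} must be >= 1")
        _check_fractions(self.copy_number_distribution,
                         "copy_number_distribution")
        bad = set(self.specificity_mix) - set(CATEGORY_KEYS)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")
        _check_fractions(self.specificity_mix, "specificity_mix")
        if self.assignment not in ("deterministic", "sample"):
            raise ValueError("assignment must be 'deterministic' or 'sample'")


def _category_motifs(category: str, n_copies: int,
                     rng: np.random.Generator) -> list[str]:
    if category == "NTP_ONLY":
        return [NTP_MOTIF] * n_copies
    if category == "NDP_ONLY":
        return [NDP_MOTIF] * n_copies
    # MIXED: at least one of each, remainder random
    extra = [NDP_MOTIF if rng.random() < 0.5 else NTP_MOTIF
             for _ in range(n_copies - 2)]
    motifs = [NDP_MOTIF, NTP_MOTIF] + extra
    rng.shuffle(motifs)
    return motifs


def generate_genomes(spec: GenomeSpec
                     ) -> tuple[list[tuple[str, list[tuple[str, str]]]],
                                pd.DataFrame]:
    """Generate per-genome NrdJ protein sets with known categories.

    Returns ``(genomes, truth)``: ``genomes`` is a list of
    ``(genome_id, [(seq_id, protein), ...])``; ``truth`` has columns
    ``genome_id, n_copies, category`` where single-copy genomes carry
    category ``SINGLE`` and multi-copy genomes one of MIXED / NTP_ONLY /
    NDP_ONLY.  Under deterministic assignment the multi-copy category
    counts equal the largest-remainder allocation of ``specificity_mix``
    exactly, independent of the seed.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.assignment == "deterministic":
        copy_counts = _deterministic_counts(
            {int(k): v for k, v in spec.copy_number_distribution.items()},
            spec.n_genomes)
        copies = [k for k, c in sorted(copy_counts.items())
                  for _ in range(c)]
    else:
        ks = np.array([int(k) for k in spec.copy_number_distribution])
        ps = np.array([float(v)
                       for v in spec.copy_number_distribution.values()])
        copies = list(rng.choice(ks, size=spec.n_genomes, p=ps / ps.sum()))

    n_multi = sum(1 for c in copies if c >= 2)
    if spec.assignment == "deterministic":
        cat_counts = _deterministic_counts(spec.specificity_mix, n_multi)
        multi_cats = [c for c, n in cat_counts.items() for _ in range(n)]
        rng.shuffle(multi_cats)  # exact counts, seed-dependent arrangement
    else:
        cats = list(spec.specificity_mix)
        ps = np.array([float(spec.specificity_mix[c]) for c in cats])
        multi_cats = list(rng.choice(cats, size=n_multi, p=ps / ps.sum()))

    genomes, rows = [], []
    mi = 0
    for g, n_copies in enumerate(copies):
        gid = f"genome{spec.seed}_{g:05d}"
        if n_copies >= 2:
            category = multi_cats[mi]
            mi += 1
            motifs = _category_motifs(category, int(n_copies), rng)
        else:
            category = "SINGLE"
            motifs = [NDP_MOTIF if rng.random() < 0.5 else NTP_MOTIF]
        members = []
        for c, motif in enumerate(motifs):
            chars, m0, m1 = _embed_motif(motif)
            protected = _protected_positions(m0, m1)
            seq, _ = _mutate_sequence(chars, protected,
                                      spec.substitution_rate, 0.0, rng, m0)
            members.append((f"{gid}_nrdJ{c + 1}", seq))
        genomes.append((gid, members))
        rows.append({"genome_id": gid, "n_copies": int(n_copies),
                     "category": category})
    return genomes, pd.DataFrame(rows)


@dataclass(frozen=True)
class TreeScenario:
    """A tip-state evolution scenario on a random binary tree.

    ``scenario`` is ``"SINGLE_ORIGIN"``, ``"K_ORIGINS"`` (with
    ``k_origins`` set) or ``"RANDOM"``.  ``clade_fraction`` is the
    fraction of tips carrying the derived state (NDP); under K_ORIGINS
    those tips are split into k clades kept disjoint by ancestral-state
    tips on a backbone, so the true minimum number of origins is k.
    """

    n_tips: int
    scenario: str = "SINGLE_ORIGIN"
    k_origins: int = 1
    clade_fraction: float = 0.4
    seed: int = 0

    derived_state: str = "NDP"
    ancestral_state: str = "NTP"

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if not (0.0 < self.clade_fraction < 1.0):
            raise ValueError("clade_fraction must be in (0, 1)")
        if self.scenario not in ("SINGLE_ORIGIN", "K_ORIGINS", "RANDOM"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "K_ORIGINS" and self.k_origins < 1:
            raise ValueError("k_origins must be >= 1")


def _random_subtree(labels: Sequence[str], rng: np.random.Generator) -> str:
    """Random binary subtree over the given tips, as a Newick fragment."""
    labels = list(labels)
    if len(labels) == 1:
        return f"{labels[0]}:{rng.exponential(0.1):.6f}"
    rng.shuffle(labels)
    cut = int(rng.integers(1, len(labels)))
    left = _random_subtree(labels[:cut], rng)
    right = _random_subtree(labels[cut:], rng)
    return f"({left},{right}):{rng.exponential(0.1):.6f}"


def generate_tree_states(scenario: TreeScenario) -> tuple[str, dict]:
    """Generate a Newick tree and tip-state map under the scenario.

    Returns ``(newick, tip_states)``.  SINGLE_ORIGIN trees place all
    derived-state tips in exactly one clade; K_ORIGINS trees place them
    in k disjoint clades separated by ancestral tips along a backbone;
    RANDOM assigns states independently per tip.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_tips
    n_derived = int(round(scenario.clade_fraction * n))
    n_derived = min(max(n_derived, 1), n - 1)
    derived = [f"t{i:03d}" for i in range(n_derived)]
    ancestral = [f"t{i:03d}" for i in range(n_derived, n)]
    D, A = scenario.derived_state, scenario.ancestral_state

    if scenario.scenario == "RANDOM":
        labels = [f"t{i:03d}" for i in range(n)]
        nwk = f"({_random_subtree(labels, rng)});"
        states = {lab: (D if rng.random() < scenario.clade_fraction else A)
                  for lab in labels}
        return nwk, states

    if scenario.scenario == "SINGLE_ORIGIN":
        left = _random_subtree(derived, rng)
        right = _random_subtree(ancestral, rng)
        nwk = f"({left},{right});"
        states = {t: D for t in derived}
        states.update({t: A for t in ancestral})
        return nwk, states

    # K_ORIGINS: k derived clades interleaved with ancestral groups on a
    # caterpillar backbone: (A0,(D1,(A1,(D2,(A2,...)))))
    k = scenario.k_origins
    if k > n_derived:
        raise ValueError(f"k_origins={k} exceeds {n_derived} derived tips "
                         f"(clade_fraction {scenario.clade_fraction} of "
                         f"{n} tips)")
    if len(ancestral) < k + 1:
        raise ValueError(
            f"need >= {k + 1} ancestral tips to separate {k} derived "
            f"clades, have {len(ancestral)}; lower clade_fraction")
    d_groups = [list(x) for x in np.array_split(np.array(derived), k)]
    a_groups = [list(x) for x in np.array_split(np.array(ancestral), k + 1)]
    node = _random_subtree(a_groups[-1], rng)
    for i in range(k - 1, -1, -1):
        dsub = _random_subtree(d_groups[i], rng)
        node = f"({dsub},{node}):{rng.exponential(0.1):.6f}"
        asub = _random_subtree(a_groups[i], rng)
        node = f"({asub},{node}):{rng.exponential(0.1):.6f}"
    nwk = f"({node});"
    states = {t: D for t in derived}
    states.update({t: A for t in ancestral})
    return nwk, states


@dataclass(frozen=True)
class AssaySpec:
    """Forward model for a saturation-kinetics assay.

    ``true_ki=None`` gives plain Michaelis–Menten behaviour; a finite
    ``true_ki`` activates substrate-surplus inhibition.  Noise is
    multiplicative Gaussian, ``v·(1+ε)`` with ε ~ N(0, cv²), truncated
    at 0.
    """

    true_kcat: float = 47.6          # min⁻¹
    true_km: float = 0.30            # mmol L⁻¹
    true_ki: float | None = None     # mmol L⁻¹
    enzyme_conc: float = 2.0         # µmol L⁻¹
    substrate_grid: tuple = (0.05, 0.1, 0.2, 0.3, 0.5, 0.75,
                             1.0, 1.5, 2.0, 3.0)
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for nm in ("true_kcat", "true_km", "enzyme_conc"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if self.true_ki is not None and self.true_ki <= 0:
            raise ValueError("true_ki must be > 0 or None")
        if not self.substrate_grid or any(s <= 0 for s in self.substrate_grid):
            raise ValueError("substrate_grid must be non-empty and > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def simulate_assay(spec: AssaySpec) -> pd.DataFrame:
    """Simulate (substrate, rate) data under the assay forward model.

    Returns a DataFrame with columns ``substrate_mM, rate_per_min,
    replicate``.  With ``noise_cv=0`` the rates follow the model
    exactly.
    """
    rng = np.random.default_rng(spec.seed)
    S = np.asarray(spec.substrate_grid, dtype=float)
    if spec.true_ki is None:
        v_true = mm_rate(S, spec.true_kcat, spec.true_km)
    else:
        v_true = si_rate(S, spec.true_kcat, spec.true_km, spec.true_ki)
    rows = []
    for rep in range(1, spec.replicates + 1):
        if spec.noise_cv > 0:
            eps = rng.normal(0.0, spec.noise_cv, size=S.size)
            v = np.maximum(v_true * (1.0 + eps), 0.0)
        else:
            v = v_true
        for s, vi in zip(S, v):
            rows.append({"substrate_mM": float(s),
                         "rate_per_min": float(vi),
                         "replicate": rep})
    return pd.DataFrame(rows)
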