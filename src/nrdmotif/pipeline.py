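"""End-to-end pipeline orchestration.

Runs sequences → motifs → specificity labels → census, plus the optional
logo, phylogeny, co-occurrence and kinetics stages, from a single
YAML/JSON config.  Every stage writes its outputs under the run's
output directory and the run closes with a manifest (inputs, seed,
package version, SHA-256 checksums of all outputs) sufficient to verify
a bit-identical re-run.  Stages whose inputs are absent from the config
are skipped and noted in the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anchor import (MotifCall, PairwiseMotifExtractor, ReferenceAnchor,
                     extract_motif_msa, motif_calls_to_frame, read_fasta)
from .cooccurrence import GenomeRecord, summarize_cooccurrence
from .kinetics import RateDataset, apparent_fit, fit_model
from .phylo import StateTree, parse_newick, state_report
from .seqlogo import build_logo
from .specificity import SpecificityClassifier, census, load_lexicon

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Any stage whose input paths are ``None`` is skipped.  The reference
    is given either as ``reference_fasta`` + ``apical_span`` /
    ``distal_span``, or queries can be anchored through an MSA with
    ``msa_fasta`` + ``apical_columns``.
    """

    out_dir: str
    seed: int = 0
    # anchoring stage
    query_fasta: str | None = None
    reference_fasta: str | None = None
    apical_span: tuple[int, int] | None = None
    distal_span: tuple[int, int] | None = None
    msa_fasta: str | None = None
    apical_columns: list[int] | None = None
    # classification
    lexicon: str | None = None
    # phylogeny stage
    tree_newick: str | None = None
    tip_states_csv: str | None = None
    # co-occurrence stage
    genome_map_csv: str | None = None
    # kinetics stage
    kinetics_csv: str | None = None
    kinetics_model: str = "mm"
    apparent_s_max: float | None = None
    rounding: int = 4

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        if "apical_span" in doc and doc["apical_span"] is not None:
            doc["apical_span"] = tuple(doc["apical_span"])
        if "distal_span" in doc and doc["distal_span"] is not None:
            doc["distal_span"] = tuple(doc["distal_span"])
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; return the manifest dict.

    A stage failure aborts the run with an error naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "stages": {}, "checksums": {}}
    outputs: list[Path] = []
    lexicon = load_lexicon(cfg.lexicon) if cfg.lexicon else None

    calls: list[MotifCall] | None = None
    try:
        if cfg.query_fasta and cfg.reference_fasta:
            refs = read_fasta(cfg.reference_fasta)
            rid, rseq = refs[0]
            ref = ReferenceAnchor(reference_id=rid, sequence=rseq,
                                  apical_span=tuple(cfg.apical_span),
                                  distal_span=tuple(cfg.distal_span))
            extractor = PairwiseMotifExtractor(reference=ref).fit()
            calls = extractor.transform(read_fasta(cfg.query_fasta))
            manifest["stages"]["anchor"] = "pairwise"
        elif cfg.msa_fasta and cfg.apical_columns:
            calls = extract_motif_msa(read_fasta(cfg.msa_fasta),
                                      cfg.apical_columns)
            manifest["stages"]["anchor"] = "msa"
        else:
            manifest["stages"]["anchor"] = "skipped"
    except Exception as exc:
        raise RuntimeError(f"anchor stage failed: {exc}") from exc

    labels = None
    if calls is not None:
        try:
            p = out / "motifs.csv"
            motif_calls_to_frame(calls).to_csv(p, index=False)
            outputs.append(p)
            clf = SpecificityClassifier(lexicon=lexicon).fit()
            labels = clf.predict(calls)
            lab_df = pd.DataFrame({
                "query_id": [c.query_id for c in calls],
                "motif": [l.motif for l in labels],
                "label": [l.label for l in labels],
                "pattern": [l.matched_pattern for l in labels],
            })
            p = out / "labels.csv"
            lab_df.to_csv(p, index=False)
            outputs.append(p)
            cen = census(calls, lexicon)
            p = out / "census.json"
            _write_json(p, cen.as_dict())
            outputs.append(p)
            manifest["stages"]["classify"] = "done"
        except Exception as exc:
            raise RuntimeError(f"classify stage failed: {exc}") from exc
    else:
        manifest["stages"]["classify"] = "skipped"

    if cfg.msa_fasta and cfg.apical_columns and labels is not None:
        try:
            rows = read_fasta(cfg.msa_fasta)
            by_class: dict[str, list[str]] = {}
            for (rid, seq), lab in zip(rows, labels):
                if lab.label != "UNKNOWN":
                    by_class.setdefault(lab.label, []).append(seq)
            logos = {k: build_logo(v, cfg.apical_columns).as_dict()
                     for k, v in by_class.items() if v}
            p = out / "logos.json"
            _write_json(p, logos)
            outputs.append(p)
            manifest["stages"]["logo"] = "done"
        except Exception as exc:
            raise RuntimeError(f"logo stage failed: {exc}") from exc
    else:
        manifest["stages"]["logo"] = "skipped"

    if cfg.tree_newick and cfg.tip_states_csv:
        try:
            tree = parse_newick(Path(cfg.tree_newick).read_text())
            sdf = pd.read_csv(cfg.tip_states_csv)
            states = dict(zip(sdf["tip_id"].astype(str), sdf["state"]))
            report = state_report(StateTree(tree=tree, tip_states=states))
            p = out / "phylo.json"
            _write_json(p, report)
            outputs.append(p)
            manifest["stages"]["phylo"] = "done"
        except Exception as exc:
            raise RuntimeError(f"phylo stage failed: {exc}") from exc
    else:
        manifest["stages"]["phylo"] = "skipped"

    if cfg.genome_map_csv and labels is not None:
        try:
            gmap = pd.read_csv(cfg.genome_map_csv)
            by_id = {c.query_id: l for c, l in zip(calls, labels)}
            records = []
            for gid, grp in gmap.groupby("genome_id", sort=True):
                labs = [by_id[q].label for q in grp["seq_id"]
                        if q in by_id]
                if labs:
                    records.append(GenomeRecord(genome_id=str(gid),
                                                labels=tuple(labs)))
            summary = summarize_cooccurrence(records)
            p = out / "cooccurrence.json"
            _write_json(p, summary.as_dict())
            outputs.append(p)
            manifest["stages"]["cooccurrence"] = "done"
        except Exception as exc:
            raise RuntimeError(f"cooccurrence stage failed: {exc}") from exc
    else:
        manifest["stages"]["cooccurrence"] = "skipped"

    if cfg.kinetics_csv:
        try:
            data = RateDataset.from_frame(pd.read_csv(cfg.kinetics_csv))
            fit = fit_model(data, model=cfg.kinetics_model)
            result = {"fit": fit.as_dict()}
            if cfg.apparent_s_max is not None:
                result["apparent"] = apparent_fit(
                    data, cfg.apparent_s_max).as_dict()
            p = out / "kinetics.json"
            _write_json(p, result)
            outputs.append(p)
            manifest["stages"]["kinetics"] = "done"
        except Exception as exc:
            raise RuntimeError(f"kinetics stage failed: {exc}") from exc
    else:
        manifest["stages"]["kinetics"] = "skipped"

    for p in outputs:
        manifest["checksums"][p.name] = _sha256(p)
    _write_json(out / "manifest.json", manifest)
    return manifest
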