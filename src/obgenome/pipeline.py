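"""End-to-end genome characterization: orchestrates the analysis stages.

Given a genome (and optionally an evidence table, a pileup, per-gene
alignments, and a core-gene reference set), produces the full report
bundle: genome statistics, the accepted ORF table with GFF3, hr regions
with a rendered unit consensus, the polymorphism table with its frequency
summary, the core-gene inventory with identity summary, and the NJ tree
with bootstrap supports.  Stages whose inputs are absent are skipped
gracefully; any stage error aborts the run and removes partial outputs.

Outputs are byte-reproducible for a fixed config and seed: percents are
formatted to 2 decimals and branch lengths to 6.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import hr as hr_mod
from .genome import FeatureRecord, gc_content
from .homology import identity_summary, inventory_core_genes
from .io import read_alignment_file, read_fasta, read_fasta_proteins, write_gff3
from .orfs import (EvidenceRecord, classify_conservation, conservation_counts,
                   find_orfs, resolve_overlaps)
from .phylogeny import (DistanceModel, GeneAlignment, bootstrap_support,
                        concatenate, nj_tree, distance_matrix)
from .variants import (calls_to_frame, call_polymorphisms, classify_all,
                       read_pileup, summarize_frequencies)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str = ""
    evidence: str = ""
    pileup: str = ""
    alignments_dir: str = ""
    core_refs: str = ""
    out_dir: str = "obgenome_out"
    min_codons: int = 50
    max_overlap: int = 75
    hr_consensus: str = hr_mod.HR_CONSENSUS
    max_mismatch: int = 12
    strict: bool = True
    max_gap: int = 1000
    min_depth: int = 20
    min_alt: int = 2
    min_freq: float = 1.0
    core_floor: float = 15.0
    distance_model: str = "gamma"
    gamma_shape: float = 1.0
    bootstrap_reps: int = 500
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


def read_evidence_tsv(path: str) -> list[EvidenceRecord]:
    """Evidence TSV: orf_id, best_subject, best_identity, evalue, fgenes, zcurve."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        subject = str(row.get("best_subject", "")).strip()
        records.append(EvidenceRecord(
            orf_id=str(row["orf_id"]),
            has_homology=bool(subject),
            best_subject=subject,
            best_identity=(float(row["best_identity"])
                           if str(row.get("best_identity", "")).strip() else None),
            fgenes_pred=str(row.get("fgenes", "0")).strip() in ("1", "True", "true", "yes"),
            zcurve_pred=str(row.get("zcurve", "0")).strip() in ("1", "True", "true", "yes"),
        ))
    return records


def _orf_features(annotations, genome) -> list[FeatureRecord]:
    feats = []
    for ann in annotations:
        if not ann.accepted:
            continue
        c = ann.candidate
        lo, hi = min(c.start, c.end), max(c.start, c.end)
        if c.wraps:
            lo, hi = (c.start, c.end) if c.strand == "+" else (c.end, c.start)
        feats.append(FeatureRecord(
            c.orf_id, lo, hi, c.strand, "ORF",
            {"n_codons": c.n_codons, "class": ann.conservation_class},
            wraps=c.wraps,
        ))
    return feats


def run_characterization(cfg: PipelineConfig) -> dict:
    """Run all configured stages; return the report dict and write the bundle."""
    if not cfg.genome or not os.path.exists(cfg.genome):
        raise FileNotFoundError(f"genome FASTA not found: {cfg.genome!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _path(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    report: dict = {"config": asdict(cfg)}
    try:
        genome = read_fasta(cfg.genome)[0]
        report["genome"] = {"id": genome.id, "length": genome.length,
                            "gc_percent": gc_content(genome)}
        logger.info("genome %s: %d bp, G+C %.2f%%", genome.id, genome.length,
                    report["genome"]["gc_percent"])

        # --- ORF stage ---------------------------------------------------
        candidates = find_orfs(genome, min_codons=cfg.min_codons)
        evidence = read_evidence_tsv(cfg.evidence) if cfg.evidence else []
        annotations = resolve_overlaps(candidates, evidence, genome.length,
                                       max_overlap=cfg.max_overlap,
                                       min_codons=cfg.min_codons)
        core_hits = []
        if cfg.core_refs:
            proteins = [(a.candidate.orf_id, a.candidate.protein(genome))
                        for a in annotations if a.accepted]
            refs = read_fasta_proteins(cfg.core_refs)
            core_hits = inventory_core_genes(proteins, refs, floor=cfg.core_floor,
                                             query_taxon=genome.id)
            annotations = classify_conservation(annotations, core_hits, evidence)
        reasons = {}
        for a in annotations:
            reasons[a.rejection_reason] = reasons.get(a.rejection_reason, 0) + 1
        accepted = [a for a in annotations if a.accepted]
        report["orfs"] = {
            "candidates": len(candidates),
            "accepted": len(accepted),
            "rejected_by_reason": {k: v for k, v in sorted(reasons.items()) if k != "none"},
            "conservation_counts": conservation_counts(annotations),
        }
        logger.info("ORFs: %d candidates, %d accepted (%s)", len(candidates),
                    len(accepted), report["orfs"]["rejected_by_reason"])
        write_gff3(_orf_features(annotations, genome), genome, _path("orfs.gff3"))
        pd.DataFrame([{
            "orf_id": a.candidate.orf_id, "start": a.candidate.start,
            "end": a.candidate.end, "strand": a.candidate.strand,
            "n_codons": a.candidate.n_codons, "accepted": int(a.accepted),
            "rejection_reason": a.rejection_reason,
            "class": a.conservation_class, "product": a.product,
        } for a in annotations]).to_csv(_path("orfs.tsv"), sep="\t", index=False)

        # --- hr stage ----------------------------------------------------
        matches = hr_mod.scan_degenerate(genome, cfg.hr_consensus,
                                         max_mismatch=cfg.max_mismatch,
                                         strict_mode=cfg.strict)
        regions = hr_mod.cluster_matches(matches, genome.length, max_gap=cfg.max_gap,
                                         unit_length=len(cfg.hr_consensus))
        report["hrs"] = {
            "n_regions": len(regions),
            "copy_counts": [r.copy_count for r in regions],
            "spans": [[r.span_start, r.span_end] for r in regions],
        }
        logger.info("hr regions: %d with copies %s", len(regions),
                    report["hrs"]["copy_counts"])
        hr_feats = []
        for r in regions:
            hr_feats.append(FeatureRecord(r.region_id, r.span_start, r.span_end, "+",
                                          "hr", {"copies": r.copy_count}, wraps=r.wraps))
            for k, m in enumerate(r.repeats, start=1):
                end = m.position + len(cfg.hr_consensus) - 1
                wraps = end > genome.length
                hr_feats.append(FeatureRecord(
                    f"{r.region_id}_u{k}", m.position,
                    end - genome.length if wraps else end,
                    m.strand, "repeat_unit",
                    {"mismatches": m.mismatch_total}, wraps=wraps))
        write_gff3(hr_feats, genome, _path("hrs.gff3"))
        if len(matches) >= 2:
            cons = hr_mod.build_consensus([m.matched_seq for m in matches])
            with open(_path("hr_consensus.txt"), "w") as fh:
                fh.write(cons.consensus + "\n")
                fh.write("".join({"black": "#", "gray": "+", "none": "."}[s]
                                 for s in cons.shading) + "\n")
            report["hrs"]["unit_consensus"] = cons.consensus

        # --- polymorphism stage -------------------------------------------
        if cfg.pileup:
            columns = read_pileup(cfg.pileup)
            calls = call_polymorphisms(columns, min_depth=cfg.min_depth,
                                       min_alt=cfg.min_alt, min_freq=cfg.min_freq)
            classified = classify_all(calls, annotations, genome)
            summary = summarize_frequencies(classified, thresholds=[6.0, 8.0])
            calls_to_frame(classified).to_csv(_path("variants.tsv"), sep="\t", index=False)
            report["polymorphisms"] = {
                "calls": len(calls),
                "records": len(classified),
                "ge_8pct": summary["ge"][8.0],
                "le_6pct": summary["le"][6.0],
                "top": [[p, f"{f:.2f}"] for p, f in summary["top"][:5]],
            }
            logger.info("polymorphisms: %d calls, %d at >=8%%", len(calls),
                        summary["ge"][8.0])

        # --- core-gene inventory ------------------------------------------
        if core_hits:
            found = [h for h in core_hits if h.found]
            pd.DataFrame([{
                "core_gene": h.core_gene, "best_orf": h.best_orf,
                "identity_pct": f"{h.identity_pct:.2f}", "found": int(h.found),
            } for h in core_hits]).to_csv(_path("core_genes.tsv"), sep="\t", index=False)
            block = {"found": len(found), "of": len(core_hits)}
            if found:
                s = identity_summary(core_hits)
                block.update(identity_min=round(s.min, 2), identity_max=round(s.max, 2),
                             identity_median=round(s.median, 2))
            report["core_genes"] = block
            logger.info("core genes: %d/%d found", len(found), len(core_hits))

        # --- phylogeny stage ----------------------------------------------
        if cfg.alignments_dir:
            files = sorted(Path(cfg.alignments_dir).glob("*"))
            alns = []
            for f in files:
                if f.suffix.lower() in (".fa", ".fasta", ".aln", ".clustal", ".fas"):
                    taxa, rows = read_alignment_file(f)
                    alns.append(GeneAlignment(f.stem, taxa, rows))
            if alns:
                super_aln = concatenate(alns)
                model = DistanceModel(cfg.distance_model,
                                      cfg.gamma_shape if cfg.distance_model == "gamma"
                                      else None)
                if cfg.bootstrap_reps > 0 and len(super_aln.taxa) >= 4:
                    tree = bootstrap_support(super_aln, model,
                                             n_reps=cfg.bootstrap_reps, seed=cfg.seed)
                else:
                    tree = nj_tree(distance_matrix(super_aln, model))
                _path("tree.nwk").write_text(tree.to_newick() + "\n")
                pd.DataFrame([{"gene": g, "first": a, "last": b}
                              for g, (a, b) in super_aln.partitions.items()]
                             ).to_csv(_path("partitions.tsv"), sep="\t", index=False)
                report["phylogeny"] = {
                    "taxa": len(super_aln.taxa),
                    "genes": len(alns),
                    "alignment_length": super_aln.length,
                    "newick": tree.to_newick(),
                }
                logger.info("phylogeny: %d taxa, %d genes, %d columns",
                            len(super_aln.taxa), len(alns), super_aln.length)
    except Exception as exc:
        for p in written:
            if p.exists():
                p.unlink()
        raise RuntimeError(f"characterization failed: {exc}") from exc

    import json

    (out / "report.json").write_text(json.dumps(report, indent=1) + "\n")
    return report
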