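"""End-to-end discovery workflow: preprocessing cascade, homology calling,
hairpin evaluation and grouping, target scan, expression and enrichment,
with a consolidated stage-count report.

Stage order follows the screening scheme: clean -> collapse -> length
profile -> ncRNA filter -> size select -> known-miRNA homology -> genomic
hairpin evaluation -> group 1/2a/2b/3 classification -> targets ->
expression -> enrichment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as expr
from . import hairpin as hp
from . import homology as hom
from . import preprocess as pre
from . import targets as tgt
from .seq import iter_reads, read_fasta, write_fasta

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the discovery workflow.

    Unknown keys in a config file are rejected at load time.
    """

    reads: str = ""
    scaffolds: str = ""
    contaminants: str = ""
    known_mirnas: str = ""
    transcripts: str = ""
    annotation: str = ""
    microarray: str = ""
    ct_table: str = ""
    out_dir: str = "results"
    seed: int = 0

    adapter: str | None = None
    min_len: int = 15
    max_n: int = 0
    size_lo: int = 17
    size_hi: int = 25
    ncrna_max_mismatch: int = 0
    max_mismatch: int = 3
    max_shift: int = 2
    flank: int = 200
    max_precursor_len: int = 300
    target_cutoff: float = 4.0
    alpha: float = 0.05
    criteria: hp.CriteriaConfig = field(default_factory=hp.CriteriaConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        crit = raw.pop("criteria", {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        crit_known = set(hp.CriteriaConfig.__dataclass_fields__)
        bad = set(crit) - crit_known
        if bad:
            raise ValueError(f"unknown criteria keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.criteria = hp.CriteriaConfig(**crit)
        return cfg


def discover(
    tags: list[pre.UniqueTag],
    scaffolds: dict[str, str],
    known: list[hom.KnownMiRNA],
    criteria: hp.CriteriaConfig | None = None,
    max_mismatch: int = 3,
    max_shift: int = 2,
    flank: int = 200,
    max_len: int = 300,
    backend: hp.FoldBackend | None = None,
) -> list[hp.MiRNACall]:
    """Classify every tag into groups 1/2a/2b/3 (or discard).  Novel calls
    are numbered csn-miRn{k} in input (descending-count) order."""
    calls: list[hp.MiRNACall] = []
    novel_k = 0
    for tag in tags:
        hits = hom.match_known(tag, known, max_mismatch, max_shift)
        homology = hom.assign_family(hits)
        loci = hp.locate_tag(tag.sequence, scaffolds)
        if loci:
            best_pass, best_any = hp.best_hairpin(
                tag.sequence, scaffolds, loci, flank, max_len, backend, criteria,
            )
        else:
            best_pass, best_any = None, None
        novel_id = None
        if homology is None and best_pass is not None:
            novel_k += 1
            novel_id = f"csn-miRn{novel_k}"
        call = hp.classify(tag, homology, best_pass, best_any, bool(loci), novel_id)
        if call is None and novel_id is not None:
            novel_k -= 1
        if call is not None:
            calls.append(call)
    return calls


def compare_to_truth(calls: list[hp.MiRNACall], truth) -> dict:
    """Score discovery calls against the synthetic truth table.

    A planted locus is recovered when some call's tag locus overlaps its
    precursor interval on the right scaffold with the correct group
    (conserved -> 1, novel -> 3).  Calls whose hairpin overlaps no planted
    precursor count as background false calls."""
    recovered = 0
    per_locus = {}
    for rec in truth:
        want = "1" if rec.is_conserved else "3"
        hit = False
        for call in calls:
            if call.hairpin is None or call.group != want:
                continue
            sid, s, e, _ = call.hairpin.locus
            if sid == rec.scaffold_id and s <= rec.precursor_end and e >= rec.precursor_start:
                hit = True
                break
        per_locus[rec.locus_id] = hit
        recovered += hit
    false_background = 0
    for call in calls:
        if call.hairpin is None:
            continue
        sid, s, e, _ = call.hairpin.locus
        if not any(
            sid == rec.scaffold_id and s <= rec.precursor_end and e >= rec.precursor_start
            for rec in truth
        ):
            false_background += 1
    return {
        "n_loci": len(truth),
        "n_recovered": recovered,
        "recovery_fraction": recovered / len(truth) if truth else 0.0,
        "false_background_calls": false_background,
        "per_locus": per_locus,
    }


def run_discovery(config: PipelineConfig) -> dict:
    """Execute the full workflow per the config; returns the report bundle
    (stage counts, calls, census, targets, expression and enrichment
    tables).  Any stage error aborts with the stage name and cause."""
    stage = "load_reads"
    report: dict = {"schema_version": SCHEMA_VERSION, "config": _config_dict(config),
                    "stages": {}}
    try:
        reads = [pre.ReadRecord(rid, seq, qual) for rid, seq, qual in iter_reads(config.reads)]
        if not reads:
            raise ValueError(f"no reads in {config.reads}")
        report["stages"]["raw_reads"] = len(reads)

        stage = "clean"
        clean = pre.clean_reads(reads, adapter=config.adapter,
                                min_len=config.min_len, max_n=config.max_n)
        report["stages"]["clean_reads"] = len(clean)

        stage = "collapse"
        tags = pre.collapse(clean)
        report["stages"]["unique_tags"] = len(tags)
        report["length_distribution"] = pre.length_distribution(tags)

        stage = "ncrna_filter"
        contaminants = read_fasta(config.contaminants)
        tags, removed = pre.filter_ncrna(tags, contaminants, config.ncrna_max_mismatch)
        report["stages"]["tags_after_ncrna"] = len(tags)
        report["stages"]["ncrna_removed_tags"] = len(removed)
        report["stages"]["ncrna_removed_reads"] = sum(t.count for t in removed)

        stage = "size_select"
        tags = pre.size_select(tags, config.size_lo, config.size_hi)
        report["stages"]["tags_after_size_select"] = len(tags)

        stage = "discovery"
        scaffolds = read_fasta(config.scaffolds)
        known_ref = [
            hom.KnownMiRNA.from_header(name, seq)
            for name, seq in read_fasta(config.known_mirnas).items()
        ]
        calls = discover(
            tags, scaffolds, known_ref, config.criteria,
            config.max_mismatch, config.max_shift,
            config.flank, config.max_precursor_len,
        )
        report["calls"] = calls
        for g in ("1", "2a", "2b", "3"):
            report["stages"][f"group_{g}_calls"] = sum(c.group == g for c in calls)
        conserved_hits = [
            hom.match_known(pre.UniqueTag(c.mature_seq, c.count), known_ref,
                            config.max_mismatch, config.max_shift)[0]
            for c in calls if c.group in ("1", "2a", "2b")
        ]
        report["family_census"] = hom.family_census(conserved_hits)
        report["stages"]["conserved_families"] = len(report["family_census"])

        stage = "targets"
        report["targets"] = []
        if config.transcripts:
            transcripts = read_fasta(config.transcripts)
            for call in calls:
                if call.group not in ("1", "3"):
                    continue
                for aln in tgt.scan_transcriptome(call.mature_seq, transcripts,
                                                  config.target_cutoff):
                    report["targets"].append(aln)
        report["stages"]["target_sites"] = len(report["targets"])

        stage = "expression"
        if config.microarray:
            spots = expr.spots_from_frame(pd.read_csv(config.microarray, sep="\t"))
            report["expression_calls"] = expr.microarray_qc(spots)
            report["stages"]["microarray_expressed"] = sum(
                c.status == "expressed" for c in report["expression_calls"])

        stage = "enrichment"
        if config.annotation and report["targets"]:
            ann = enr.AnnotationMap.from_frame(pd.read_csv(config.annotation, sep="\t"))
            genes = {a.transcript_id for a in report["targets"]} & ann.universe
            report["enrichment"] = enr.enrich(genes, ann, config.alpha)
            report["stages"]["enriched_terms"] = sum(r.enriched for r in report["enrichment"])
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["criteria"] = asdict(config.criteria)
    return d


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write TSV/FASTA/GFF3 outputs and a versioned JSON stage summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    calls = report.get("calls", [])
    rows = []
    for c in calls:
        rows.append({
            "mature_seq": c.mature_seq, "count": c.count, "group": c.group,
            "family": c.family or "", "novel_id": c.novel_id or "",
            "best_known": c.best_known or "",
            "mismatches": "" if c.mismatches is None else c.mismatches,
            "mfe": "" if c.metrics is None else round(c.metrics.mfe, 2),
            "amfe": "" if c.metrics is None else round(c.metrics.amfe, 2),
            "mfei": "" if c.metrics is None or c.metrics.mfei is None
                    else round(c.metrics.mfei, 3),
            "passed": "" if c.report is None else c.report.passed,
        })
    calls_df = pd.DataFrame(rows)
    paths["calls"] = out / "mirna_calls.tsv"
    calls_df.to_csv(paths["calls"], sep="\t", index=False)

    precursors = [
        (c.novel_id or c.best_known or f"call{i}", c.hairpin.precursor_seq)
        for i, c in enumerate(calls) if c.hairpin is not None
    ]
    paths["precursors"] = out / "precursors.fa"
    write_fasta(precursors, paths["precursors"])

    gff_lines = ["##gff-version 3"]
    for i, c in enumerate(calls):
        if c.hairpin is None:
            continue
        sid, s, e, strand = c.hairpin.locus
        name = c.novel_id or c.best_known or f"call{i}"
        gff_lines.append("\t".join(map(str, [
            sid, "smirnaforge", "miRNA_primary_transcript", s, e, ".", strand,
            ".", f"ID={name}_pri;Name={name}"])))
        gff_lines.append("\t".join(map(str, [
            sid, "smirnaforge", "miRNA", s, e, ".", strand, ".",
            f"ID={name};Parent={name}_pri"])))
    paths["gff"] = out / "mirna_loci.gff3"
    paths["gff"].write_text("\n".join(gff_lines) + "\n")

    if "length_distribution" in report:
        paths["length_distribution"] = out / "length_distribution.tsv"
        report["length_distribution"].to_csv(paths["length_distribution"],
                                             sep="\t", index=False)
    if "family_census" in report:
        paths["family_census"] = out / "family_census.tsv"
        report["family_census"].to_csv(paths["family_census"], sep="\t", index=False)
    if report.get("targets"):
        tdf = pd.DataFrame([
            {"mirna": a.mirna_seq, "transcript": a.transcript_id,
             "start": a.site_start, "end": a.site_end, "score": a.score}
            for a in report["targets"]
        ])
        paths["targets"] = out / "targets.tsv"
        tdf.to_csv(paths["targets"], sep="\t", index=False)

    summary = {
        "schema_version": report["schema_version"],
        "config": report["config"],
        "stages": report["stages"],
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths
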