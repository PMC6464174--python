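"""The two end-to-end pipelines and their report writers.

miRNA discovery: deduplicate references -> exact homology hits -> precursor
windows -> coding filter -> MFE folding -> four-criteria evaluation ->
window-level deduplication -> MFEI summary.  Every filter logs its input and
output counts so the cascade is auditable.

SSR marker design: MISA-style scan -> compound grouping -> distribution
summary -> flanking primer pairs.

Internally all coordinates are 0-based half-open; every report (TSV, GFF3)
uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from . import criteria as crit
from . import homology as hom
from . import primers as prm
from . import ssr as ssrmod
from .config import PipelineConfig
from .fold import PAIR_COUNT, STACKING, fold_mfe
from .io import read_fasta

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    tool_version: str
    config: dict
    inputs: Dict[str, str]          # path -> sha256
    counts: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"tool_version": self.tool_version, "config": self.config,
             "inputs": self.inputs, "counts": self.counts},
            indent=2, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dedup_transcripts(transcripts: List[hom.Transcript]) -> List[hom.Transcript]:
    ordered = sorted(transcripts, key=lambda t: (-len(t.seq), t.id))
    kept: List[hom.Transcript] = []
    for tr in ordered:
        if any(tr.seq in k.seq for k in kept):
            continue
        kept.append(tr)
    kept.sort(key=lambda t: t.id)
    return kept


@dataclass
class MirnaResult:
    evaluations: List[crit.HairpinEvaluation]
    accepted: List[crit.HairpinEvaluation]
    removed_coding: List[hom.PrecursorCandidate]
    summary: crit.MfeiSummary
    manifest: RunManifest
    candidates_table: pd.DataFrame


@dataclass
class SsrResult:
    loci: List[ssrmod.SSRLocus]
    primer_pairs: List[prm.PrimerPair]
    summary: pd.DataFrame
    manifest: RunManifest
    loci_table: pd.DataFrame
    primer_table: pd.DataFrame


def run_mirna_pipeline(transcripts_path: str, matures_path: str,
                       config: Optional[PipelineConfig] = None,
                       out_dir: Optional[str] = None) -> MirnaResult:
    cfg = config or PipelineConfig()
    model = STACKING if cfg.energy_model == "stacking" else PAIR_COUNT
    thresholds = crit.CriteriaThresholds(
        mfei_threshold=cfg.mfei_threshold,
        max_star_mismatches=cfg.max_star_mismatches,
        max_internal_gap=cfg.max_internal_gap,
        min_arm_len=cfg.min_match,
    )
    transcripts = [hom.Transcript(i, s) for i, s in read_fasta(transcripts_path)]
    matures_raw = [hom.MatureRef(i, s) for i, s in read_fasta(matures_path)]
    counts = {"transcripts": len(transcripts), "matures_raw": len(matures_raw)}
    if cfg.dedup_transcripts:
        transcripts = _dedup_transcripts(transcripts)
        counts["transcripts_unique"] = len(transcripts)
    matures = hom.deduplicate_matures(matures_raw)
    counts["matures_unique"] = len(matures)
    log.info("references: %d -> %d after redundancy removal",
             len(matures_raw), len(matures))

    hits = hom.find_homology_hits(transcripts, matures, cfg.min_match,
                                  cfg.both_strands)
    counts["hits"] = len(hits)
    by_id = {t.id: t for t in transcripts}
    candidates = [hom.extract_precursor_window(h, by_id[h.transcript_id], cfg.flank)
                  for h in hits]
    counts["candidates"] = len(candidates)
    hom.set_coding_flags(candidates, by_id, cfg.min_orf_aa)
    removed_coding = [c for c in candidates if c.coding_flag]
    noncoding = [c for c in candidates if not c.coding_flag]
    counts["coding_removed"] = len(removed_coding)
    counts["folded"] = len(noncoding)
    log.info("candidates: %d hits -> %d windows -> %d after coding filter",
             len(hits), len(candidates), len(noncoding))

    evaluations = [crit.evaluate_candidate(c, fold_mfe(c.seq, model), thresholds)
                   for c in noncoding]
    # one evaluation per window: keep the best MFEI among co-located hits
    best: Dict[Tuple[str, str, int, int], crit.HairpinEvaluation] = {}
    for ev in evaluations:
        c = ev.candidate
        key = (c.hit.transcript_id, c.hit.strand, c.window_start, c.window_end)
        if key not in best or ev.mfei > best[key].mfei:
            best[key] = ev
    deduped = sorted(best.values(),
                     key=lambda e: (e.candidate.hit.transcript_id,
                                    e.candidate.window_start))
    accepted = [e for e in deduped if e.verdict]
    counts["evaluated"] = len(deduped)
    counts["accepted"] = len(accepted)
    reason_hist: Dict[str, int] = {}
    for e in deduped:
        if not e.verdict:
            reason_hist[e.fail_reason] = reason_hist.get(e.fail_reason, 0) + 1
    log.info("accepted %d / %d evaluated windows (fail reasons: %s)",
             len(accepted), len(deduped), reason_hist or "none")
    summary = crit.summarize_mfei(accepted)

    manifest = RunManifest(
        tool_version=__version__, config=cfg.to_dict(),
        inputs={transcripts_path: _sha256(transcripts_path),
                matures_path: _sha256(matures_path)},
        counts=counts)
    table = _candidates_table(deduped, removed_coding)
    result = MirnaResult(deduped, accepted, removed_coding, summary, manifest, table)
    if out_dir:
        _write_mirna_outputs(result, out_dir)
    return result


def _candidates_table(evaluations: List[crit.HairpinEvaluation],
                      removed_coding: List[hom.PrecursorCandidate]) -> pd.DataFrame:
    rows = []
    for ev in evaluations:
        c = ev.candidate
        rows.append({
            "transcript_id": c.hit.transcript_id,
            "mature_id": c.hit.mature_id,
            "family": hom.parse_family(c.hit.mature_id),
            "strand": c.hit.strand,
            "window_start": c.window_start + 1,
            "window_end": c.window_end,
            "arm": ev.arm,
            "star_mismatches": ev.star_mismatches,
            "delta_g_mag": round(ev.fold.delta_g_mag, 2),
            "gc_pct": round(ev.gc_pct, 2),
            "amfe": round(ev.amfe, 2),
            "mfei": round(ev.mfei, 2),
            "pass_arm": ev.passes["arm"],
            "pass_mfei": ev.passes["mfei"],
            "pass_star_mismatch": ev.passes["star_mismatch"],
            "pass_loop_break": ev.passes["loop_break"],
            "coding_flag": False,
            "truncated": c.truncated,
            "verdict": ev.verdict,
            "fail_reason": ev.fail_reason,
        })
    for c in removed_coding:
        rows.append({
            "transcript_id": c.hit.transcript_id,
            "mature_id": c.hit.mature_id,
            "family": hom.parse_family(c.hit.mature_id),
            "strand": c.hit.strand,
            "window_start": c.window_start + 1,
            "window_end": c.window_end,
            "arm": "", "star_mismatches": pd.NA, "delta_g_mag": pd.NA,
            "gc_pct": pd.NA, "amfe": pd.NA, "mfei": pd.NA,
            "pass_arm": pd.NA, "pass_mfei": pd.NA,
            "pass_star_mismatch": pd.NA, "pass_loop_break": pd.NA,
            "coding_flag": True, "truncated": c.truncated,
            "verdict": False, "fail_reason": "coding",
        })
    return pd.DataFrame(rows)


def _write_mirna_outputs(result: MirnaResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.candidates_table.to_csv(os.path.join(out_dir, "candidates.tsv"),
                                   sep="\t", index=False)
    with open(os.path.join(out_dir, "accepted.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for k, ev in enumerate(result.accepted, 1):
            c = ev.candidate
            fam = hom.parse_family(c.hit.mature_id)
            strand = c.hit.strand
            fh.write("\t".join([
                c.hit.transcript_id, "mirssr", "miRNA_primary_transcript",
                str(c.window_start + 1), str(c.window_end), ".", strand, ".",
                f"ID=pre{k};family={fam};mature={c.hit.mature_id};"
                f"mfei={ev.mfei:.2f};arm={ev.arm}"]) + "\n")
            fh.write("\t".join([
                c.hit.transcript_id, "mirssr", "miRNA",
                str(c.hit.t_start + 1), str(c.hit.t_end), ".", strand, ".",
                f"ID=mir{k};Parent=pre{k}"]) + "\n")
    s = result.summary
    with open(os.path.join(out_dir, "mfei_summary.tsv"), "w") as fh:
        fh.write("n\tmean\tmin\tmax\n")
        if s.n:
            fh.write(f"{s.n}\t{s.mean:.2f}\t{s.min:.2f}\t{s.max:.2f}\n")
        else:
            fh.write("0\t\t\t\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(result.manifest.to_json() + "\n")


def run_ssr_pipeline(transcripts_path: str,
                     config: Optional[PipelineConfig] = None,
                     out_dir: Optional[str] = None) -> SsrResult:
    cfg = config or PipelineConfig()
    transcripts = [hom.Transcript(i, s) for i, s in read_fasta(transcripts_path)]
    constraints = prm.PrimerConstraints(
        product_min=cfg.product_min, product_max=cfg.product_max,
        len_min=cfg.primer_len_min, len_max=cfg.primer_len_max,
        tm_min=cfg.tm_min, tm_max=cfg.tm_max, tm_opt=cfg.tm_opt,
        monovalent_mm=cfg.monovalent_mm, oligo_nm=cfg.oligo_nm)
    counts = {"transcripts": len(transcripts)}
    loci: List[ssrmod.SSRLocus] = []
    pairs: List[prm.PrimerPair] = []
    for tr in transcripts:
        found = ssrmod.scan_ssrs(tr, cfg.ssr_thresholds)
        found = ssrmod.merge_compound(found, cfg.compound_max_interruption)
        loci.extend(found)
        for loc in found:
            designed = prm.design_primer_pairs(tr, loc, constraints,
                                               max_pairs=cfg.primers_per_locus)
            pairs.extend(designed)
    counts["ssr_loci"] = len(loci)
    counts["primer_pairs"] = len(pairs)
    log.info("SSR scan: %d loci in %d transcripts; %d primer pairs designed",
             len(loci), len(transcripts), len(pairs))
    summary = ssrmod.ssr_summary(loci, cfg.exclude_mono)
    manifest = RunManifest(
        tool_version=__version__, config=cfg.to_dict(),
        inputs={transcripts_path: _sha256(transcripts_path)}, counts=counts)
    result = SsrResult(loci, pairs, summary, manifest,
                       _loci_table(loci), _primer_table(pairs))
    if out_dir:
        _write_ssr_outputs(result, out_dir)
    return result


def _loci_table(loci: List[ssrmod.SSRLocus]) -> pd.DataFrame:
    rows = []
    nr: Dict[str, int] = {}
    for loc in loci:
        nr[loc.transcript_id] = nr.get(loc.transcript_id, 0) + 1
        rows.append({
            "ID": loc.transcript_id,
            "SSR_nr": nr[loc.transcript_id],
            "SSR_type": f"p{loc.unit_len}" if loc.compound_id is None else "c",
            "SSR": f"({loc.motif}){loc.repeats}",
            "motif_class": str(ssrmod.canonical_motif_class(loc.motif)),
            "size": loc.end - loc.start,
            "start": loc.start + 1,
            "end": loc.end,
        })
    return pd.DataFrame(rows)


def _primer_table(pairs: List[prm.PrimerPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        loc = p.target_locus
        rows.append({
            "ID": loc.transcript_id,
            "SSR": f"({loc.motif}){loc.repeats}",
            "forward_primer": p.forward_seq,
            "forward_tm": round(p.fwd_tm, 3),
            "forward_len": len(p.forward_seq),
            "reverse_primer": p.reverse_seq,
            "reverse_tm": round(p.rev_tm, 3),
            "reverse_len": len(p.reverse_seq),
            "product_size": p.product_size,
        })
    return pd.DataFrame(rows)


def _write_ssr_outputs(result: SsrResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.loci_table.to_csv(os.path.join(out_dir, "ssr.tsv"), sep="\t", index=False)
    result.primer_table.to_csv(os.path.join(out_dir, "primers.tsv"),
                               sep="\t", index=False)
    result.summary.to_csv(os.path.join(out_dir, "ssr_summary.tsv"),
                          sep="\t", index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(result.manifest.to_json() + "\n")
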