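"""End-to-end orchestration: filter -> phylo -> verify -> structure ->
selection -> expression, with a run manifest and the synthetic demo.

A candidate becomes a FINAL HGT call only if it survives the filter cascade,
is classified as nested in a donor clade, maps onto an assembly contig at
the strict thresholds, and the mapped contigs show no coverage bias.
Structure, selection and expression stages are annotative: they never veto
a call.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import dge as _dge
from . import filtering as _filtering
from . import io as hio
from . import kaks as _kaks
from . import phylo as _phylo
from . import structure as _structure
from . import synthetic as _synthetic
from . import verify as _verify
from .align import kmer_set, shares_kmer
from .phylo import HgtParams, MultipleAlignment

logger = logging.getLogger("hgtscan")


@dataclass
class PipelineParams:
    """Stage thresholds; defaults follow the published analysis."""

    max_e: float = 1e-20
    min_identity: float = 25.0
    min_overlap: int = 25
    min_homologs: int = 10
    bootstrap: int = 1000
    min_support: float = 70.0
    min_basal_donor_species: int = 3
    map_max_e: float = 1e-40
    map_min_identity: float = 90.0
    structure_max_e: float = 1e-10
    dge_min_ratio: float = 2.0
    dge_max_p: float = 0.001
    dge_max_fdr: float = 0.001
    n_background: int = 1000
    alpha: float = 0.05
    seed: int = 7

    def filter_thresholds(self) -> _filtering.FilterThresholds:
        return _filtering.FilterThresholds(
            max_e=self.max_e, min_identity=self.min_identity,
            min_overlap=self.min_overlap, min_homologs=self.min_homologs)

    def hgt_params(self) -> HgtParams:
        return HgtParams(min_basal_donor_species=self.min_basal_donor_species,
                         min_support=self.min_support)

    def dge_criteria(self) -> _dge.DgeCriteria:
        return _dge.DgeCriteria(min_ratio=self.dge_min_ratio,
                                max_p=self.dge_max_p, max_fdr=self.dge_max_fdr)


@dataclass
class RunManifest:
    params: Dict
    attrition: Dict[str, int]
    final_calls: List[str]
    checksums: Dict[str, str]
    runtime_s: float
    version: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_alignment(path: Path, taxmap: Dict[str, str], query_id: str
                    ) -> MultipleAlignment:
    seqs = hio.read_fasta(path)
    groups = {label: taxmap.get(label, "arthropod") for label in seqs}
    groups[query_id] = "arthropod"
    return MultipleAlignment(labels=list(seqs), rows=list(seqs.values()),
                             groups=groups)


def run_all(data_dir, out_dir, params: PipelineParams = PipelineParams()
            ) -> RunManifest:
    """Execute every stage on a dataset directory (see
    :func:`hgtscan.synthetic.write_dataset` for the layout)."""
    t0 = time.time()
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: filter cascade -----------------------------------------
    segments = hio.read_fasta(data / "segments.fasta")
    taxmap = hio.read_taxmap(data / "taxmap.tsv")
    hits = _filtering.read_hit_table(data / "hits.tsv", taxmap)
    report = _filtering.run_cascade(list(segments), hits,
                                    params.filter_thresholds())
    report.to_tsv(out / "filter_report.tsv")
    logger.info("filter cascade: %s -> %d candidates",
                dict(report.stage_counts), len(report.retained))

    attrition: Dict[str, int] = dict(report.stage_counts)

    # ---- stage 2: phylogenetic classification ----------------------------
    calls: List[_phylo.HGTCall] = []
    hgt_ids: List[str] = []
    n_no_alignment = 0
    for qid in report.retained:
        aln_path = data / "alignments" / f"{qid}.afa"
        if not aln_path.exists():
            n_no_alignment += 1
            calls.append(_phylo.HGTCall(query_id=qid, verdict="ambiguous",
                                        notes="no alignment provided"))
            continue
        aln = _load_alignment(aln_path, taxmap, qid)
        try:
            trimmed, _ = _phylo.trim_conserved_blocks(aln)
        except ValueError:
            trimmed = aln
        ptree = _phylo.bootstrap_support(trimmed, n_reps=params.bootstrap,
                                         seed=params.seed)
        call = _phylo.classify_hgt_topology(ptree, qid, params.hgt_params())
        calls.append(call)
        if call.verdict == "hgt":
            hgt_ids.append(qid)
    _phylo.calls_to_tsv(out / "hgt_calls.tsv", calls)
    attrition["phylo_rejected"] = len(report.retained) - len(hgt_ids)
    logger.info("phylo: %d/%d candidates keep an HGT topology",
                len(hgt_ids), len(report.retained))

    # ---- stage 3: genome verification ------------------------------------
    contigs = hio.read_fasta(data / "contigs.fasta")
    candidates = {qid: segments[qid] for qid in hgt_ids}
    contig_hits = _verify.map_to_contigs(
        candidates, contigs, max_e=params.map_max_e,
        min_identity=params.map_min_identity) if candidates else []
    _verify.contig_hits_to_tsv(out / "contig_hits.tsv", contig_hits)
    best_contig: Dict[str, str] = {}
    for h in contig_hits:
        best_contig.setdefault(h.candidate_id, h.contig_id)
    mapped = [qid for qid in hgt_ids if qid in best_contig]
    attrition["unmapped"] = len(hgt_ids) - len(mapped)

    reads_path = data / "reads.fastq"
    coverage_ok = True
    bias = None
    if reads_path.exists() and mapped:
        reads = hio.read_fastq(reads_path)
        profiles = _verify.compute_coverage(reads, contigs)
        with open(out / "coverage.tsv", "w") as fh:
            fh.write("contig_id\tlength\taligned_reads\tdepth\n")
            for cid, p in sorted(profiles.items()):
                fh.write(f"{cid}\t{p.length}\t{p.aligned_reads}\t{p.depth:.4f}\n")
        target_cids = sorted({best_contig[q] for q in mapped})
        pool_cids = [c for c in sorted(contigs) if c not in target_cids]
        if len(target_cids) >= 2 and pool_cids:
            n_bg = min(params.n_background, len(pool_cids))
            bias = _verify.coverage_bias_test(
                [profiles[c].depth for c in target_cids],
                [profiles[c].depth for c in pool_cids],
                n_background=n_bg, seed=params.seed, alpha=params.alpha)
            coverage_ok = bias.verdict == "consistent"
            with open(out / "coverage_test.json", "w") as fh:
                json.dump(asdict(bias), fh, indent=1)
                fh.write("\n")
            logger.info("coverage test: %s (p = %.3g)", bias.verdict, bias.p_value)

    final = mapped if coverage_ok else []
    attrition["coverage_biased"] = len(mapped) - len(final)
    attrition["final_hgt"] = len(final)
    (out / "final_calls.txt").write_text("".join(f"{q}\n" for q in final))

    # ---- stage 4: structure (annotative) ---------------------------------
    donor_path = data / "donor_genome.fasta"
    structure_lines: List[str] = []
    if donor_path.exists():
        donors = hio.read_fasta(donor_path)
        annotations = (hio.read_gff3(data / "donor_genome.gff3")
                       if (data / "donor_genome.gff3").exists() else [])
        donor_kmers = {did: kmer_set(seq, 21) for did, seq in donors.items()}
        all_blocks = []
        for cid in sorted(contigs):
            ckm = kmer_set(contigs[cid], 21)
            for did in sorted(donors):
                if not shares_kmer(ckm, donor_kmers[did]):
                    continue
                blocks = _structure.compare_segments(
                    contigs[cid], donors[did], max_e=params.structure_max_e)
                if not blocks:
                    continue
                all_blocks.extend(blocks)
                rep = _structure.summarize_transfer(
                    cid, blocks, [a for a in annotations if a.seq_id == did])
                structure_lines.append(rep.to_text())
                operons = _structure.predict_operons(
                    [a for a in annotations if a.seq_id == did])
                for op in operons:
                    structure_lines.append(
                        "operon: " + ",".join(op.genes) + f" ({op.strand})")
        _structure.blocks_to_tsv(out / "synteny_blocks.tsv", all_blocks)
    for qid in final:
        cid = best_contig[qid]
        try:
            introns = _structure.detect_introns(qid, segments[qid], contigs[cid])
        except ValueError:
            continue
        for call in introns:
            structure_lines.append(
                f"intron {qid} on {cid}: [{call.start}, {call.end}) "
                f"{call.length} bp {call.donor_site}..{call.acceptor_site}"
                f"{' canonical' if call.canonical else ''}")
    (out / "structure_report.txt").write_text(
        "".join(line + "\n" for line in structure_lines))

    # ---- stage 5: selection (annotative) ---------------------------------
    pairs_path = data / "ortholog_pairs.fasta"
    if pairs_path.exists():
        seqs = hio.read_fasta(pairs_path)
        pairs: Dict[str, _kaks.CodonAlignment] = {}
        for name in sorted({k.rsplit("|", 1)[0] for k in seqs}):
            a, b = seqs.get(f"{name}|A"), seqs.get(f"{name}|B")
            if a and b:
                pairs[name] = _kaks.CodonAlignment(a, b)
        table = _kaks.screen_orthologs(pairs)
        table.to_tsv(out / "kaks.tsv")
        logger.info("selection screen: %s", table.summary)

    # ---- stage 6: expression (annotative) --------------------------------
    counts_path = data / "counts.tsv"
    if counts_path.exists():
        cm = _dge.CountMatrix.from_tsv(counts_path)
        fpkm = _dge.compute_fpkm(cm)
        fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        result = _dge.run_dge(cm, params.dge_criteria())
        result.to_tsv(out / "dge.tsv")
        logger.info("DGE: %d flagged gene/pair combinations",
                    int(result.table["flag"].sum()))

    checksums = {p.name: _sha256(p) for p in sorted(out.iterdir())
                 if p.is_file() and p.name != "manifest.json"}
    manifest = RunManifest(params=asdict(params), attrition=attrition,
                           final_calls=final, checksums=checksums,
                           runtime_s=round(time.time() - t0, 2),
                           version="0.1.0")
    manifest.write(out / "manifest.json")
    return manifest


def make_demo(seed: int = 7, outdir="demo_data",
              config: Optional[_synthetic.SimulationConfig] = None
              ) -> _synthetic.SyntheticDataset:
    """Write the small standard demo dataset (50 host genes, 5 bacterial +
    2 fungal planted HGT genes) to ``outdir``."""
    cfg = config or _synthetic.SimulationConfig(seed=seed)
    ds = _synthetic.generate_dataset(cfg)
    _synthetic.write_dataset(ds, outdir)
    return ds
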