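"""Structural comparison of HGT-bearing contigs against donor genomes.

Covers four analyses: translated (six-frame) synteny blocks between a contig
and a donor genome; a transfer summary deciding which donor genes were
co-transferred and which intergenic stretches went missing; spliced-match
intron detection between a transcript and its genomic copy; and a simple
same-strand/gap operon heuristic standing in for a database lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import align as _align
from .io import GeneAnnotation


@dataclass
class SyntenyBlock:
    """One translated local-similarity block (nucleotide coordinates,
    0-based half-open, on the forward strands of contig and donor)."""

    contig_start: int
    contig_end: int
    donor_start: int
    donor_end: int
    strand: str
    frame: Tuple[int, int]     # (contig frame, donor frame), 0-2 fwd / 3-5 rev
    e_value: float
    percent_identity: float
    score: int


def compare_segments(contig: str, donor: str, max_e: float = 1e-10,
                     word_size: int = 5) -> List[SyntenyBlock]:
    """tBLASTx-style comparison: ungapped high-scoring pairs between all six
    reading frames of contig and donor, filtered at ``max_e`` and reported
    sorted by contig coordinate.

    An exact nucleotide copy matches in every co-shifted frame pair, so
    near-duplicate blocks (same nucleotide region in several frame pairs)
    are suppressed, keeping the best-scoring representative."""
    if len(contig) < 3:
        raise ValueError("contig shorter than one codon")
    db_size = max(len(donor) // 3, 1)
    blocks: List[SyntenyBlock] = []
    contig_frames = _align.six_frame_translations(contig)
    donor_frames = _align.six_frame_translations(donor)
    for cf, cprot in contig_frames:
        if not cprot:
            continue
        cprot = cprot.replace("*", "X")
        for df, dprot in donor_frames:
            if not dprot:
                continue
            dprot = dprot.replace("*", "X")
            for hsp in _align.ungapped_hsps(cprot, dprot, word_size=word_size):
                e = _align.e_value(hsp.score, len(cprot), db_size,
                                   _align.PROTEIN_LAMBDA, _align.PROTEIN_K)
                if e > max_e:
                    continue
                c_start, c_end = _aa_to_nt(hsp.q_start, hsp.q_end, cf, len(contig))
                d_start, d_end = _aa_to_nt(hsp.s_start, hsp.s_end, df, len(donor))
                strand = "+" if (cf < 3) == (df < 3) else "-"
                blocks.append(SyntenyBlock(
                    contig_start=c_start, contig_end=c_end,
                    donor_start=d_start, donor_end=d_end,
                    strand=strand, frame=(cf, df), e_value=e,
                    percent_identity=hsp.identity, score=hsp.score))
    blocks = _suppress_redundant(blocks)
    blocks.sort(key=lambda b: (b.contig_start, b.contig_end))
    return blocks


def _overlap_frac(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def _suppress_redundant(blocks: List[SyntenyBlock],
                        min_jaccard: float = 0.8) -> List[SyntenyBlock]:
    """Keep the best-scoring block among near-duplicates covering the same
    contig/donor nucleotide region in different frame pairs."""
    kept: List[SyntenyBlock] = []
    for b in sorted(blocks, key=lambda x: -x.score):
        dup = any(
            _overlap_frac((b.contig_start, b.contig_end),
                          (k.contig_start, k.contig_end)) >= min_jaccard
            and _overlap_frac((b.donor_start, b.donor_end),
                              (k.donor_start, k.donor_end)) >= min_jaccard
            for k in kept)
        if not dup:
            kept.append(b)
    return kept


def _aa_to_nt(aa_start: int, aa_end: int, frame: int, seq_len: int
              ) -> Tuple[int, int]:
    """Map aa coordinates in a reading frame back to forward-strand
    nucleotide coordinates."""
    if frame < 3:
        return frame + 3 * aa_start, frame + 3 * aa_end
    off = frame - 3
    return seq_len - (off + 3 * aa_end), seq_len - (off + 3 * aa_start)


@dataclass
class TransferSegmentReport:
    contig_id: str
    blocks: List[SyntenyBlock]
    co_transferred_genes: List[str]
    missing_intergenic: List[Tuple[int, int]]   # donor coordinates
    total_span: int                             # bp on the contig

    def to_text(self) -> str:
        lines = [f"contig {self.contig_id}: {len(self.blocks)} blocks, "
                 f"span {self.total_span} bp"]
        lines.append("co-transferred genes: "
                     + (", ".join(self.co_transferred_genes) or "none"))
        for a, b in self.missing_intergenic:
            lines.append(f"missing intergenic donor interval: [{a}, {b})")
        return "\n".join(lines)


def _interval_coverage(start: int, end: int,
                       blocks: Sequence[Tuple[int, int]]) -> float:
    """Fraction of [start, end) covered by the union of intervals."""
    if end <= start:
        return 0.0
    clipped = sorted((max(a, start), min(b, end)) for a, b in blocks
                     if b > start and a < end)
    covered = 0
    cur = start
    for a, b in clipped:
        a = max(a, cur)
        if b > a:
            covered += b - a
            cur = b
    return covered / (end - start)


def summarize_transfer(contig_id: str, blocks: Sequence[SyntenyBlock],
                       donor_annotations: Sequence[GeneAnnotation],
                       gene_cov_min: float = 0.5,
                       intergenic_cov_max: float = 0.2) -> TransferSegmentReport:
    """Decide co-transferred donor genes (>= 50% of the gene covered by
    blocks) and missing intergenic donor intervals (< 20% covered between
    consecutive co-transferred genes)."""
    blocks = list(blocks)
    donor_spans = [(b.donor_start, b.donor_end) for b in blocks]
    co: List[str] = []
    co_ann: List[GeneAnnotation] = []
    for ann in sorted(donor_annotations, key=lambda a: a.start):
        if _interval_coverage(ann.start, ann.end, donor_spans) >= gene_cov_min:
            co.append(ann.name)
            co_ann.append(ann)
    missing: List[Tuple[int, int]] = []
    for left, right in zip(co_ann, co_ann[1:]):
        gap_start, gap_end = left.end, right.start
        if gap_end <= gap_start:
            continue
        if _interval_coverage(gap_start, gap_end, donor_spans) < intergenic_cov_max:
            missing.append((gap_start, gap_end))
    if blocks:
        span = max(b.contig_end for b in blocks) - min(b.contig_start for b in blocks)
    else:
        span = 0
    return TransferSegmentReport(contig_id=contig_id, blocks=blocks,
                                 co_transferred_genes=co,
                                 missing_intergenic=missing, total_span=span)


@dataclass
class IntronCall:
    transcript_id: str
    start: int                 # genomic (contig) coordinates, half-open
    end: int
    donor_site: str            # first two intron bases
    acceptor_site: str         # last two intron bases
    canonical: bool = field(init=False)

    def __post_init__(self):
        self.canonical = self.donor_site == "GT" and self.acceptor_site == "AG"

    @property
    def length(self) -> int:
        return self.end - self.start


def _exact_match_runs(transcript: str, contig: str, k: int
                      ) -> List[Tuple[int, int, int]]:
    """Maximal exact-match runs as (t_start, g_start, length), length >= k,
    built by coalescing shared k-mers along diagonals."""
    positions: Dict[str, List[int]] = {}
    for i in range(len(contig) - k + 1):
        positions.setdefault(contig[i:i + k], []).append(i)
    anchors: Dict[int, List[int]] = {}
    for t in range(len(transcript) - k + 1):
        for g in positions.get(transcript[t:t + k], ()):
            anchors.setdefault(g - t, []).append(t)
    runs: List[Tuple[int, int, int]] = []
    for diag, ts in anchors.items():
        ts.sort()
        start = prev = ts[0]
        for t in ts[1:]:
            if t == prev + 1:
                prev = t
            else:
                runs.append((start, start + diag, prev - start + k))
                start = prev = t
        runs.append((start, start + diag, prev - start + k))
    return sorted(runs)


def detect_introns(transcript_id: str, transcript: str, contig: str,
                   min_intron: int = 30, min_exon: int = 20,
                   min_chain_cov: float = 0.8) -> List[IntronCall]:
    """Detect introns by chaining co-linear exact matches between a
    transcript and its genomic copy.

    Consecutive chained exons with zero transcript gap and a genomic gap of
    at least ``min_intron`` yield intron calls (with splice-site
    dinucleotides); smaller genomic gaps are treated as alignment gaps. The
    chain must cover at least ``min_chain_cov`` of the transcript."""
    runs = [r for r in _exact_match_runs(transcript, contig, min_exon)
            if r[2] >= min_exon]
    if not runs:
        raise ValueError(f"transcript {transcript_id!r} not mappable")
    # chain: maximize covered transcript length over co-linear runs; small
    # overlaps between consecutive runs are allowed (coincidental matches at
    # junction boundaries extend runs past the true splice point)
    runs.sort(key=lambda r: (r[0], r[1]))
    best_len = [r[2] for r in runs]
    prev_idx: List[Optional[int]] = [None] * len(runs)
    for i, (ti, gi, li) in enumerate(runs):
        for j in range(i):
            tj, gj, lj = runs[j]
            if tj >= ti or gj >= gi:
                continue
            overlap = max(tj + lj - ti, gj + lj - gi, 0)
            if overlap >= min(li, lj):
                continue
            cand = best_len[j] + li - max(tj + lj - ti, 0)
            if cand > best_len[i]:
                best_len[i] = cand
                prev_idx[i] = j
    end = int(np.argmax(best_len))
    chain: List[Tuple[int, int, int]] = []
    node: Optional[int] = end
    while node is not None:
        chain.append(runs[node])
        node = prev_idx[node]
    chain.reverse()
    covered = int(best_len[end])
    if covered < min_chain_cov * len(transcript):
        raise ValueError(f"transcript {transcript_id!r} not mappable "
                         f"(chain covers {covered}/{len(transcript)})")
    calls: List[IntronCall] = []
    for (t1, g1, l1), (t2, g2, _l2) in zip(chain, chain[1:]):
        junction_lo = min(t2, t1 + l1)       # ambiguous junction window
        junction_hi = t1 + l1
        if t2 > t1 + l1:
            continue  # transcript not contiguous across the gap: no call
        g_len = (g2 - g1) - (t2 - t1)        # intron length, shift-invariant
        if g_len < min_intron:
            continue
        # choose the junction placement giving canonical GT..AG if possible
        chosen = junction_hi
        for t in range(junction_hi, junction_lo - 1, -1):
            a = g1 + (t - t1)
            b = g2 + (t - t2)
            if contig[a:a + 2] == "GT" and contig[b - 2:b] == "AG":
                chosen = t
                break
        start = g1 + (chosen - t1)
        endg = g2 + (chosen - t2)
        intron = contig[start:endg]
        calls.append(IntronCall(transcript_id=transcript_id,
                                start=start, end=endg,
                                donor_site=intron[:2],
                                acceptor_site=intron[-2:]))
    return calls


@dataclass
class OperonPrediction:
    genes: List[str]
    strand: str
    max_gap: int

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValueError("operon needs >= 2 genes")


def predict_operons(annotations: Sequence[GeneAnnotation], max_gap: int = 200,
                    min_genes: int = 2) -> List[OperonPrediction]:
    """Maximal runs of same-strand genes with successive intergenic gaps
    <= max_gap and at least min_genes members."""
    out: List[OperonPrediction] = []
    anns = sorted(annotations, key=lambda a: a.start)
    run: List[GeneAnnotation] = []

    def flush():
        if len(run) >= min_genes:
            gaps = [b.start - a.end for a, b in zip(run, run[1:])]
            out.append(OperonPrediction(genes=[a.name for a in run],
                                        strand=run[0].strand,
                                        max_gap=max(gaps) if gaps else 0))

    for ann in anns:
        if run and (ann.strand != run[-1].strand
                    or ann.start - run[-1].end > max_gap
                    or ann.seq_id != run[-1].seq_id):
            flush()
            run = []
        run.append(ann)
    flush()
    return out


def blocks_to_tsv(path, blocks: Sequence[SyntenyBlock]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_start\tcontig_end\tdonor_start\tdonor_end\tstrand\t"
                 "frame_contig\tframe_donor\te_value\tpercent_identity\tscore\n")
        for b in blocks:
            fh.write("\t".join([
                str(b.contig_start), str(b.contig_end), str(b.donor_start),
                str(b.donor_end), b.strand, str(b.frame[0]), str(b.frame[1]),
                f"{b.e_value:.3e}", f"{b.percent_identity:.2f}", str(b.score)])
                + "\n")
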