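"""Genome-residency verification for HGT candidates.

Three checks mirror the verification chain: (1) strict BLASTn-style mapping
of each candidate onto assembly contigs (E <= 1e-40, identity >= 90%),
(2) a read-coverage contamination test comparing the depth of
candidate-bearing contigs against randomly sampled background contigs with
a two-sided Welch t-test, and (3) a mitochondrial-genome screen that flags
candidates with no similarity to the mito sequence as not NUMT-like.

The built-in read aligner keeps the external mapper's rule of at most two
base mismatches per read (exact pigeonhole seeding, best placement, ties
resolved toward the lowest contig id and coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import align as _align


@dataclass
class ContigHit:
    candidate_id: str
    contig_id: str
    e_value: float
    percent_identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("identity out of range")
        if self.q_start >= self.q_end or self.s_start >= self.s_end:
            raise ValueError("empty span")


def map_to_contigs(candidates: Mapping[str, str], contigs: Mapping[str, str],
                   max_e: float = 1e-40, min_identity: float = 90.0,
                   prefilter_k: int = 11) -> List[ContigHit]:
    """Local-alignment mapping of candidates onto contigs.

    Scoring is +1/-2 with gap open 5 / extend 2; E-values use the total
    contig length as database size. Pairs sharing no ``prefilter_k``-mer
    (either strand) are skipped without alignment. Hits are sorted best
    (lowest E) first within each candidate, candidates in input order.
    """
    if not contigs:
        raise ValueError("empty contig set")
    db_size = sum(len(s) for s in contigs.values())
    contig_kmers = {cid: _align.kmer_set(seq, prefilter_k)
                    for cid, seq in contigs.items()}
    out: List[ContigHit] = []
    for cand_id, cand_seq in candidates.items():
        fwd = _align.kmer_set(cand_seq, prefilter_k)
        rev = _align.kmer_set(_align.revcomp(cand_seq), prefilter_k)
        cand_hits: List[ContigHit] = []
        for cid in sorted(contigs):
            cseq = contigs[cid]
            strand_hits = []
            if _align.shares_kmer(fwd, contig_kmers[cid]):
                strand_hits.append(("+", cand_seq))
            if _align.shares_kmer(rev, contig_kmers[cid]):
                strand_hits.append(("-", _align.revcomp(cand_seq)))
            best: Optional[Tuple[str, _align.LocalHit]] = None
            for strand, qseq in strand_hits:
                hit = _align.nucleotide_local_align(qseq, cseq, db_size=db_size)
                if hit is None:
                    continue
                if best is None or hit.score > best[1].score:
                    best = (strand, hit)
            if best is None:
                continue
            strand, hit = best
            if hit.e_value <= max_e and hit.identity >= min_identity:
                q_start, q_end = hit.q_start, hit.q_end
                if strand == "-":
                    q_start = len(cand_seq) - hit.q_end
                    q_end = len(cand_seq) - hit.q_start
                cand_hits.append(ContigHit(
                    candidate_id=cand_id, contig_id=cid,
                    e_value=hit.e_value, percent_identity=hit.identity,
                    q_start=q_start, q_end=q_end,
                    s_start=hit.s_start, s_end=hit.s_end, strand=strand))
        cand_hits.sort(key=lambda h: h.e_value)
        out.extend(cand_hits)
    return out


@dataclass
class CoverageProfile:
    contig_id: str
    length: int
    aligned_reads: int
    aligned_bases: int

    @property
    def depth(self) -> float:
        return self.aligned_bases / self.length


def compute_coverage(reads: Mapping[str, str], contigs: Mapping[str, str],
                     max_mismatches: int = 2) -> Dict[str, CoverageProfile]:
    """Assign each read to its best placement with <= max_mismatches and
    report per-contig mean depth.

    Unmapped reads are dropped; multi-mapping reads go to the single best
    placement (fewest mismatches, then lowest contig id, then lowest
    coordinate). Forward-strand placements only.
    """
    order = sorted(contigs)
    arrays = {cid: np.frombuffer(contigs[cid].encode(), dtype=np.uint8)
              for cid in order}
    profiles = {cid: CoverageProfile(cid, len(contigs[cid]), 0, 0)
                for cid in order}
    index: Dict[bytes, List[Tuple[str, int]]] = {}
    kmer = None
    lens = {len(r) for r in reads.values()}
    if not reads:
        return profiles
    kmer = max(min(lens) // (max_mismatches + 1), 8)
    for cid in order:
        seq = contigs[cid].encode()
        for pos in range(len(seq) - kmer + 1):
            index.setdefault(seq[pos:pos + kmer], []).append((cid, pos))
    for rid in sorted(reads):
        rseq = reads[rid]
        L = len(rseq)
        renc = rseq.encode()
        rarr = np.frombuffer(renc, dtype=np.uint8)
        seen = set()
        best: Optional[Tuple[int, str, int]] = None
        for chunk in range(max_mismatches + 1):
            off = chunk * kmer
            if off + kmer > L:
                break
            for cid, pos in index.get(renc[off:off + kmer], ()):
                start = pos - off
                if start < 0 or start + L > len(contigs[cid]):
                    continue
                key = (cid, start)
                if key in seen:
                    continue
                seen.add(key)
                mism = int(np.count_nonzero(arrays[cid][start:start + L] != rarr))
                if mism > max_mismatches:
                    continue
                cand = (mism, cid, start)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            _, cid, _ = best
            profiles[cid].aligned_reads += 1
            profiles[cid].aligned_bases += L
    return profiles


@dataclass
class CoverageBiasResult:
    target_mean: float
    background_mean: float
    t_statistic: float
    df: float
    p_value: float
    verdict: str  # consistent | biased
    n_target: int
    n_background: int


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, df, p). Zero variance in both
    groups with equal means is the defined p = 1 limit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def coverage_bias_test(target_depths: Sequence[float],
                       background_pool: Sequence[float],
                       n_background: int = 1000, seed: int = 0,
                       alpha: float = 0.05) -> CoverageBiasResult:
    """Welch-compare target contig depths against ``n_background`` contigs
    sampled without replacement (seeded) from the background pool.
    Verdict is 'consistent' iff p > alpha."""
    target = np.asarray(target_depths, dtype=float)
    pool = np.asarray(background_pool, dtype=float)
    if target.size < 2:
        raise ValueError("need at least two target contigs")
    if n_background > pool.size:
        raise ValueError("n_background exceeds available contigs")
    rng = np.random.default_rng(seed)
    background = rng.choice(pool, size=n_background, replace=False)
    t, df, p = welch_t_test(target, background)
    return CoverageBiasResult(
        target_mean=float(target.mean()),
        background_mean=float(background.mean()),
        t_statistic=t, df=df, p_value=p,
        verdict="consistent" if p > alpha else "biased",
        n_target=int(target.size), n_background=int(n_background))


def mito_screen(candidates: Mapping[str, str], mito_genome: str,
                max_e: float = 1e-10) -> Dict[str, List[ContigHit]]:
    """Map candidates against the mitochondrial genome; empty hit lists mark
    candidates as not NUMT-like."""
    hits = map_to_contigs(candidates, {"mito": mito_genome},
                          max_e=max_e, min_identity=0.0)
    out: Dict[str, List[ContigHit]] = {cid: [] for cid in candidates}
    for h in hits:
        out[h.candidate_id].append(h)
    return out


def contig_hits_to_tsv(path, hits: Iterable[ContigHit]) -> None:
    with open(path, "w") as fh:
        fh.write("candidate_id\tcontig_id\te_value\tpercent_identity\t"
                 "q_start\tq_end\ts_start\ts_end\tstrand\n")
        for h in hits:
            fh.write("\t".join([
                h.candidate_id, h.contig_id, f"{h.e_value:.3e}",
                f"{h.percent_identity:.2f}", str(h.q_start), str(h.q_end),
                str(h.s_start), str(h.s_end), h.strand]) + "\n")
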