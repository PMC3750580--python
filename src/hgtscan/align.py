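"""Local alignment utilities shared by the hit-table generator, the genome
verifier and the structure analyser.

Optimal affine-gap Smith-Waterman alignments are delegated to biotite's
C-accelerated dynamic programming; this module adds Karlin-Altschul
statistics, translated (BLASTx-like) search over reading frames, k-mer
prefilters, and ungapped diagonal HSP extraction (tBLASTx-like, where
multiple blocks per sequence pair are required).

Karlin-Altschul parameters are fixed constants published for the scoring
schemes used here, so results are reproducible without an external BLAST
binary:

* protein: BLOSUM62, gap open 11 / extend 1  -> lambda = 0.267, K = 0.041
* nucleotide: match +1 / mismatch -2, gap open 5 / extend 2
  -> lambda = 1.28, K = 0.46
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import biotite.sequence as bioseq
import biotite.sequence.align as bioalign
from Bio.Seq import Seq

PROTEIN_LAMBDA = 0.267
PROTEIN_K = 0.041
PROTEIN_GAP = (-11, -1)

NUC_LAMBDA = 1.28
NUC_K = 0.46
NUC_GAP = (-5, -2)

_BLOSUM62 = bioalign.SubstitutionMatrix.std_protein_matrix()
_NUC_ALPH = bioseq.NucleotideSequence.alphabet_unamb
_NUC_MATRIX = bioalign.SubstitutionMatrix(
    _NUC_ALPH, _NUC_ALPH,
    np.where(np.eye(4, dtype=bool), 1, -2).astype(np.int32),
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate a nucleotide string (frame 0, universal code, '*' for stops,
    trailing partial codon dropped)."""
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def six_frame_translations(nt: str) -> List[Tuple[int, str]]:
    """All six reading frames as (frame, protein). Frames 0-2 are forward
    offsets; 3-5 are offsets on the reverse complement."""
    rc = revcomp(nt)
    out = []
    for f in range(3):
        out.append((f, translate(nt[f:])))
    for f in range(3):
        out.append((3 + f, translate(rc[f:])))
    return out


def e_value(score: float, m: int, n: int, lam: float, k: float) -> float:
    return k * m * n * math.exp(-lam * score)


def bit_score(score: float, lam: float, k: float) -> float:
    return (lam * score - math.log(k)) / math.log(2.0)


@dataclass
class LocalHit:
    """One optimal local alignment with BLAST-tabular-style statistics.

    Coordinates are 0-based half-open on the original query/subject strings.
    """

    score: float
    bitscore: float
    e_value: float
    identity: float          # percent, 0-100
    length: int              # alignment columns
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: Optional[int] = None  # query frame for translated searches


def _hit_from_alignment(aln, m: int, n: int, lam: float, k: float) -> LocalHit:
    trace = aln.trace
    s1, s2 = aln.sequences
    matches = mismatches = gap_opens = 0
    prev_gap1 = prev_gap2 = False
    for a, b in trace:
        if a < 0:
            if not prev_gap1:
                gap_opens += 1
            prev_gap1, prev_gap2 = True, False
        elif b < 0:
            if not prev_gap2:
                gap_opens += 1
            prev_gap1, prev_gap2 = False, True
        else:
            prev_gap1 = prev_gap2 = False
            if s1[a] == s2[b]:
                matches += 1
            else:
                mismatches += 1
    qcols = trace[:, 0][trace[:, 0] >= 0]
    scols = trace[:, 1][trace[:, 1] >= 0]
    length = len(trace)
    score = float(aln.score)
    return LocalHit(
        score=score,
        bitscore=bit_score(score, lam, k),
        e_value=e_value(score, m, n, lam, k),
        identity=100.0 * matches / length if length else 0.0,
        length=length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=int(qcols.min()),
        q_end=int(qcols.max()) + 1,
        s_start=int(scols.min()),
        s_end=int(scols.max()) + 1,
    )


def protein_local_align(query: str, subject: str,
                        db_size: Optional[int] = None) -> Optional[LocalHit]:
    """Optimal local protein alignment (BLOSUM62, gap 11/1). ``db_size``
    overrides the subject length in the E-value (Karlin-Altschul n)."""
    if not query or not subject:
        return None
    q = bioseq.ProteinSequence(query)
    s = bioseq.ProteinSequence(subject)
    alns = bioalign.align_optimal(q, s, _BLOSUM62, gap_penalty=PROTEIN_GAP,
                                  local=True, max_number=1)
    if not alns or alns[0].score <= 0:
        return None
    n = db_size if db_size is not None else len(subject)
    return _hit_from_alignment(alns[0], len(query), n, PROTEIN_LAMBDA, PROTEIN_K)


def nucleotide_local_align(query: str, subject: str,
                           db_size: Optional[int] = None) -> Optional[LocalHit]:
    """Optimal local nucleotide alignment (+1/-2, gap 5/2)."""
    if not query or not subject:
        return None
    q = bioseq.NucleotideSequence(query)
    s = bioseq.NucleotideSequence(subject)
    alns = bioalign.align_optimal(q, s, _NUC_MATRIX, gap_penalty=NUC_GAP,
                                  local=True, max_number=1)
    if not alns or alns[0].score <= 0:
        return None
    n = db_size if db_size is not None else len(subject)
    return _hit_from_alignment(alns[0], len(query), n, NUC_LAMBDA, NUC_K)


def translated_align(nt_query: str, protein_subject: str,
                     db_size: Optional[int] = None,
                     both_strands: bool = True) -> Optional[LocalHit]:
    """Align a nucleotide query against a protein in its best reading frame
    (BLASTx-like). Query coordinates in the result are nucleotide positions
    on the forward strand of the query."""
    best: Optional[LocalHit] = None
    frames = six_frame_translations(nt_query) if both_strands else [
        (f, translate(nt_query[f:])) for f in range(3)
    ]
    for frame, prot in frames:
        prot = prot.replace("*", "X")
        if len(prot) < 1:
            continue
        hit = protein_local_align(prot, protein_subject, db_size=db_size)
        if hit is None:
            continue
        if best is None or hit.score > best.score:
            hit.frame = frame
            # map aa coords back to forward-strand nucleotide coords
            if frame < 3:
                q_start = frame + 3 * hit.q_start
                q_end = frame + 3 * hit.q_end
            else:
                off = frame - 3
                q_end_rc = off + 3 * hit.q_end
                q_start = len(nt_query) - q_end_rc
                q_end = len(nt_query) - (off + 3 * hit.q_start)
            hit.q_start, hit.q_end = q_start, q_end
            best = hit
    return best


def kmer_set(seq: str, k: int) -> Set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def shares_kmer(a: Set[str], b: Set[str]) -> bool:
    if len(a) > len(b):
        a, b = b, a
    return any(w in b for w in a)


# ---------------------------------------------------------------------------
# Ungapped diagonal HSPs (tBLASTx-style multi-block comparison)
# ---------------------------------------------------------------------------

_AA_ORDER = "".join(_BLOSUM62.get_alphabet1())
_AA_INDEX = {c: i for i, c in enumerate(_AA_ORDER)}
_SCORE = np.asarray(_BLOSUM62.score_matrix(), dtype=np.int32)


def _encode_protein(p: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(c, _AA_INDEX["X"]) for c in p),
                       dtype=np.int32, count=len(p))


@dataclass
class UngappedHsp:
    """A maximal positive-scoring ungapped segment on one diagonal of a
    protein/protein comparison (0-based half-open aa coordinates)."""

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float


def ungapped_hsps(query_aa: str, subject_aa: str, word_size: int = 5,
                  min_score: int = 25) -> List[UngappedHsp]:
    """Find all high-scoring ungapped segments between two protein strings.

    Seeds are exact shared words of ``word_size``; each seeded diagonal is
    scanned for maximal positive-sum runs (a Ruzzo-Tompa-style sweep).
    """
    if len(query_aa) < word_size or len(subject_aa) < word_size:
        return []
    words: Dict[str, List[int]] = {}
    for i in range(len(subject_aa) - word_size + 1):
        words.setdefault(subject_aa[i:i + word_size], []).append(i)
    diagonals: Set[int] = set()
    for i in range(len(query_aa) - word_size + 1):
        for j in words.get(query_aa[i:i + word_size], ()):
            diagonals.add(i - j)
    if not diagonals:
        return []
    q = _encode_protein(query_aa)
    s = _encode_protein(subject_aa)
    out: List[UngappedHsp] = []
    for d in sorted(diagonals):
        q_off = max(d, 0)
        s_off = max(-d, 0)
        n = min(len(q) - q_off, len(s) - s_off)
        if n < word_size:
            continue
        qi = q[q_off:q_off + n]
        si = s[s_off:s_off + n]
        scores = _SCORE[qi, si]
        # x-drop segmentation: emit each segment trimmed to its maximal-
        # scoring endpoint; close it when the running sum dies or drops
        # x_drop below the segment maximum (keeps noise tails off HSP ends)
        x_drop = 15

        def emit(a, b, best):
            if best < min_score or b <= a:
                return
            # trim to the exact maximum-sum subsegment (both ends)
            run = 0
            cur_min = 0
            cur_min_idx = 0
            best_sum = 0
            sa, sb = a, b
            for k in range(b - a):
                run += int(scores[a + k])
                if run - cur_min > best_sum:
                    best_sum = run - cur_min
                    sa, sb = a + cur_min_idx, a + k + 1
                if run < cur_min:
                    cur_min = run
                    cur_min_idx = k + 1
            if best_sum < min_score or sb <= sa:
                return
            # trim ends back to a conserved core: drop terminal columns until
            # the outermost 5-column window holds a majority of identities
            # (random-sequence flanks occasionally carry net-positive score
            # and would otherwise inflate HSP spans)
            W, NEED = 10, 6
            match = qi == si
            while sb - sa >= W and int(match[sa:sa + W].sum()) < NEED:
                sa += 1
            while sb - sa >= W and int(match[sb - W:sb].sum()) < NEED:
                sb -= 1
            best_sum = int(scores[sa:sb].sum())
            if best_sum < min_score or sb <= sa:
                return
            ident = float(np.mean(qi[sa:sb] == si[sa:sb])) * 100.0
            out.append(UngappedHsp(score=int(best_sum),
                                   q_start=q_off + sa, q_end=q_off + sb,
                                   s_start=s_off + sa, s_end=s_off + sb,
                                   identity=ident))

        i = 0
        run_start = 0
        running = 0
        best = 0
        best_end = 0
        while i < n:
            running += int(scores[i])
            if running > best:
                best = running
                best_end = i + 1
            if running <= 0:
                emit(run_start, best_end, best)
                run_start = i + 1
                running = 0
                best = 0
                best_end = run_start
            elif running < best - x_drop:
                emit(run_start, best_end, best)
                i = best_end  # restart right after the maximum
                run_start = i
                running = 0
                best = 0
                best_end = run_start
                continue
            i += 1
        emit(run_start, best_end, best)
    return out
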