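"""Nei-Gojobori (1986) dN/dS estimation for codon-aligned ortholog pairs.

Sites: each of the nine single-nucleotide mutants of a codon contributes 1/3
of a site, synonymous when the encoded amino acid is unchanged; mutants that
create stop codons are excluded from the denominator. Differences between a
codon pair are resolved by averaging over all minimal mutational pathways
(1, 2 or 6 orderings for 1, 2 or 3 differing positions), excluding pathways
that pass through stop codons. Proportions are Jukes-Cantor corrected and
significance of omega != 1 comes from Fisher's exact test on the 2x2
site/substitution table.

This is a counting method standing in for ML-style (YN) estimators; a hook
(:func:`result_from_rates`) accepts externally computed (dN, dS) for users
who need parity with other tools.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from scipy import stats

NUCS = "ACGT"

_CODON_TABLE: Dict[str, str] = {}


def _build_codon_table() -> Dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table
    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


_CODON_TABLE = _build_codon_table()
SENSE_CODONS: Tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCS, repeat=3))
    if _CODON_TABLE[c] != "*"
)


def amino_acid(codon: str) -> str:
    return _CODON_TABLE[codon]


def is_stop(codon: str) -> bool:
    return _CODON_TABLE.get(codon, "?") == "*"


def _codon_site_counts(codon: str) -> Tuple[float, float]:
    """(S, N) site contributions of one codon, stop mutants excluded."""
    aa = _CODON_TABLE[codon]
    s = n = 0.0
    for pos in range(3):
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            maa = _CODON_TABLE[mutant]
            if maa == "*":
                continue  # NG86: stop-creating mutants drop out of the denominator
            if maa == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


_SITE_CACHE: Dict[str, Tuple[float, float]] = {
    c: _codon_site_counts(c) for c in SENSE_CODONS
}


@dataclass
class CodonAlignment:
    """A pair of in-frame, gap-free, equal-length nucleotide sequences."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValueError("paired sequences must have equal length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length must be a multiple of 3")
        if len(a) < 3:
            raise ValueError("alignment must contain at least one codon")
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        for seq, name in ((a, "a"), (b, "b")):
            for i in range(0, len(seq), 3):
                cod = seq[i:i + 3]
                if cod in _CODON_TABLE and is_stop(cod):
                    raise ValueError(
                        f"internal stop codon {cod} at position {i} in sequence {name}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> List[Tuple[str, str]]:
        return [(self.seq_a[i:i + 3], self.seq_b[i:i + 3])
                for i in range(0, len(self.seq_a), 3)]


@dataclass
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    p_value: float
    classification: str  # negative | neutral | positive | undefined
    n_codons: int
    saturated: bool = False
    method: str = "NG86"


def _valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(c in NUCS for c in codon)


def count_sites(codons: List[str]) -> Tuple[float, float]:
    """Total (S, N) sites over a codon list; ambiguous codons are skipped
    with a warning."""
    s_tot = n_tot = 0.0
    for cod in codons:
        if not _valid_codon(cod) or is_stop(cod):
            warnings.warn(f"skipping unusable codon {cod!r} in site counting")
            continue
        s, n = _SITE_CACHE[cod]
        s_tot += s
        n_tot += n
    return s_tot, n_tot


def _pathway_steps(c1: str, c2: str) -> Tuple[float, float]:
    """(syn, nonsyn) differences for one codon pair, averaged over minimal
    mutational pathways that avoid stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        i = diff[0]
        inter = c1
        mutant = c2
        if _CODON_TABLE[inter] == _CODON_TABLE[mutant]:
            return 1.0, 0.0
        return 0.0, 1.0
    valid: List[Tuple[float, float]] = []
    fallback: List[Tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if is_stop(nxt):
                blocked = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        fallback.append((sd, nd))
        if not blocked:
            valid.append((sd, nd))
    paths = valid if valid else fallback  # degenerate case: every path blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


_DIFF_CACHE: Dict[Tuple[str, str], Tuple[float, float]] = {}


def count_differences(pair: CodonAlignment) -> Tuple[float, float]:
    """Total (Sd, Nd) over the alignment, pathway-averaged per codon."""
    sd_tot = nd_tot = 0.0
    for c1, c2 in pair.codon_pairs():
        if not (_valid_codon(c1) and _valid_codon(c2)):
            warnings.warn(f"skipping unusable codon pair {c1!r}/{c2!r}")
            continue
        key = (c1, c2)
        if key not in _DIFF_CACHE:
            _DIFF_CACHE[key] = _pathway_steps(c1, c2)
        sd, nd = _DIFF_CACHE[key]
        sd_tot += sd
        nd_tot += nd
    return sd_tot, nd_tot


def jukes_cantor(p: float) -> Optional[float]:
    """-(3/4) ln(1 - 4p/3); None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def compute_dnds(pair: CodonAlignment, alpha: float = 0.05) -> DnDsResult:
    """Full NG86 estimate with Fisher's exact significance test.

    Sites are averaged between the two sequences. dS = 0 yields an undefined
    omega (kept as None rather than infinity). The Fisher table uses counts
    rounded half-up to integers; the rates themselves do not.
    """
    codons_a = [pair.seq_a[i:i + 3] for i in range(0, len(pair.seq_a), 3)]
    codons_b = [pair.seq_b[i:i + 3] for i in range(0, len(pair.seq_b), 3)]
    s_a, n_a = count_sites(codons_a)
    s_b, n_b = count_sites(codons_b)
    S = 0.5 * (s_a + s_b)
    N = 0.5 * (n_a + n_b)
    Sd, Nd = count_differences(pair)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    saturated = dS is None or dN is None
    if saturated:
        warnings.warn("substitution proportion >= 3/4: distance saturated")
    omega: Optional[float]
    if dS is None or dN is None or dS == 0.0:
        omega = None
    else:
        omega = dN / dS

    def _round_half_up(x: float) -> int:
        return int(math.floor(x + 0.5))

    table = [
        [_round_half_up(Sd), max(_round_half_up(S - Sd), 0)],
        [_round_half_up(Nd), max(_round_half_up(N - Nd), 0)],
    ]
    _, p_value = stats.fisher_exact(table)

    if omega is None:
        classification = "undefined"
    elif omega < 1.0 and p_value <= alpha:
        classification = "negative"
    elif omega > 1.0 and p_value <= alpha:
        classification = "positive"
    else:
        classification = "neutral"

    return DnDsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
                      omega=omega, p_value=float(p_value),
                      classification=classification,
                      n_codons=pair.n_codons, saturated=saturated)


def result_from_rates(dn: float, ds: float, n_codons: int,
                      p_value: float = float("nan"),
                      method: str = "external") -> DnDsResult:
    """Wrap externally computed (dN, dS) (e.g. from a YN-style tool) in the
    result type used downstream."""
    omega = dn / ds if ds > 0 else None
    classification = "undefined" if omega is None else (
        "negative" if omega < 1 and p_value <= 0.05 else
        "positive" if omega > 1 and p_value <= 0.05 else "neutral")
    return DnDsResult(S=float("nan"), N=float("nan"), Sd=float("nan"),
                      Nd=float("nan"), pS=float("nan"), pN=float("nan"),
                      dS=ds, dN=dn, omega=omega, p_value=p_value,
                      classification=classification, n_codons=n_codons,
                      method=method)


def best_reciprocal_pairs(genes: Dict[str, str],
                          orthologs: Dict[str, str]) -> Dict[str, Optional[str]]:
    """Pair each gene with its best reciprocal nucleotide match (optimal
    local alignment score both ways); genes without any scoring partner map
    to None."""
    from . import align as _align

    best_for_gene: Dict[str, Optional[str]] = {}
    score: Dict[Tuple[str, str], float] = {}
    for g, gseq in genes.items():
        best = None
        best_s = 0.0
        for o, oseq in orthologs.items():
            hit = _align.nucleotide_local_align(gseq, oseq)
            s = hit.score if hit else 0.0
            score[(g, o)] = s
            if s > best_s:
                best, best_s = o, s
        best_for_gene[g] = best
    out: Dict[str, Optional[str]] = {}
    for g, o in best_for_gene.items():
        if o is None:
            out[g] = None
            continue
        rival = max(genes, key=lambda gg: score[(gg, o)])
        out[g] = o if rival == g else None
    return out


def screen_orthologs(pairs: Dict[str, CodonAlignment]) -> "ScreenTable":
    """One NG86 result per named pair plus summary counts."""
    results = {name: compute_dnds(aln) for name, aln in sorted(pairs.items())}
    summary = {"negative": 0, "neutral": 0, "positive": 0, "undefined": 0}
    for r in results.values():
        summary[r.classification] += 1
    return ScreenTable(results=results, summary=summary)


@dataclass
class ScreenTable:
    results: Dict[str, DnDsResult]
    summary: Dict[str, int]

    def to_tsv(self, path) -> None:
        cols = ["pair", "n_codons", "alignment_length", "S", "N", "Sd", "Nd",
                "dS", "dN", "dN_dS", "p_value", "classification"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for name, r in self.results.items():
                fh.write("\t".join([
                    name, str(r.n_codons), str(3 * r.n_codons),
                    f"{r.S:.4f}", f"{r.N:.4f}", f"{r.Sd:.4f}", f"{r.Nd:.4f}",
                    "NA" if r.dS is None else f"{r.dS:.6f}",
                    "NA" if r.dN is None else f"{r.dN:.6f}",
                    "NA" if r.omega is None else f"{r.omega:.4f}",
                    f"{r.p_value:.3e}", r.classification,
                ]) + "\n")
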