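"""FPKM computation and pairwise differential-expression calls.

Expression of gene A in one stage library is FPKM = 1e9 * C / (N * L) with
C the uniquely aligned fragment count, N the library's total uniquely
aligned fragments and L the CDS length in bp. Stage pairs are compared with
the Audic-Claverie two-library exact test (the standard no-replicate test;
the conditional distribution of the second count given the first is negative
binomial), with Benjamini-Hochberg FDR across genes within each comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple
import warnings

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountMatrix:
    """Genes x stages fragment counts with library sizes and CDS lengths."""

    counts: pd.DataFrame            # integer counts, index = genes, columns = stages
    lengths: pd.Series              # CDS length (bp) per gene
    library_sizes: pd.Series = None  # N per stage; defaults to column sums

    def __post_init__(self):
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        self.lengths = self.lengths.reindex(counts.index)
        if (self.lengths <= 0).any() or self.lengths.isna().any():
            raise ValueError("every gene needs a positive CDS length")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = self.library_sizes.reindex(counts.columns)
            if (self.counts.sum(axis=0) > self.library_sizes).any():
                raise ValueError("per-stage counts exceed library size")

    @property
    def stages(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> List[str]:
        return list(self.counts.index)

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.insert(0, "length", self.lengths)
        df.index.name = "gene"
        with open(path, "w") as fh:
            fh.write("#library_sizes\t" + "\t".join(
                str(int(self.library_sizes[s])) for s in self.stages) + "\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        lib_sizes = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#library_sizes"):
                vals = [int(x) for x in first.strip().split("\t")[1:]]
                df = pd.read_csv(fh, sep="\t", index_col=0)
                lib_sizes = pd.Series(vals, index=[c for c in df.columns if c != "length"])
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        lengths = df.pop("length")
        return cls(counts=df, lengths=lengths, library_sizes=lib_sizes)


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """FPKM = 1e9 * C / (N * L), elementwise; stages with N = 0 give 0."""
    N = cm.library_sizes.astype(float)
    if (N == 0).any():
        warnings.warn("library with zero size: FPKM set to 0 for that stage")
    L = cm.lengths.astype(float).values[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = 1e9 * cm.counts.values / (N.values[None, :] * L)
    fpkm = np.where(np.isfinite(fpkm), fpkm, 0.0)
    return pd.DataFrame(fpkm, index=cm.counts.index, columns=cm.counts.columns)


def audic_claverie_p(c_a, c_b, n_a: float, n_b: float) -> np.ndarray:
    """Two-sided Audic-Claverie p-values for counts (c_a, c_b) from
    libraries of sizes (n_a, n_b); vectorized over genes.

    Given c_a, the null distribution of c_b is NegBin(c_a + 1,
    n_a / (n_a + n_b)); the two-sided p doubles the smaller tail (capped
    at 1), with the observed point included in both tails.
    """
    c_a = np.atleast_1d(np.asarray(c_a, dtype=np.int64))
    c_b = np.atleast_1d(np.asarray(c_b, dtype=np.int64))
    pr = n_a / (n_a + n_b)
    lower = stats.nbinom.cdf(c_b, c_a + 1, pr)
    upper = stats.nbinom.sf(c_b - 1, c_a + 1, pr)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def pairwise_dge(cm: CountMatrix, stage_a: str, stage_b: str
                 ) -> pd.DataFrame:
    """Per-gene (ratio, p) for one stage pair.

    The DGE ratio is the folded (>= 1) normalized FPKM ratio; a zero FPKM is
    replaced by a pseudo-value equal to the smallest nonzero FPKM observed in
    the two stage columns (nonzero values are used as-is).
    """
    if stage_a == stage_b:
        raise ValueError("stages must differ")
    fpkm = compute_fpkm(cm)
    fa = fpkm[stage_a].values
    fb = fpkm[stage_b].values
    nonzero = np.concatenate([fa[fa > 0], fb[fb > 0]])
    eps = nonzero.min() if nonzero.size else 1.0
    ratio = np.where(fa > 0, fa, eps) / np.where(fb > 0, fb, eps)
    ratio = np.where(ratio < 1.0, 1.0 / ratio, ratio)
    p = audic_claverie_p(cm.counts[stage_a].values, cm.counts[stage_b].values,
                         float(cm.library_sizes[stage_a]),
                         float(cm.library_sizes[stage_b]))
    return pd.DataFrame({"ratio": ratio, "p_value": p}, index=cm.counts.index)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class DgeCriteria:
    min_ratio: float = 2.0
    max_p: float = 0.001
    max_fdr: float = 0.001


def flag_dge(ratio, p, q, criteria: DgeCriteria = DgeCriteria()) -> np.ndarray:
    """True where ratio >= min_ratio AND p <= max_p AND q <= max_fdr
    (boundaries inclusive)."""
    ratio = np.asarray(ratio, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return (ratio >= criteria.min_ratio) & (p <= criteria.max_p) & (q <= criteria.max_fdr)


@dataclass
class DGEResult:
    table: pd.DataFrame  # columns: gene, stage_a, stage_b, ratio, p_value, q_value, flag
    criteria: DgeCriteria

    def flagged_genes(self) -> set:
        return set(self.table.loc[self.table["flag"], "gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_dge(cm: CountMatrix, criteria: DgeCriteria = DgeCriteria()) -> DGEResult:
    """All C(stages, 2) pairwise comparisons with per-comparison BH FDR."""
    if len(cm.stages) < 2:
        raise ValueError("need at least two stages")
    frames = []
    for a, b in itertools.combinations(cm.stages, 2):
        df = pairwise_dge(cm, a, b)
        df = df.assign(q_value=bh_fdr(df["p_value"].values),
                       stage_a=a, stage_b=b)
        df["flag"] = flag_dge(df["ratio"], df["p_value"], df["q_value"], criteria)
        df = df.reset_index(names="gene")
        frames.append(df[["gene", "stage_a", "stage_b", "ratio",
                          "p_value", "q_value", "flag"]])
    return DGEResult(table=pd.concat(frames, ignore_index=True), criteria=criteria)
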