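"""Ground-truth synthetic data for every pipeline stage.

Generates protein families evolved along known trees (with a recipient gene
either grafted into a donor clade or placed sister to the arthropods),
genomic contigs with planted GT..AG introns and spacer-deleted multi-gene
donor segments, uniform-coverage reads, codon ortholog pairs evolved at
controlled dN/dS, and stage-wise count libraries with planted fold changes.

All randomness flows from numpy Generators seeded as ``default_rng([seed,
stream])`` with fixed per-operation stream offsets, so a fixed seed yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from . import align as _align
from . import kaks as _kaks
from .dge import CountMatrix
from .filtering import HitRecord
from .io import GeneAnnotation
from .phylo import MultipleAlignment
from .trees import PhyloTree

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCS = "ACGT"

# fixed substream offsets (determinism contract)
_STREAM_FAMILIES = 1
_STREAM_CONTIGS = 2
_STREAM_READS = 3
_STREAM_PAIRS = 4
_STREAM_COUNTS = 5
_STREAM_EXTRA = 6


@dataclass
class CountModel:
    n_genes: int = 40
    mean: float = 1000.0
    n_de: int = 6
    fold_change: float = 8.0
    de_stages: Tuple[int, ...] = (2, 3)   # stages where DE genes are scaled up
    dispersion: Optional[float] = None    # None -> Poisson
    length_range: Tuple[int, int] = (500, 2000)


@dataclass
class SimulationConfig:
    seed: int = 7
    n_host_genes: int = 50
    n_planted_hgt: Dict[str, int] = field(
        default_factory=lambda: {"bacteria": 5, "fungi": 2})
    n_no_homolog: int = 8
    taxon_counts: Dict[str, int] = field(
        default_factory=lambda: {"arthropod": 4, "other_eukaryote": 4,
                                 "fungi": 10, "bacteria": 12})
    tree_depth: float = 0.5
    protein_length: int = 180
    intron_spec: List[Tuple[int, int]] = field(
        default_factory=lambda: [(1, 105), (2, 117)])  # (position slot, length)
    read_depth: float = 30.0
    read_length: int = 100
    count_model: CountModel = field(default_factory=CountModel)
    omega_targets: List[float] = field(default_factory=lambda: [0.1, 0.5, 1.0])
    t_codon: float = 0.3
    n_codons: int = 150
    pairs_per_omega: int = 2
    host_flank: int = 600
    n_host_contigs: int = 43

    def __post_init__(self):
        for name in ("n_host_genes", "n_no_homolog", "protein_length",
                     "read_length", "n_codons", "host_flank", "n_host_contigs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.taxon_counts.values()):
            raise ValueError("taxon counts must be >= 0")
        if any(w <= 0 for w in self.omega_targets):
            raise ValueError("omega targets must be > 0")
        if self.tree_depth < 0:
            raise ValueError("tree_depth must be >= 0")
        for _slot, length in self.intron_spec:
            if length < 4:
                raise ValueError("introns need >= 4 bp for GT..AG")

    def stream(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, offset])


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

@dataclass
class GeneFamily:
    name: str
    query_id: str
    is_hgt: bool
    donor_group: Optional[str]
    alignment: MultipleAlignment        # includes the query row
    tree: PhyloTree                     # the true (generating) tree
    sequences: Dict[str, str]           # leaf label -> protein


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(seq: str, t: float, rng: np.random.Generator) -> str:
    if t <= 0:
        return seq
    n_events = rng.poisson(t * len(seq))
    if n_events == 0:
        return seq
    chars = list(seq)
    for _ in range(n_events):
        pos = int(rng.integers(len(chars)))
        alternatives = AMINO_ACIDS.replace(chars[pos], "")
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _random_subtree(labels: Sequence[str], rng: np.random.Generator,
                    scale: float, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    """Random binary subtree over labels with small internal branch lengths."""
    def bl() -> float:
        return float(rng.uniform(0.3, 1.0)) * scale

    if len(labels) == 1:
        taxon = tns.get_taxon(labels[0]) or tns.new_taxon(labels[0])
        node = dendropy.Node(taxon=taxon)
        node.edge.length = bl()
        return node
    k = int(rng.integers(1, len(labels)))
    left = _random_subtree(labels[:k], rng, scale, tns)
    right = _random_subtree(labels[k:], rng, scale, tns)
    node = dendropy.Node()
    node.edge.length = bl()
    node.add_child(left)
    node.add_child(right)
    return node


def simulate_family(name: str, query_id: str, taxon_counts: Mapping[str, int],
                    rng: np.random.Generator, tree_depth: float = 0.5,
                    protein_length: int = 180,
                    donor_group: Optional[str] = None) -> GeneFamily:
    """One gene family: a group-structured tree with the query leaf grafted
    either inside the donor clade (planted HGT) or sister to the arthropods
    (vertical inheritance)."""
    counts = dict(taxon_counts)
    if donor_group is None and counts.get("arthropod", 0) == 0:
        raise ValueError("vertical families require arthropod taxa")
    if donor_group is not None and counts.get(donor_group, 0) == 0:
        raise ValueError(f"planted family requires taxa in donor group {donor_group}")

    tns = dendropy.TaxonNamespace()
    depth = tree_depth
    inner_scale = 0.15 * depth if depth > 0 else 0.0

    group_roots: Dict[str, Optional[dendropy.Node]] = {}
    labels_by_group: Dict[str, List[str]] = {}
    for group in ("arthropod", "other_eukaryote", "fungi", "bacteria"):
        n = counts.get(group, 0)
        labels = [f"{group}_sp{i + 1}" for i in range(n)]
        labels_by_group[group] = labels
        group_roots[group] = (_random_subtree(labels, rng, inner_scale, tns)
                              if labels else None)

    q_taxon = tns.new_taxon(query_id)
    query_leaf = dendropy.Node(taxon=q_taxon)
    query_leaf.edge.length = 0.3 * inner_scale if inner_scale > 0 else 0.0

    if donor_group is None:
        host = group_roots["arthropod"]
        join = dendropy.Node()
        join.edge.length = host.edge.length
        host.edge.length = 0.5 * inner_scale
        join.add_child(host)
        join.add_child(query_leaf)
        group_roots["arthropod"] = join
    else:
        donor_root = group_roots[donor_group]
        donor_leaves = [nd for nd in _subtree_leaves(donor_root)]
        target = donor_leaves[int(rng.integers(len(donor_leaves)))]
        cherry = dendropy.Node()
        cherry.edge.length = max(target.edge.length - 0.3 * inner_scale, 0.0)
        parent = target.parent_node
        if parent is not None:
            parent.remove_child(target)
            parent.add_child(cherry)
        else:
            group_roots[donor_group] = cherry
        target.edge.length = 0.3 * inner_scale if inner_scale > 0 else 0.0
        cherry.add_child(target)
        cherry.add_child(query_leaf)

    root = dendropy.Node()
    euk = dendropy.Node()
    euk.edge.length = 0.5 * depth
    for group in ("arthropod", "other_eukaryote"):
        sub = group_roots[group]
        if sub is not None:
            sub.edge.length = (sub.edge.length or 0.0) + 0.5 * depth
            euk.add_child(sub)
    if euk.child_nodes():
        root.add_child(euk)
    for group in ("fungi", "bacteria"):
        sub = group_roots[group]
        if sub is not None:
            sub.edge.length = (sub.edge.length or 0.0) + depth
            root.add_child(sub)
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = False

    # evolve sequences preorder under the Poisson model
    sequences: Dict[str, str] = {}
    root_seq = random_protein(rng, protein_length)

    def walk(node: dendropy.Node, seq: str) -> None:
        for child in node.child_nodes():
            child_seq = _mutate_protein(seq, child.edge.length or 0.0, rng)
            if child.is_leaf():
                sequences[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(root, root_seq)

    groups = {lab: g for g, labs in labels_by_group.items() for lab in labs}
    groups[query_id] = "arthropod"
    labels = sorted(sequences)
    aln = MultipleAlignment(labels=labels, rows=[sequences[l] for l in labels],
                            groups=groups)
    return GeneFamily(name=name, query_id=query_id, is_hgt=donor_group is not None,
                      donor_group=donor_group, alignment=aln,
                      tree=PhyloTree(tree=tree, groups=groups),
                      sequences=sequences)


def _subtree_leaves(node: dendropy.Node) -> List[dendropy.Node]:
    return [nd for nd in node.preorder_iter() if nd.is_leaf()]


def simulate_gene_families(config: SimulationConfig) -> List[GeneFamily]:
    """All families of a dataset: planted HGT first, then vertical hosts."""
    if not config.taxon_counts:
        raise ValueError("taxon_counts must be non-empty")
    rng = config.stream(_STREAM_FAMILIES)
    fams: List[GeneFamily] = []
    idx = 1
    for donor_group in sorted(config.n_planted_hgt):
        for k in range(config.n_planted_hgt[donor_group]):
            qid = f"hgt_{donor_group}_{k + 1:02d}"
            fams.append(simulate_family(
                f"fam{idx:04d}", qid, config.taxon_counts, rng,
                tree_depth=config.tree_depth,
                protein_length=config.protein_length, donor_group=donor_group))
            idx += 1
    for k in range(config.n_host_genes):
        qid = f"host_{k + 1:04d}"
        fams.append(simulate_family(
            f"fam{idx:04d}", qid, config.taxon_counts, rng,
            tree_depth=config.tree_depth,
            protein_length=config.protein_length, donor_group=None))
        idx += 1
    return fams


# ---------------------------------------------------------------------------
# nucleotide helpers
# ---------------------------------------------------------------------------

_CODONS_FOR_AA: Dict[str, List[str]] = {}
for codon in _kaks.SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(_kaks.amino_acid(codon), []).append(codon)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCS), size=length))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice per residue (universal code)."""
    out = []
    for aa in protein:
        options = _CODONS_FOR_AA[aa]
        out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [ _kaks.SENSE_CODONS[int(rng.integers(len(_kaks.SENSE_CODONS)))]
               for _ in range(n_codons)]
    return "".join(codons)


# ---------------------------------------------------------------------------
# contig planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedContig:
    contig_id: str
    sequence: str
    gene_id: str
    gene_start: int                       # genomic span of the gene copy
    gene_end: int
    introns: List[Tuple[int, int]]        # contig coordinates, half-open
    transcript: str


def make_intron(rng: np.random.Generator, length: int) -> str:
    if length < 4:
        raise ValueError("intron length must be >= 4")
    return "GT" + random_dna(rng, length - 4) + "AG"


def embed_gene(gene_id: str, transcript: str, rng: np.random.Generator,
               intron_lengths: Sequence[int] = (), flank: int = 600,
               contig_id: Optional[str] = None) -> PlantedContig:
    """Place a transcript on a synthetic contig with host flanks and GT..AG
    introns inserted at evenly spread, recorded positions."""
    n = len(intron_lengths)
    cuts = [len(transcript) * (i + 1) // (n + 1) for i in range(n)]
    pieces: List[str] = []
    introns: List[Tuple[int, int]] = []
    prev = 0
    offset = flank
    for cut, ilen in zip(cuts, intron_lengths):
        exon = transcript[prev:cut]
        pieces.append(exon)
        offset += len(exon)
        pieces.append(make_intron(rng, ilen))
        introns.append((offset, offset + ilen))
        offset += ilen
        prev = cut
    pieces.append(transcript[prev:])
    genomic = "".join(pieces)
    left = random_dna(rng, flank)
    right = random_dna(rng, flank)
    seq = left + genomic + right
    return PlantedContig(contig_id=contig_id or f"contig_{gene_id}",
                         sequence=seq, gene_id=gene_id,
                         gene_start=flank, gene_end=flank + len(genomic),
                         introns=introns, transcript=transcript)


@dataclass
class DonorSegment:
    contig_id: str
    contig: str
    donor_id: str
    donor_genome: str
    donor_annotations: List[GeneAnnotation]
    co_transferred: List[str]
    spacer_intervals: List[Tuple[int, int]]   # donor coordinates
    segment_start: int                        # segment span on the contig
    segment_end: int


def plant_donor_segment(rng: np.random.Generator, n_genes: int = 3,
                        gene_codons: Tuple[int, int] = (150, 240),
                        spacer_range: Tuple[int, int] = (160, 260),
                        donor_flank: int = 400, host_flank: int = 600,
                        keep_spacers: bool = False,
                        name: str = "seg") -> DonorSegment:
    """A donor genome region of ``n_genes`` CDSs separated by intergenic
    spacers, and a host contig carrying the same genes with the spacers
    deleted (or kept, for the fully-transferred transposon-like case)."""
    genes = [random_cds(rng, int(rng.integers(*gene_codons)))
             for _ in range(n_genes)]
    spacers = [random_dna(rng, int(rng.integers(*spacer_range)))
               for _ in range(n_genes - 1)]
    donor_parts = [random_dna(rng, donor_flank)]
    annotations: List[GeneAnnotation] = []
    spacer_intervals: List[Tuple[int, int]] = []
    pos = donor_flank
    donor_id = f"donor_{name}"
    for i, gene in enumerate(genes):
        annotations.append(GeneAnnotation(seq_id=donor_id, start=pos,
                                          end=pos + len(gene), strand="+",
                                          name=f"{name}_g{i + 1}"))
        donor_parts.append(gene)
        pos += len(gene)
        if i < len(spacers):
            spacer_intervals.append((pos, pos + len(spacers[i])))
            donor_parts.append(spacers[i])
            pos += len(spacers[i])
    donor_parts.append(random_dna(rng, donor_flank))
    donor_genome = "".join(donor_parts)
    if keep_spacers:
        segment = donor_genome[donor_flank:pos]
    else:
        segment = "".join(genes)
    left = random_dna(rng, host_flank)
    right = random_dna(rng, host_flank)
    contig = left + segment + right
    return DonorSegment(
        contig_id=f"contig_{name}", contig=contig, donor_id=donor_id,
        donor_genome=donor_genome, donor_annotations=annotations,
        co_transferred=[a.name for a in annotations],
        spacer_intervals=[] if keep_spacers else spacer_intervals,
        segment_start=host_flank, segment_end=host_flank + len(segment))


def plant_contig(config: SimulationConfig
                 ) -> Tuple[Dict[str, str], Dict[str, str],
                            List[GeneAnnotation], Dict]:
    """The spec'd pair of structures: (a) a single-gene contig with GT..AG
    introns per config.intron_spec, (b) a spacer-deleted 3-gene donor
    segment. Returns (contigs, donor_genome, donor_annotations, truth)."""
    rng = config.stream(_STREAM_CONTIGS)
    transcript = random_cds(rng, max(config.protein_length, 60))
    lengths = [l for _slot, l in sorted(config.intron_spec)]
    single = embed_gene("single", transcript, rng, intron_lengths=lengths,
                        flank=config.host_flank)
    seg = plant_donor_segment(rng, host_flank=config.host_flank)
    contigs = {single.contig_id: single.sequence, seg.contig_id: seg.contig}
    donor_genome = {seg.donor_id: seg.donor_genome}
    truth = {
        "introns": {single.contig_id: [list(iv) for iv in single.introns]},
        "transcripts": {single.gene_id: single.transcript},
        "co_transferred": seg.co_transferred,
        "spacer_intervals": [list(iv) for iv in seg.spacer_intervals],
        "segment_contig": seg.contig_id,
        "donor_id": seg.donor_id,
    }
    return contigs, donor_genome, seg.donor_annotations, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(contigs: Mapping[str, str], depth: float, read_length: int,
                   seed: int | np.random.Generator = 0,
                   depth_overrides: Optional[Mapping[str, float]] = None,
                   error_rate: float = 0.0) -> Dict[str, str]:
    """Uniform error-free reads at the requested mean fold-coverage.

    ``depth_overrides`` raises or lowers individual contigs (the coverage-
    bias substrate); ``error_rate`` optionally flips bases uniformly."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    shortest = min(len(s) for s in contigs.values())
    if read_length > shortest:
        raise ValueError("read_length exceeds the shortest contig")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    reads: Dict[str, str] = {}
    n = 0
    for cid in sorted(contigs):
        seq = contigs[cid]
        d = depth_overrides.get(cid, depth) if depth_overrides else depth
        n_reads = int(round(d * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, size=n_reads)
        for s in np.sort(starts):
            r = seq[s:s + read_length]
            if error_rate > 0:
                arr = list(r)
                flips = rng.random(read_length) < error_rate
                for i in np.flatnonzero(flips):
                    alternatives = NUCS.replace(arr[i], "")
                    arr[i] = alternatives[int(rng.integers(3))]
                r = "".join(arr)
            reads[f"read{n:07d}"] = r
            n += 1
    return reads


# ---------------------------------------------------------------------------
# codon ortholog pairs
# ---------------------------------------------------------------------------

@dataclass
class OrthologPair:
    pair_id: str
    seq_a: str
    seq_b: str
    omega: float


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _evolve_cds(cds: str, t: float, omega: float,
                rng: np.random.Generator) -> str:
    """GY-style acceptance thinning on an HKY (kappa = 2) proposal process.

    ``t`` is the expected number of proposed mutations per nucleotide site.
    Synonymous proposals are always accepted, nonsynonymous ones with
    probability omega, stop-creating ones never."""
    if t < 0:
        raise ValueError("t must be >= 0")
    seq = list(cds)
    L = len(seq)
    n_events = int(rng.poisson(t * L))
    for _ in range(n_events):
        pos = int(rng.integers(L))
        base = seq[pos]
        # kappa = 2: transition twice as likely as each transversion
        u = rng.random()
        if u < 0.5:
            alt = _TRANSITION[base]
        else:
            tv = [b for b in NUCS if b != base and b != _TRANSITION[base]]
            alt = tv[0] if u < 0.75 else tv[1]
        cstart = 3 * (pos // 3)
        old_codon = "".join(seq[cstart:cstart + 3])
        new_codon = old_codon[:pos - cstart] + alt + old_codon[pos - cstart + 1:]
        if _kaks.is_stop(new_codon):
            continue
        syn = _kaks.amino_acid(old_codon) == _kaks.amino_acid(new_codon)
        if syn or rng.random() < omega:
            seq[pos] = alt
    return "".join(seq)


def simulate_ortholog_pairs(omega_targets: Sequence[float], t_codon: float,
                            n_codons: int, seed: int | np.random.Generator = 0,
                            pairs_per_omega: int = 1) -> List[OrthologPair]:
    """Codon pairs diverged from a common ancestor (t/2 per lineage) with
    known omega truth."""
    if n_codons < 30:
        raise ValueError("n_codons must be >= 30")
    for w in omega_targets:
        if w <= 0:
            raise ValueError("omega targets must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out: List[OrthologPair] = []
    for w in omega_targets:
        for k in range(pairs_per_omega):
            ancestor = random_cds(rng, n_codons)
            a = _evolve_cds(ancestor, t_codon / 2.0, w, rng)
            b = _evolve_cds(ancestor, t_codon / 2.0, w, rng)
            out.append(OrthologPair(
                pair_id=f"pair_w{w:g}_{k + 1:02d}", seq_a=a, seq_b=b, omega=w))
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(model: CountModel, n_stages: int = 5,
                    seed: int | np.random.Generator = 0
                    ) -> Tuple[CountMatrix, Set[str]]:
    """Per-stage fragment counts (Poisson, or gamma-Poisson when a
    dispersion is set) with the first ``n_de`` genes carrying the configured
    fold change in the designated stages."""
    if n_stages < 2:
        raise ValueError("need at least two stages")
    if model.mean <= 0:
        raise ValueError("mean must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = [f"gene{i + 1:04d}" for i in range(model.n_genes)]
    de_genes = set(genes[:model.n_de])
    stages = [f"stage{j + 1}" for j in range(n_stages)]
    mu = np.full((model.n_genes, n_stages), float(model.mean))
    for i in range(model.n_de):
        for j in model.de_stages:
            mu[i, j] *= model.fold_change
    if model.dispersion:
        shape = 1.0 / model.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)
    lengths = rng.integers(model.length_range[0], model.length_range[1] + 1,
                           size=model.n_genes)
    cm = CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=stages),
                     lengths=pd.Series(lengths, index=genes))
    return cm, de_genes


# ---------------------------------------------------------------------------
# hit table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefProtein:
    protein_id: str     # '<species>|<family>' convention
    species: str
    group: str
    sequence: str


def derive_hit_table(segments: Mapping[str, str],
                     references: Sequence[RefProtein],
                     max_e_emit: float = 1e-3, prefilter_k: int = 5
                     ) -> Tuple[List[HitRecord], List[Tuple]]:
    """Translated local-alignment search of nucleotide segments against a
    taxonomy-labeled protein set (stands in for an external BLASTx).

    Returns (HitRecords, raw 12-column outfmt-6 rows), sorted by query then
    ascending E-value. Database size for the Karlin-Altschul E-value is the
    total reference residue count. A shared ``prefilter_k``-mer between any
    translation frame and the reference is required before alignment."""
    db_size = sum(len(r.sequence) for r in references)
    ref_kmers = [ _align.kmer_set(r.sequence, prefilter_k) for r in references ]
    hits: List[HitRecord] = []
    rows: List[Tuple] = []
    for qid, nt in segments.items():
        if len(nt) < 3:
            warnings.warn(f"segment {qid!r} shorter than one codon: skipped")
            continue
        frames = [(f, prot.replace("*", "X"))
                  for f, prot in _align.six_frame_translations(nt) if prot]
        frame_kmers = [(_align.kmer_set(prot, prefilter_k)) for _f, prot in frames]
        qhits = []
        for ref, km in zip(references, ref_kmers):
            best = None
            for (frame, prot), fkm in zip(frames, frame_kmers):
                if not _align.shares_kmer(fkm, km):
                    continue
                hit = _align.protein_local_align(prot, ref.sequence, db_size=db_size)
                if hit is None:
                    continue
                if best is None or hit.score > best.score:
                    hit.frame = frame
                    if frame < 3:
                        hit.q_start, hit.q_end = (frame + 3 * hit.q_start,
                                                  frame + 3 * hit.q_end)
                    else:
                        off = frame - 3
                        start = len(nt) - (off + 3 * hit.q_end)
                        end = len(nt) - (off + 3 * hit.q_start)
                        hit.q_start, hit.q_end = start, end
                    best = hit
            if best is None or best.e_value > max_e_emit:
                continue
            qhits.append((ref, best))
        qhits.sort(key=lambda t: (t[1].e_value, t[0].protein_id))
        for ref, hit in qhits:
            hits.append(HitRecord(
                query_id=qid, subject_id=ref.protein_id,
                taxon_group=ref.group, species_id=ref.species,
                e_value=hit.e_value, percent_identity=hit.identity,
                overlap=hit.length, bitscore=hit.bitscore))
            rows.append((qid, ref.protein_id, f"{hit.identity:.2f}",
                         hit.length, hit.mismatches, hit.gap_opens,
                         hit.q_start + 1, hit.q_end, hit.s_start + 1,
                         hit.s_end, f"{hit.e_value:.3e}",
                         f"{hit.bitscore:.1f}"))
    return hits, rows


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    families: List[GeneFamily]
    segments: Dict[str, str]
    hits: List[HitRecord]
    hit_rows: List[Tuple]
    taxmap: Dict[str, str]
    contigs: Dict[str, str]
    donor_genome: Dict[str, str]
    donor_annotations: List[GeneAnnotation]
    mito: str
    reads: Dict[str, str]
    ortholog_pairs: List[OrthologPair]
    counts: CountMatrix
    truth: Dict


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Build every pipeline input with consistent ground truth."""
    families = simulate_gene_families(config)
    rng_extra = config.stream(_STREAM_EXTRA)

    # nucleotide segments for every family query + no-homolog extras
    segments: Dict[str, str] = {}
    for fam in families:
        segments[fam.query_id] = reverse_translate(
            fam.sequences[fam.query_id], rng_extra)
    no_homolog_ids = []
    for k in range(config.n_no_homolog):
        nid = f"orphan_{k + 1:03d}"
        segments[nid] = random_dna(rng_extra, 3 * config.protein_length)
        no_homolog_ids.append(nid)

    # reference proteins: every non-query leaf of every family
    references: List[RefProtein] = []
    for fam in families:
        for label, seq in sorted(fam.sequences.items()):
            if label == fam.query_id:
                continue
            references.append(RefProtein(
                protein_id=f"{label}|{fam.name}", species=label,
                group=fam.alignment.groups[label], sequence=seq))
    taxmap = {r.species: r.group for r in references}

    hits, hit_rows = derive_hit_table(segments, references)

    # contigs: one per planted HGT gene (the first gets the configured
    # introns), host background contigs, and the multi-gene donor segment
    rng_contigs = config.stream(_STREAM_CONTIGS)
    contigs: Dict[str, str] = {}
    hgt_contig: Dict[str, str] = {}
    introns_truth: Dict[str, List[List[int]]] = {}
    transcripts: Dict[str, str] = {}
    planted = [f for f in families if f.is_hgt]
    intron_lengths = [l for _s, l in sorted(config.intron_spec)]
    for i, fam in enumerate(planted):
        lens = intron_lengths if i == 0 else ()
        pc = embed_gene(fam.query_id, segments[fam.query_id], rng_contigs,
                        intron_lengths=lens, flank=config.host_flank)
        contigs[pc.contig_id] = pc.sequence
        hgt_contig[fam.query_id] = pc.contig_id
        transcripts[fam.query_id] = pc.transcript
        if pc.introns:
            introns_truth[pc.contig_id] = [list(iv) for iv in pc.introns]
    for k in range(config.n_host_contigs):
        cid = f"contig_host_{k + 1:03d}"
        contigs[cid] = random_dna(
            rng_contigs, int(rng_contigs.integers(2000, 4001)))
    seg = plant_donor_segment(rng_contigs, host_flank=config.host_flank)
    contigs[seg.contig_id] = seg.contig

    mito = random_dna(rng_contigs, 3000)

    reads = simulate_reads(contigs, config.read_depth, config.read_length,
                           seed=config.stream(_STREAM_READS))

    pairs = simulate_ortholog_pairs(
        config.omega_targets, config.t_codon, config.n_codons,
        seed=config.stream(_STREAM_PAIRS),
        pairs_per_omega=config.pairs_per_omega)

    counts, de_genes = simulate_counts(config.count_model,
                                       seed=config.stream(_STREAM_COUNTS))

    truth = {
        "planted_hgt": {f.query_id: f.donor_group for f in planted},
        "host_genes": [f.query_id for f in families if not f.is_hgt],
        "no_homolog": no_homolog_ids,
        "hgt_contig": hgt_contig,
        "introns": introns_truth,
        "co_transferred": seg.co_transferred,
        "spacer_intervals": [list(iv) for iv in seg.spacer_intervals],
        "segment_contig": seg.contig_id,
        "donor_id": seg.donor_id,
        "omega": {p.pair_id: p.omega for p in pairs},
        "de_genes": sorted(de_genes),
    }
    _check_truth(truth, segments, contigs)

    return SyntheticDataset(
        config=config, families=families, segments=segments, hits=hits,
        hit_rows=hit_rows, taxmap=taxmap, contigs=contigs,
        donor_genome={seg.donor_id: seg.donor_genome},
        donor_annotations=seg.donor_annotations, mito=mito, reads=reads,
        ortholog_pairs=pairs, counts=counts, truth=truth)


def _check_truth(truth: Dict, segments: Mapping[str, str],
                 contigs: Mapping[str, str]) -> None:
    for qid in truth["planted_hgt"]:
        if qid not in segments:
            raise AssertionError(f"planted id {qid} missing from segments")
    for cid, ivs in truth["introns"].items():
        for a, b in ivs:
            if not (0 <= a < b <= len(contigs[cid])):
                raise AssertionError(f"intron [{a},{b}) outside contig {cid}")


def write_dataset(ds: SyntheticDataset, outdir: str | os.PathLike) -> None:
    """Serialize a dataset to plain-text files (FASTA/FASTQ/GFF3/TSV/JSON)."""
    from . import io as hio
    from .filtering import write_hit_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_fasta(out / "segments.fasta", ds.segments)
    write_hit_table(out / "hits.tsv", ds.hit_rows)
    hio.write_taxmap(out / "taxmap.tsv", ds.taxmap)
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for fam in ds.families:
        hio.write_fasta(aln_dir / f"{fam.query_id}.afa",
                        dict(zip(fam.alignment.labels, fam.alignment.rows)))
    hio.write_fasta(out / "contigs.fasta", ds.contigs)
    hio.write_fasta(out / "donor_genome.fasta", ds.donor_genome)
    hio.write_gff3(out / "donor_genome.gff3", ds.donor_annotations)
    hio.write_fasta(out / "mito.fasta", {"mito": ds.mito})
    hio.write_fastq(out / "reads.fastq", ds.reads)
    pair_seqs: Dict[str, str] = {}
    for p in ds.ortholog_pairs:
        pair_seqs[f"{p.pair_id}|A"] = p.seq_a
        pair_seqs[f"{p.pair_id}|B"] = p.seq_b
    hio.write_fasta(out / "ortholog_pairs.fasta", pair_seqs)
    ds.counts.to_tsv(out / "counts.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
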