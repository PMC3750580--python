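# hgtscan

A toolkit for detecting and characterizing horizontally transferred genes
(HGT) in a eukaryotic genome from homology evidence, with a fully synthetic,
ground-truthed data generator for testing every stage.

The pipeline mirrors a classic genome-wide HGT survey:

1. **Homology filter cascade** (`hgtscan.filtering`) — BLAST-tabular hits
   are reduced in three steps: E-value/identity/overlap thresholds
   (defaults `1e-20 / 25% / 25 aa`), exclusion of queries whose best
   similarity is to the recipient's own group (arthropods), and a floor of
   10 distinct homolog species.
2. **Phylogenetic classification** (`hgtscan.phylo`) — Gblocks-flavored
   conserved-block trimming, Poisson-corrected distances, Saitou–Nei
   neighbor joining with column-bootstrap supports, and a donor-clade
   nesting classifier (query nested in a supported clade of one donor group
   with ≥ 3 distinct donor species basal to it). External newick trees
   (e.g. ML trees) can be fed directly via `hgtscan.trees.parse_newick`.
3. **Genome verification** (`hgtscan.verify`) — strict local-alignment
   mapping of candidates onto assembly contigs (`E ≤ 1e-40`, identity
   ≥ 90%), a ≤ 2-mismatch read aligner with per-contig depth profiles, a
   Welch two-sample coverage-bias test against randomly sampled background
   contigs, and a mitochondrial (NUMT) screen.
4. **Structure analysis** (`hgtscan.structure`) — six-frame translated
   synteny blocks between contigs and donor genomes (`E ≤ 1e-10`),
   co-transfer summaries with missing-intergenic calls, spliced-match
   intron detection (GT..AG), and a same-strand/gap operon heuristic.
5. **Selection screen** (`hgtscan.kaks`) — Nei–Gojobori (1986) dN/dS with
   pathway averaging, Jukes–Cantor correction and Fisher's exact
   significance test.
6. **Expression profiling** (`hgtscan.dge`) — FPKM (`1e9·C/(N·L)`), the
   Audic–Claverie two-library exact test over all stage pairs, BH FDR, and
   flagging at ratio ≥ 2, p ≤ 0.001, FDR ≤ 0.001.

`hgtscan.synthetic` generates every input with known truth: gene families
evolved along recorded trees with the recipient grafted into a donor clade,
contigs with planted introns and spacer-deleted multi-gene transfers,
uniform-coverage reads, codon pairs evolved at controlled ω, and count
matrices with planted fold changes.

## CLI

```bash
hgtscan demo --seed 7 --out demo_data          # write the synthetic demo
hgtscan run-all --data demo_data --out results # full pipeline
hgtscan filter --hits H.tsv --taxmap T.tsv --segments S.fasta
hgtscan phylo --aln A.afa --taxmap T.tsv --query seg1 --bootstrap 1000
hgtscan verify --candidates c.fasta --contigs g.fasta --reads r.fastq
hgtscan structure --contig c.fasta --donor d.fasta --donor-gff d.gff3
hgtscan kaks --pairs pairs.fasta
hgtscan dge --counts counts.tsv
```

`run-all` writes per-stage TSV reports, a `final_calls.txt` (candidates
passing filter → phylogeny → contig mapping → coverage consistency) and a
`manifest.json` with the attrition table and output checksums; reruns with
the same configuration are byte-identical.

## Layout

```
src/hgtscan/
  synthetic.py   ground-truth data generator
  filtering.py   homology filter cascade
  phylo.py       trimming, distances, NJ, bootstrap, HGT classifier
  trees.py       tree plumbing (NJ core, splits, rooting, newick I/O)
  verify.py      contig mapping, read coverage, bias test, mito screen
  structure.py   synteny, co-transfer, introns, operons
  kaks.py        NG86 dN/dS + Fisher test
  dge.py         FPKM, exact test, BH FDR
  align.py       local alignment + Karlin–Altschul statistics
  pipeline.py    orchestration, manifest, demo
  cli.py         click CLI
```
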