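"""Three-step homology filter cascade reducing gene segments to HGT
candidates.

Stage 1 keeps hits passing E-value / identity / overlap thresholds
(boundaries inclusive); segments left without hits are binned as
``no_homolog``. Stage 2 drops queries whose best similarity (bitscore) is an
arthropod hit, or whose hits are arthropod-only; ties retain the query.
Stage 3 drops queries with fewer than ``min_homologs`` distinct subject
species among the retained hits.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import io as hio

TAXON_GROUPS = ("arthropod", "other_metazoan", "other_eukaryote",
                "fungi", "plant", "bacteria", "virus")

RECIPIENT_GROUP = "arthropod"


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    taxon_group: str
    species_id: str
    e_value: float
    percent_identity: float
    overlap: int          # aligned length, aa residues
    bitscore: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {self.taxon_group!r}")


@dataclass(frozen=True)
class FilterThresholds:
    max_e: float = 1e-20
    min_identity: float = 25.0
    min_overlap: int = 25
    min_homologs: int = 10

    def __post_init__(self):
        if self.max_e <= 0:
            raise ValueError("max_e must be > 0")
        if self.min_homologs < 2:
            raise ValueError("min_homologs must be >= 2")


VERDICTS = ("no_homolog", "arthropod_preferred", "too_few_homologs", "candidate")


@dataclass
class FilterReport:
    verdicts: Dict[str, str]                  # query id -> verdict
    stage_counts: "OrderedDict[str, int]"     # stage -> eliminated count
    retained: List[str]                       # candidate ids, input order
    n_input: int

    def check_conservation(self) -> bool:
        return sum(self.stage_counts.values()) + len(self.retained) == self.n_input

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#stage_counts\t" + "\t".join(
                f"{k}={v}" for k, v in self.stage_counts.items())
                + f"\tcandidate={len(self.retained)}\n")
            fh.write("query_id\tverdict\n")
            for qid, v in self.verdicts.items():
                fh.write(f"{qid}\t{v}\n")


def threshold_filter(hits: Iterable[HitRecord],
                     thresholds: FilterThresholds = FilterThresholds()
                     ) -> List[HitRecord]:
    """Keep hits with e_value <= max_e, identity >= min_identity and
    overlap >= min_overlap (all inclusive)."""
    return [h for h in hits
            if h.e_value <= thresholds.max_e
            and h.percent_identity >= thresholds.min_identity
            and h.overlap >= thresholds.min_overlap]


def group_by_query(hits: Iterable[HitRecord]) -> "OrderedDict[str, List[HitRecord]]":
    out: "OrderedDict[str, List[HitRecord]]" = OrderedDict()
    for h in hits:
        out.setdefault(h.query_id, []).append(h)
    return out


def classify_no_homolog(segment_ids: Sequence[str],
                        retained_hits: Iterable[HitRecord]) -> List[str]:
    """Segments with zero retained hits."""
    with_hits = {h.query_id for h in retained_hits}
    return [s for s in segment_ids if s not in with_hits]


def ingroup_preference_filter(query_hits: Sequence[HitRecord],
                              recipient_group: str = RECIPIENT_GROUP) -> str:
    """'arthropod_preferred' when all hits are from the recipient group or
    the best recipient bitscore strictly exceeds the best non-recipient one;
    'candidate' otherwise (ties retain)."""
    if not query_hits:
        raise ValueError("ingroup filter requires at least one retained hit")
    ingroup = [h.bitscore for h in query_hits if h.taxon_group == recipient_group]
    outgroup = [h.bitscore for h in query_hits if h.taxon_group != recipient_group]
    if not outgroup:
        return "arthropod_preferred"
    if ingroup and max(ingroup) > max(outgroup):
        return "arthropod_preferred"
    return "candidate"


def homolog_count_filter(query_hits: Sequence[HitRecord],
                         min_homologs: int = 10) -> str:
    """'candidate' when the retained hits span >= min_homologs distinct
    subject species, else 'too_few_homologs'."""
    species = {h.species_id for h in query_hits}
    return "candidate" if len(species) >= min_homologs else "too_few_homologs"


def run_cascade(segment_ids: Sequence[str], hits: Iterable[HitRecord],
                thresholds: FilterThresholds = FilterThresholds()) -> FilterReport:
    """Apply the three filters in order and account for every segment."""
    segment_ids = list(segment_ids)
    if len(set(segment_ids)) != len(segment_ids):
        raise ValueError("duplicate query ids in segment list")
    retained_hits = threshold_filter(hits, thresholds)
    by_query = group_by_query(retained_hits)

    verdicts: Dict[str, str] = {}
    stage_counts: "OrderedDict[str, int]" = OrderedDict(
        (("no_homolog", 0), ("arthropod_preferred", 0), ("too_few_homologs", 0)))
    retained: List[str] = []

    for qid in segment_ids:
        qhits = by_query.get(qid)
        if not qhits:
            verdicts[qid] = "no_homolog"
        elif ingroup_preference_filter(qhits) == "arthropod_preferred":
            verdicts[qid] = "arthropod_preferred"
        elif homolog_count_filter(qhits, thresholds.min_homologs) == "too_few_homologs":
            verdicts[qid] = "too_few_homologs"
        else:
            verdicts[qid] = "candidate"
            retained.append(qid)
        if verdicts[qid] != "candidate":
            stage_counts[verdicts[qid]] += 1

    report = FilterReport(verdicts=verdicts, stage_counts=stage_counts,
                          retained=retained, n_input=len(segment_ids))
    assert report.check_conservation()
    return report


# ---------------------------------------------------------------------------
# BLAST 12-column tabular I/O
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = ("qseqid sseqid pident length mismatch gapopen "
                   "qstart qend sstart send evalue bitscore").split()


def read_hit_table(path, taxmap: Mapping[str, str]) -> List[HitRecord]:
    """Parse BLAST outfmt-6 rows into HitRecords; subject species resolve
    via the '<species>|<protein>' id convention and the taxon-group map."""
    out: List[HitRecord] = []
    for row in hio.read_tsv_rows(path):
        if len(row) < 12:
            raise ValueError(f"expected 12 columns, got {len(row)}: {row}")
        qid, sid = row[0], row[1]
        species = hio.species_of_subject(sid)
        if species not in taxmap:
            raise KeyError(f"species {species!r} missing from taxon map")
        out.append(HitRecord(
            query_id=qid, subject_id=sid, taxon_group=taxmap[species],
            species_id=species, e_value=float(row[10]),
            percent_identity=float(row[2]), overlap=int(row[3]),
            bitscore=float(row[11])))
    return out


def write_hit_table(path, rows: Iterable[Tuple]) -> None:
    """Write raw outfmt-6 rows (12-tuples, already formatted or numeric)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
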