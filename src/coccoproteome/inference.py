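"""Peptide-to-database mapping and homologous protein group (HPG) clustering.

Identifications made against several sequence databases (draft-genome
protein models, curated protein entries, six-frame-translated ESTs) are
redundant: the same protein surfaces under different identifiers.  This
module maps tryptic peptides onto the databases by exact substring search,
applies the two-distinct-peptide rule, scores all pairwise similarities with
Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1) and an
ungapped Karlin-Altschul e-value, and single-linkage clusters identifications
whose similarity passes BOTH an e-value and a percent-identity threshold
into HPGs.

ESTs are single-pass cDNA reads with unknown strand and frame, so they are
searched in all six reading frames; stop codons break the translated
sequence into segments for peptide matching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from pyteomics import parser as _pyt_parser

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "IdentifiedProtein",
    "AlignmentResult",
    "HPG",
    "six_frame_translate",
    "tryptic_digest",
    "map_peptides",
    "local_align",
    "cluster_hpgs",
]

# ungapped Karlin-Altschul parameters for BLOSUM62 (Altschul & Gish 1996)
KA_LAMBDA = 0.3176
KA_K = 0.134

E_THRESHOLD = 1.00e-10
MIN_IDENTITY = 5.0  # percent, exclusive


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    alphabet: str = "amino-acid"  # or "nucleotide"
    source_db: str = "uniprot"  # genome | uniprot | est

    def __post_init__(self):
        if not self.residues:
            raise ValueError("residues must be non-empty")


@dataclass(frozen=True)
class IdentifiedProtein:
    id: str
    source_db: str
    matched_peptides: frozenset
    shared_peptides: frozenset = frozenset()

    @property
    def n_distinct_peptides(self) -> int:
        return len(self.matched_peptides)


@dataclass(frozen=True)
class AlignmentResult:
    score: float  # raw Smith-Waterman score
    identity: float  # % identical positions over aligned columns
    e_value: float


@dataclass(frozen=True)
class HPG:
    hpg_id: str
    members: tuple  # member identification ids
    source_dbs: tuple
    representative: str
    n_peptides: dict = field(default_factory=dict)


def six_frame_translate(record: SequenceRecord) -> list[str]:
    """All six conceptual translations of a nucleotide record.

    Frames 0-2 read the forward strand with offsets 0/1/2; frames 3-5 read
    the reverse complement the same way.  Stop codons are rendered as ``*``
    (segment breaks for downstream peptide matching); trailing partial
    codons are dropped.
    """
    if record.alphabet != "nucleotide":
        raise ValueError(f"{record.id}: six-frame translation needs a nucleotide record")
    nt = record.residues.upper().replace("U", "T")
    frames = []
    for strand in (nt, str(Seq(nt).reverse_complement())):
        for off in range(3):
            sub = strand[off : off + 3 * ((len(strand) - off) // 3)]
            frames.append(str(Seq(sub).translate()) if sub else "")
    return frames


def tryptic_digest(aa: str, missed_cleavages: int = 0, min_length: int = 6) -> list[str]:
    """In-silico trypsin digest: cleave after K/R except before P.

    Emits peptides with 0..``missed_cleavages`` internal missed sites, at
    least ``min_length`` residues long, in order of first occurrence.
    """
    peps = _pyt_parser.cleave(
        aa, _pyt_parser.expasy_rules["trypsin"], missed_cleavages=missed_cleavages
    )
    kept = [p for p in peps if len(p) >= min_length and "*" not in p]
    return sorted(kept, key=lambda p: (aa.find(p), p))


def map_peptides(
    peptides,
    db: list[SequenceRecord],
    min_peptides: int = 2,
    merge_il: bool = False,
) -> list[IdentifiedProtein]:
    """Exact-substring peptide assignment with the two-peptide rule.

    Nucleotide records are six-frame translated first and a peptide matches
    if it occurs within any stop-free segment of any frame.  Identifications
    with fewer than ``min_peptides`` distinct peptides are dropped (logged);
    peptides matching several records are credited to each and flagged as
    shared.  ``merge_il`` treats I and L as equivalent (isobaric residues).
    """

    def canon(s: str) -> str:
        return s.replace("L", "I") if merge_il else s

    pep_list = sorted(set(peptides))
    hits: dict[str, set] = {}
    owners: dict[str, set] = {p: set() for p in pep_list}
    for rec in db:
        if rec.alphabet == "nucleotide":
            segments = [seg for fr in six_frame_translate(rec) for seg in fr.split("*") if seg]
        else:
            segments = [rec.residues]
        segments = [canon(s) for s in segments]
        for pep in pep_list:
            cp = canon(pep)
            if any(cp in seg for seg in segments):
                hits.setdefault(rec.id, set()).add(pep)
                owners[pep].add(rec.id)

    shared = {p for p, own in owners.items() if len(own) > 1}
    out = []
    n_dropped = 0
    by_id = {r.id: r for r in db}
    for rec_id in sorted(hits):
        peps = hits[rec_id]
        if len(peps) < min_peptides:
            n_dropped += 1
            logger.debug("%s: %d distinct peptide(s) < %d, dropped", rec_id, len(peps), min_peptides)
            continue
        out.append(
            IdentifiedProtein(
                id=rec_id,
                source_db=by_id[rec_id].source_db,
                matched_peptides=frozenset(peps),
                shared_peptides=frozenset(peps & shared),
            )
        )
    if n_dropped:
        logger.info("dropped %d identifications with < %d distinct peptides", n_dropped, min_peptides)
    return out


_aligner = None


def _get_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def local_align(a: str, b: str, search_space: float | None = None) -> AlignmentResult:
    """Smith-Waterman local alignment with a Karlin-Altschul e-value.

    ``search_space`` is the effective database residue count n used in
    E = K * m * n * exp(-lambda * S); it defaults to len(b) (a one-sequence
    database).  Identity is percent identical positions over all aligned
    columns of the best local alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _get_aligner()
    aln = aligner.align(a, b)
    best = aln[0]
    score = float(best.score)
    ident = matched = 0
    for (a0, a1), (b0, b1) in zip(*best.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            matched += 1
            if a[i] == b[j]:
                ident += 1
    # count gap columns inside the local alignment span
    blocks_a, blocks_b = best.aligned
    span = 0
    if matched:
        span = (blocks_a[-1][1] - blocks_a[0][0]) + (blocks_b[-1][1] - blocks_b[0][0]) - matched
    identity = 100.0 * ident / span if span else 0.0
    n = search_space if search_space is not None else float(len(b))
    e_value = KA_K * len(a) * n * math.exp(-KA_LAMBDA * score)
    return AlignmentResult(score=score, identity=identity, e_value=e_value)


def cluster_hpgs(
    identifications: list[IdentifiedProtein],
    sequences: dict,
    e_threshold: float = E_THRESHOLD,
    min_identity: float = MIN_IDENTITY,
) -> list[HPG]:
    """Single-linkage clustering of identifications into HPGs.

    Two identifications are linked when their pairwise local alignment has
    e-value <= ``e_threshold`` AND identity strictly above ``min_identity``
    percent.  The e-value search space is the summed residue count of all
    identification sequences.  Output is a partition, deterministically
    ordered by representative id; the representative is the longest member
    sequence (ties broken lexicographically by id).
    """
    ids = sorted(identifications, key=lambda p: p.id)
    missing = [p.id for p in ids if p.id not in sequences]
    if missing:
        raise ValueError(f"no sequence for identifications: {missing}")
    total_residues = float(sum(len(sequences[p.id]) for p in ids))

    parent = {p.id: p.id for p in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            res = local_align(
                sequences[ids[i].id], sequences[ids[j].id], search_space=total_residues
            )
            if res.e_value <= e_threshold and res.identity > min_identity:
                union(ids[i].id, ids[j].id)

    clusters: dict[str, list[IdentifiedProtein]] = {}
    for p in ids:
        clusters.setdefault(find(p.id), []).append(p)

    hpgs = []
    for members in clusters.values():
        rep = min(members, key=lambda p: (-len(sequences[p.id]), p.id))
        hpgs.append(
            HPG(
                hpg_id="",
                members=tuple(sorted(p.id for p in members)),
                source_dbs=tuple(sorted({p.source_db for p in members})),
                representative=rep.id,
                n_peptides={p.id: p.n_distinct_peptides for p in members},
            )
        )
    hpgs.sort(key=lambda h: h.representative)
    return [
        HPG(
            hpg_id=f"HPG{i + 1:04d}",
            members=h.members,
            source_dbs=h.source_dbs,
            representative=h.representative,
            n_peptides=h.n_peptides,
        )
        for i, h in enumerate(hpgs)
    ]
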