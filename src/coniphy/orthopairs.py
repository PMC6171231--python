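"""Redundancy collapsing and cross-species orthologue pairing.

Within a taxon, transcripts with global identity strictly above a
threshold (default 0.95) are merged into single-linkage classes and
each class is represented by its longest member (the "unigene").
Between two taxa, putative orthologues are transcript pairs whose
global alignment identity reaches a second threshold (default 0.90),
reduced to a one-to-one best-hit matching.

Identity is defined on an end-to-end global alignment (match +1,
mismatch -1, gap -2) as matching columns divided by total alignment
columns; gapped columns count as mismatches and ``N`` never matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import Align, SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptSet",
    "OrthologuePair",
    "global_identity",
    "global_alignment",
    "collapse_redundant",
    "pair_orthologues",
    "read_fasta_set",
    "write_pairs_tsv",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class TranscriptSet:
    """All transcripts of one taxon."""

    taxon: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate transcript ids in taxon {self.taxon}")
        for rec_id, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for {rec_id}")
            if not set(seq) <= _VALID:
                bad = sorted(set(seq) - _VALID)
                raise ValueError(f"invalid characters {bad} in {rec_id}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class OrthologuePair:
    """Two transcripts from different taxa linked by global identity."""

    taxon_a: str
    id_a: str
    taxon_b: str
    id_b: str
    identity: float
    aligned_a: str
    aligned_b: str

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise ValueError("orthologue pair must span two taxa")

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_a)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def global_alignment(seq_a: str, seq_b: str) -> tuple[float, str, str]:
    """(identity, gapped_a, gapped_b) for the optimal global alignment."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    aln = _aligner().align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(ga, gb) if x == y and x != "-" and x != "N"
    )
    return matches / len(ga), ga, gb


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of matching columns in the global alignment, in [0, 1]."""
    return global_alignment(seq_a, seq_b)[0]


# ---------------------------------------------------------------------------
# optional k-mer prefilter
# ---------------------------------------------------------------------------

def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _prefilter_pass(seq_a: str, seq_b: str, threshold: float, k: int = 8) -> bool:
    """True if the pair could still reach ``threshold`` identity.

    Uses two sound upper bounds: identity <= min(len)/max(len), and a
    shared-k-mer bound — an alignment with m matching columns among C
    has at least ``m - (k-1) * (mismatch+gap columns + 1)`` shared k-mer
    occurrences, so too few shared k-mers rule the pair out.
    """
    la, lb = len(seq_a), len(seq_b)
    if min(la, lb) / max(la, lb) < threshold:
        return False
    shared = 0
    ca, cb = _kmer_counts(seq_a, k), _kmer_counts(seq_b, k)
    for kmer, n in ca.items():
        if kmer in cb:
            shared += min(n, cb[kmer])
    c_min = max(la, lb)  # alignment has at least this many columns
    needed = threshold * c_min - (k - 1) * ((1 - threshold) * c_min + 1)
    return shared >= needed


# ---------------------------------------------------------------------------
# redundancy collapsing (single linkage, longest representative)
# ---------------------------------------------------------------------------

def collapse_redundant(transcripts: TranscriptSet, threshold: float = 0.95) -> TranscriptSet:
    """Merge transcripts at identity strictly above ``threshold``.

    Single-linkage classes; each class keeps exactly its longest member
    (ties broken by lexicographically smallest id).  Idempotent.
    """
    n = len(transcripts.records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if global_identity(transcripts.records[i][1], transcripts.records[j][1]) > threshold:
                parent[find(j)] = find(i)

    classes: dict[int, list[int]] = {}
    for i in range(n):
        classes.setdefault(find(i), []).append(i)
    survivors = []
    for members in classes.values():
        best = min(members, key=lambda i: (-len(transcripts.records[i][1]), transcripts.records[i][0]))
        survivors.append(best)
    survivors.sort()
    logger.info(
        "collapse_redundant[%s]: %d transcripts -> %d unigenes",
        transcripts.taxon, n, len(survivors),
    )
    return TranscriptSet(
        taxon=transcripts.taxon,
        records=tuple(transcripts.records[i] for i in survivors),
    )


# ---------------------------------------------------------------------------
# cross-taxon pairing
# ---------------------------------------------------------------------------

def pair_orthologues(
    set_a: TranscriptSet,
    set_b: TranscriptSet,
    threshold: float = 0.90,
    prefilter: bool = False,
) -> list[OrthologuePair]:
    """One-to-one best-hit orthologue pairs at identity >= ``threshold``.

    All cross-taxon alignments reaching the threshold are ranked by
    identity, then alignment length, then ids, and greedily matched so
    each transcript appears in at most one pair.  The optional k-mer
    prefilter skips alignments that provably cannot reach the
    threshold; it does not change the result.
    """
    if set_a.taxon == set_b.taxon:
        raise ValueError("orthologue pairing requires two distinct taxa")
    if len(set_a) == 0 or len(set_b) == 0:
        logger.warning(
            "pair_orthologues(%s, %s): empty transcript set", set_a.taxon, set_b.taxon
        )
        return []
    candidates = []
    for id_a, seq_a in set_a.records:
        for id_b, seq_b in set_b.records:
            if prefilter and not _prefilter_pass(seq_a, seq_b, threshold):
                continue
            identity, ga, gb = global_alignment(seq_a, seq_b)
            if identity >= threshold:
                candidates.append((identity, len(ga), id_a, id_b, ga, gb))
    # best-hit greedy matching: identity desc, aligned length desc, ids
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for identity, _, id_a, id_b, ga, gb in candidates:
        if id_a in used_a or id_b in used_b:
            continue
        used_a.add(id_a)
        used_b.add(id_b)
        pairs.append(
            OrthologuePair(
                taxon_a=set_a.taxon, id_a=id_a,
                taxon_b=set_b.taxon, id_b=id_b,
                identity=identity, aligned_a=ga, aligned_b=gb,
            )
        )
    logger.info(
        "pair_orthologues(%s, %s): %d pairs at identity >= %.2f",
        set_a.taxon, set_b.taxon, len(pairs), threshold,
    )
    return pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta_set(path: Path, taxon: Optional[str] = None) -> TranscriptSet:
    path = Path(path)
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    return TranscriptSet(taxon=taxon or path.stem, records=records)


def write_pairs_tsv(pairs: Iterable[OrthologuePair], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_a\tid_a\ttaxon_b\tid_b\tidentity\taligned_length\n")
        for p in pairs:
            fh.write(
                f"{p.taxon_a}\t{p.id_a}\t{p.taxon_b}\t{p.id_b}\t"
                f"{p.identity:.6f}\t{p.alignment_length}\n"
            )
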