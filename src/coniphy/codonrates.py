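"""Ka/Ks estimation on codon alignments by Nei–Gojobori (NG86) counting.

The estimator classifies every codon position into fractional synonymous
and nonsynonymous *sites* (how many of the possible single-nucleotide
changes preserve the amino acid), counts synonymous and nonsynonymous
*differences* between aligned codons by averaging over all minimal
mutational pathways, and corrects the resulting proportions for multiple
hits with the Jukes–Cantor formula.  Changes that would create a stop
codon are excluded both from site denominators and from pathways, so
S + N is exactly three times the number of counted codons.

Reading frames for unannotated transcripts are inferred with a
longest-ORF rule over all six frames, and pairwise codon alignments are
built by aligning the translated proteins and back-translating.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "CodingSequence",
    "CodonAlignment",
    "RateEstimate",
    "SaturationError",
    "infer_frame",
    "codon_align",
    "ng86",
    "jc_correct",
    "BASES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "GENETIC_CODE",
]

BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = frozenset(_table.stop_codons)
GENETIC_CODE = dict(_table.forward_table)  # codon -> amino acid, sense only
SENSE_CODONS = tuple(sorted(GENETIC_CODE))


class SaturationError(ValueError):
    """Observed difference proportion is beyond the Jukes–Cantor domain."""


# ---------------------------------------------------------------------------
# site and difference counting primitives
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _site_fractions(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (summing to 3) for one codon.

    At each of the three positions the synonymous fraction is the share
    of single-nucleotide changes, among those not creating a stop codon,
    that leave the amino acid unchanged.
    """
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_ok = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_ok += 1
            if GENETIC_CODE[alt] == aa:
                n_syn += 1
        # n_ok >= 1 always: at most two of the three alternatives are stops
        syn += n_syn / n_ok
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _path_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two sense codons.

    Averages over every minimal mutational pathway that does not pass
    through a stop codon.  For sense endpoints at least one stop-free
    pathway always exists (the three stop codons of the standard code
    cannot cover all orderings).
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    syn_tot = 0.0
    nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diffs):
        cur = codon_a
        syn = 0
        nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:  # unreachable for sense endpoints; guard anyway
        raise ValueError(f"no stop-free pathway between {codon_a} and {codon_b}")
    return syn_tot / n_paths, nonsyn_tot / n_paths


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Raises :class:`SaturationError` for p >= 3/4 where the correction is
    undefined.
    """
    if p < 0:
        raise ValueError(f"proportion must be nonnegative, got {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# reading-frame inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingSequence:
    """A transcript with an inferred reading frame.

    ``coding`` is the in-frame, stop-free nucleotide stretch (on the
    reported strand), ``protein`` its translation.
    """

    id: str
    nucleotides: str
    frame_offset: int  # 0..2, on the reported strand
    strand: str  # '+' or '-'
    coding: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if "*" in self.protein:
            raise ValueError("coding region contains an internal stop")


def _longest_orf_in_frame(seq: str, offset: int) -> tuple[int, int]:
    """(start, n_codons) of the longest stop-free codon run in one frame."""
    best_start, best_len = offset, 0
    start, run = offset, 0
    i = offset
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS or any(b not in BASES for b in codon):
            if run > best_len:
                best_start, best_len = start, run
            start, run = i + 3, 0
        else:
            run += 1
        i += 3
    if run > best_len:
        best_start, best_len = start, run
    return best_start, best_len


def infer_frame(seq: str, id: str = "", min_codons: int = 50) -> Optional[CodingSequence]:
    """Locate the longest stop-free open reading frame over all six frames.

    Returns ``None`` (a non-coding signal) when no frame carries a
    stop-free run of at least ``min_codons`` codons.  Ties are broken
    deterministically: forward strand first, then lower frame offset,
    then earlier start.
    """
    seq = seq.upper()
    if len(seq) < 3 * min_codons:
        return None
    candidates = []  # (-n_codons, strand_rank, offset, start, strand, oriented)
    for strand, oriented in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for offset in range(3):
            start, n = _longest_orf_in_frame(oriented, offset)
            if n >= min_codons:
                candidates.append((-n, 0 if strand == "+" else 1, offset, start, strand, oriented))
    if not candidates:
        return None
    neg_n, _, offset, start, strand, oriented = min(candidates)
    coding = oriented[start : start - 3 * neg_n]
    protein = str(Seq(coding).translate())
    return CodingSequence(
        id=id,
        nucleotides=seq,
        frame_offset=offset,
        strand=strand,
        coding=coding,
        protein=protein,
    )


# ---------------------------------------------------------------------------
# protein-guided codon alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns for one transcript pair.

    Each column is ``(codon_a, codon_b)`` with ``None`` marking a gap;
    gapped columns are retained for inspection but never counted.
    """

    id_a: str
    id_b: str
    columns: tuple[tuple[Optional[str], Optional[str]], ...]

    @property
    def ungapped(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b in self.columns
            if a is not None and b is not None
        ]


def _protein_aligner(matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def codon_align(a: CodingSequence, b: CodingSequence, matrix: str = "BLOSUM62") -> Optional[CodonAlignment]:
    """Globally align two proteins and back-translate to codon columns.

    Returns ``None`` (an "unalignable" signal) if no gap-free codon
    column remains.
    """
    aln = _protein_aligner(matrix).align(a.protein, b.protein)[0]
    pa, pb = str(aln[0]), str(aln[1])
    cols: list[tuple[Optional[str], Optional[str]]] = []
    ia = ib = 0
    for ca, cb in zip(pa, pb):
        codon_a = codon_b = None
        if ca != "-":
            codon_a = a.coding[3 * ia : 3 * ia + 3]
            ia += 1
        if cb != "-":
            codon_b = b.coding[3 * ib : 3 * ib + 3]
            ib += 1
        cols.append((codon_a, codon_b))
    alignment = CodonAlignment(id_a=a.id, id_b=b.id, columns=tuple(cols))
    if not alignment.ungapped:
        return None
    return alignment


# ---------------------------------------------------------------------------
# the NG86 estimator
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    """NG86 site/difference counts and corrected rates for one pair."""

    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ka: float  # nan when flagged saturated
    ks: float
    omega: float  # inf when ks == 0 < ka; nan when undefined/saturated
    n_codons: int
    flags: tuple[str, ...] = field(default_factory=tuple)
    taxon_a: str = ""
    taxon_b: str = ""

    @property
    def omega_label(self) -> str:
        """Display form matching field conventions: "> 1" when Ks = 0 < Ka."""
        if "saturated" in self.flags:
            return "saturated"
        if math.isinf(self.omega):
            return "> 1"
        if math.isnan(self.omega):
            return "undefined"
        return f"{self.omega:.4f}"


def ng86(aln: CodonAlignment) -> RateEstimate:
    """Estimate Ka, Ks and Ka/Ks for one codon alignment by NG86 counting.

    Codons containing gaps, ``N`` or stop codons are excluded.  Site
    totals are averaged over the two sequences.  Saturated pairs
    (ps or pn >= 3/4) are flagged and their rates set to NaN.
    """
    S = N = Sd = Nd = 0.0
    n_codons = 0
    flags: list[str] = []
    for ca, cb in aln.ungapped:
        if ca not in GENETIC_CODE or cb not in GENETIC_CODE:
            continue  # N-containing or stop codon
        sa, na = _site_fractions(ca)
        sb, nb = _site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _path_counts(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError(f"no countable codon columns for {aln.id_a} vs {aln.id_b}")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    try:
        ks = jc_correct(ps)
        ka = jc_correct(pn)
    except SaturationError:
        return RateEstimate(
            aln.id_a, aln.id_b, S, N, Sd, Nd, ps, pn,
            math.nan, math.nan, math.nan, n_codons, ("saturated",),
        )
    if ks > 0:
        omega = ka / ks
    elif ka > 0:
        omega = math.inf
        flags.append("ks_zero")
    else:
        omega = math.nan
        flags.append("undefined")
    return RateEstimate(
        aln.id_a, aln.id_b, S, N, Sd, Nd, ps, pn, ka, ks, omega,
        n_codons, tuple(flags),
    )
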