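"""SSR (microsatellite) scanning and SNP transition/transversion typing.

SSRs are maximal perfect tandem repeats of 1–6 nt motifs meeting
class-specific minimum repeat counts (12 for mono-, 6 for di-, 5 for
tri- and tetra-, 4 for penta- and hexanucleotide motifs — the MISA-style
thresholds used for conifer transcriptomes).  A repeat run is reported
once, under its smallest repeating unit; ``N`` breaks a run.  SNP
allele pairs are classified as transitions (purine–purine or
pyrimidine–pyrimidine) or transversions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DEFAULT_MIN_REPEATS",
    "SSRLocus",
    "SNPRecord",
    "find_ssrs",
    "classify_snp",
    "canonical_motif",
    "marker_summary",
    "write_ssrs_tsv",
    "read_snps_tsv",
]

# minimum repeat counts per motif length (1..6)
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 6, 3: 5, 4: 5, 5: 4, 6: 4}

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat; coordinates 0-based half-open."""

    sequence_id: str
    motif: str
    unit_length: int
    repeat_count: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.motif) != self.unit_length:
            raise ValueError("motif length disagrees with unit_length")
        if self.end - self.start != self.unit_length * self.repeat_count:
            raise ValueError("locus span disagrees with unit_length × repeat_count")

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:  # 1-based inclusive
        return self.end


@dataclass(frozen=True)
class SNPRecord:
    sequence_id: str
    position: int
    allele_a: str
    allele_b: str

    @property
    def klass(self) -> str:
        return classify_snp(self.allele_a, self.allele_b)


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repeat of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_ssrs(
    seq: str,
    sequence_id: str = "",
    min_repeats: Mapping[int, int] = DEFAULT_MIN_REPEATS,
) -> list[SSRLocus]:
    """All maximal perfect SSRs in a sequence, smallest-unit reporting.

    For each motif length the sequence is scanned left to right for
    maximal runs of full motif copies; runs below the class minimum are
    discarded, non-primitive motifs (e.g. ``ATAT`` as a tetramer) are
    left to their shorter unit, and runs contained inside an
    already-reported run (cyclic-rotation duplicates) are suppressed.
    """
    seq = seq.upper()
    n = len(seq)
    candidates: list[SSRLocus] = []
    for unit in sorted(min_repeats):
        i = 0
        while i + unit * min_repeats[unit] <= n:
            motif = seq[i : i + unit]
            if not (set(motif) <= _BASES) or not _is_primitive(motif):
                i += 1
                continue
            r = 1
            while seq[i + unit * r : i + unit * (r + 1)] == motif:
                r += 1
            if r >= min_repeats[unit]:
                candidates.append(
                    SSRLocus(
                        sequence_id=sequence_id,
                        motif=motif,
                        unit_length=unit,
                        repeat_count=r,
                        start=i,
                        end=i + unit * r,
                    )
                )
                i += unit * r  # a maximal run cannot restart inside itself
            else:
                i += 1
    # suppress runs properly contained in another reported run
    kept: list[SSRLocus] = []
    for c in candidates:
        contained = any(
            o is not c and o.start <= c.start and c.end <= o.end
            and (o.end - o.start) > (c.end - c.start)
            for o in candidates
        )
        if not contained:
            kept.append(c)
    kept.sort(key=lambda l: (l.start, l.unit_length))
    return kept


def classify_snp(a: str, b: str) -> str:
    """"transition" or "transversion" for an allele pair; symmetric."""
    a, b = a.upper(), b.upper()
    if a not in _BASES or b not in _BASES:
        raise ValueError(f"alleles must be A/C/G/T, got {a!r}, {b!r}")
    if a == b:
        raise ValueError(f"alleles must differ, got {a} twice")
    pair = {a, b}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest cyclic rotation, for motif grouping."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def marker_summary(
    ssrs: Iterable[SSRLocus],
    snps: Iterable[SNPRecord],
    canonical: bool = False,
) -> dict[str, pd.DataFrame]:
    """Class-frequency tables for SSRs and SNPs.

    Returns ``ssr_by_unit`` (counts per motif length), ``ssr_by_motif``
    (per motif, optionally collapsed to cyclic-rotation canonical
    form), and ``snp_classes`` (per unordered allele pair, with the
    transition/transversion fraction columns).
    """
    ssrs = list(ssrs)
    snps = list(snps)
    unit_counts = Counter(l.unit_length for l in ssrs)
    by_unit = pd.DataFrame(
        [{"unit_length": u, "count": unit_counts.get(u, 0)} for u in range(1, 7)]
    )
    motif_counts = Counter(
        canonical_motif(l.motif) if canonical else l.motif for l in ssrs
    )
    by_motif = pd.DataFrame(
        [{"motif": m, "count": c} for m, c in sorted(motif_counts.items())]
    )
    pair_counts = Counter("/".join(sorted((s.allele_a, s.allele_b))) for s in snps)
    klass_counts = Counter(s.klass for s in snps)
    total = len(snps)
    snp_rows = []
    for pair, c in sorted(pair_counts.items()):
        a, b = pair.split("/")
        snp_rows.append(
            {"allele_pair": pair, "klass": classify_snp(a, b), "count": c}
        )
    snp_classes = pd.DataFrame(snp_rows)
    snp_classes.attrs["transition_fraction"] = (
        klass_counts["transition"] / total if total else float("nan")
    )
    snp_classes.attrs["transversion_fraction"] = (
        klass_counts["transversion"] / total if total else float("nan")
    )
    return {"ssr_by_unit": by_unit, "ssr_by_motif": by_motif, "snp_classes": snp_classes}


def write_ssrs_tsv(ssrs: Iterable[SSRLocus], path: Path) -> None:
    """1-based inclusive coordinates in the report, per field convention."""
    with open(path, "w") as fh:
        fh.write("id\tmotif\tunit_length\trepeat_count\tstart\tend\n")
        for l in ssrs:
            fh.write(
                f"{l.sequence_id}\t{l.motif}\t{l.unit_length}\t{l.repeat_count}\t"
                f"{l.start_1based}\t{l.end_1based}\n"
            )


def read_snps_tsv(path: Path) -> list[SNPRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return [
        SNPRecord(str(r.id), int(r.pos), str(r.allele_a), str(r.allele_b))
        for r in df.itertuples()
    ]
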