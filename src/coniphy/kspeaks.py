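"""Modal synonymous divergence ("Ks peak") per species pair.

For every species pair the per-orthologue Ks values are binned into a
fixed-width histogram over [0, cap) and the peak is the left edge of
the modal bin.  Peaks across all pairs assemble into a symmetric
taxon-by-taxon matrix of (orthologue count, Ks peak) which doubles as
the distance matrix for tree building.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["KsDistribution", "KsPeak", "PeakMatrix", "ks_peak", "peak_matrix"]


@dataclass(frozen=True)
class KsDistribution:
    """All per-pair Ks values for one species pair."""

    taxon_a: str
    taxon_b: str
    values: tuple[float, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class KsPeak:
    """The modal Ks for one species pair.

    ``peak`` is the left edge of the modal histogram bin; a first-bin
    mode is held as 0.0 and displayed as "< <bin_width>".
    """

    taxon_a: str
    taxon_b: str
    peak: float
    n_pairs: int
    bin_width: float

    @property
    def display(self) -> str:
        """Reported form: 2 decimals on the standard 0.01 grid, and the
        sub-resolution "< width" convention for a first-bin mode."""
        if self.peak < self.bin_width:
            return f"< {self.bin_width:g}"
        decimals = 2 if self.bin_width >= 0.01 else 3
        return f"{self.peak:.{decimals}f}"


def ks_peak(
    values: Sequence[float],
    bin_width: float = 0.01,
    cap: float = 2.0,
    taxon_a: str = "",
    taxon_b: str = "",
) -> KsPeak:
    """Histogram mode of a Ks sample on a fixed grid.

    Values outside [0, cap) (saturated or negative) are dropped first;
    ties between equally tall bins resolve toward the lower bin.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    kept = arr[(arr >= 0) & (arr < cap)]
    if kept.size == 0:
        raise ValueError("no Ks values in [0, cap) — nothing to bin")
    n_bins = int(round(cap / bin_width))
    counts, _ = np.histogram(kept, bins=n_bins, range=(0.0, cap))
    mode_bin = int(np.argmax(counts))  # argmax takes the first (lower) tie
    peak = round(mode_bin * bin_width, 10)  # exact multiple of the bin width
    return KsPeak(taxon_a, taxon_b, peak, int(kept.size), bin_width)


@dataclass(frozen=True)
class PeakMatrix:
    """Symmetric taxon × taxon table of orthologue counts and Ks peaks."""

    taxa: tuple[str, ...]
    counts: pd.DataFrame  # int, NaN diagonal
    peaks: pd.DataFrame  # float, NaN diagonal

    def peak(self, a: str, b: str) -> float:
        return float(self.peaks.loc[a, b])

    def n_pairs(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.taxa):
            for b in self.taxa[i + 1 :]:
                if np.isnan(self.peaks.loc[a, b]):
                    out.append((a, b))
        return out

    def to_distance_matrix(self):
        """Ks-peak distances, for tree building; requires no missing pairs."""
        from .treeclock import DistanceMatrix

        if self.missing_pairs():
            raise ValueError(f"missing species pairs: {self.missing_pairs()}")
        d = self.peaks.loc[list(self.taxa), list(self.taxa)].to_numpy(dtype=float)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(taxa=self.taxa, values=d)

    def write_tsv(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_a\ttaxon_b\tn_pairs\tks_peak\n")
            for i, a in enumerate(self.taxa):
                for b in self.taxa[i + 1 :]:
                    if np.isnan(self.peaks.loc[a, b]):
                        continue
                    fh.write(f"{a}\t{b}\t{self.n_pairs(a, b)}\t{self.peak(a, b):.2f}\n")

    @classmethod
    def from_tsv(cls, path: Path) -> "PeakMatrix":
        df = pd.read_csv(path, sep="\t")
        peaks = [
            KsPeak(r.taxon_a, r.taxon_b, float(r.ks_peak), int(r.n_pairs), 0.01)
            for r in df.itertuples()
        ]
        return peak_matrix(peaks)


def peak_matrix(peaks: Iterable[KsPeak]) -> PeakMatrix:
    """Assemble per-pair peaks into the symmetric matrix form.

    Taxon order follows first appearance; the content is invariant to
    input ordering.  Pairs never observed stay NaN and are reported by
    :meth:`PeakMatrix.missing_pairs`.
    """
    peaks = list(peaks)
    taxa: list[str] = []
    for p in peaks:
        for t in (p.taxon_a, p.taxon_b):
            if t not in taxa:
                taxa.append(t)
    taxa_sorted = tuple(sorted(taxa))
    counts = pd.DataFrame(np.nan, index=taxa_sorted, columns=taxa_sorted)
    vals = pd.DataFrame(np.nan, index=taxa_sorted, columns=taxa_sorted)
    for p in peaks:
        counts.loc[p.taxon_a, p.taxon_b] = counts.loc[p.taxon_b, p.taxon_a] = p.n_pairs
        vals.loc[p.taxon_a, p.taxon_b] = vals.loc[p.taxon_b, p.taxon_a] = p.peak
    return PeakMatrix(taxa=taxa_sorted, counts=counts, peaks=vals)
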