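"""Neighbour-joining phylogeny from Ks-peak distances and clock dating.

The species tree is built with classical neighbour joining (Saitou–Nei
Q-criterion) on the Ks-peak matrix, rooted at the midpoint of the
outgroup's pendant edge, and each split is dated by converting its
branch-average Ks — the mean of all cross-clade pairwise Ks values —
to absolute time with a synonymous molecular clock (default
0.68 × 10⁻⁹ substitutions/site/year, giving age in years = Ks / rate).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "ClockRate",
    "CladeTree",
    "nj_tree",
    "root_with_outgroup",
    "branch_average_ks",
    "divergence_time",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not fit {n} taxa")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon names")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])

    def write_tsv(self, path: Path) -> None:
        pd.DataFrame(self.values, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t", index_label="taxon"
        )

    @classmethod
    def from_tsv(cls, path: Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(taxa=tuple(df.index), values=df.to_numpy(dtype=float))


@dataclass(frozen=True)
class ClockRate:
    """Synonymous substitution rate, substitutions per site per year."""

    rate: float = 0.68e-9

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"clock rate must be > 0, got {self.rate}")


def _token(name: str) -> str:
    if re.search(r"[\s()\[\]:;,']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.warning("negative NJ branch length %.4g at %s clamped to 0", length, context)
        return 0.0
    return length


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Classical neighbour joining; unrooted tree with a trifurcating base.

    Q-criterion ties are broken toward the lowest-index node pair (in
    order of taxon input / node creation), so the join order — and with
    it the output — is fully deterministic.  Negative branch lengths
    are clamped to zero with a warning.
    """
    n = len(m.taxa)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    d: dict[int, dict[int, float]] = {
        i: {j: float(m.values[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    sub = {i: f"{_token(m.taxa[i])}" for i in range(n)}
    active = list(range(n))
    next_id = n
    while len(active) > 3:
        k = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best_q = math.inf
        best = (-1, -1)
        for a_pos in range(k):
            for b_pos in range(a_pos + 1, k):
                i, j = active[a_pos], active[b_pos]
                q = (k - 2) * d[i][j] - r[i] - r[j]
                if q < best_q:  # strict: exact ties keep the earliest pair
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = d[i][j] - li
        li = _clamp(li, f"join({i},{j})")
        lj = _clamp(lj, f"join({i},{j})")
        u = next_id
        next_id += 1
        d[u] = {}
        for h in active:
            if h in (i, j):
                continue
            duh = 0.5 * (d[i][h] + d[j][h] - d[i][j])
            d[u][h] = duh
            d[h][u] = duh
        sub[u] = f"({sub[i]}:{li:.10g},{sub[j]}:{lj:.10g})"
        active = [h for h in active if h not in (i, j)] + [u]
    a, b, c = active
    la = _clamp(0.5 * (d[a][b] + d[a][c] - d[b][c]), "final")
    lb = _clamp(0.5 * (d[a][b] + d[b][c] - d[a][c]), "final")
    lc = _clamp(0.5 * (d[a][c] + d[b][c] - d[a][b]), "final")
    newick = f"({sub[a]}:{la:.10g},{sub[b]}:{lb:.10g},{sub[c]}:{lc:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


@dataclass
class CladeTree:
    """A rooted species tree in Ks units with clock-dated splits."""

    tree: dendropy.Tree
    outgroup: str

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node (root included)."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
        return out

    def has_clade(self, taxa: Iterable[str]) -> bool:
        return frozenset(taxa) in self.clades()

    def node_table(
        self,
        m: DistanceMatrix,
        clock: ClockRate = ClockRate(),
        per_lineage: bool = False,
    ) -> pd.DataFrame:
        """Branch-average Ks and age for the two clades at every split."""
        rows = []
        for node in self.tree.preorder_internal_node_iter():
            children = node.child_nodes()
            if len(children) < 2:
                continue
            clade_a = sorted(l.taxon.label for l in children[0].leaf_iter())
            clade_b = sorted(
                l.taxon.label for ch in children[1:] for l in ch.leaf_iter()
            )
            ks = branch_average_ks(m, clade_a, clade_b)
            rows.append(
                {
                    "clade_a": ",".join(clade_a),
                    "clade_b": ",".join(clade_b),
                    "branch_average_ks": ks,
                    "age_mya": divergence_time(ks, clock, per_lineage=per_lineage),
                    "clock_rate": clock.rate,
                }
            )
        return pd.DataFrame(rows)


def root_with_outgroup(tree: dendropy.Tree, taxon: str) -> CladeTree:
    """Root at the midpoint of the outgroup's pendant edge.  Idempotent."""
    rooted = tree.clone(depth=1)
    node = rooted.find_node_with_taxon_label(taxon)
    if node is None or not node.is_leaf():
        raise ValueError(f"outgroup taxon {taxon!r} is not a leaf of the tree")
    seed_children = rooted.seed_node.child_nodes()
    if len(seed_children) == 2 and node in seed_children:
        # already rooted on this outgroup's pendant edge
        rooted.is_rooted = True
        return CladeTree(tree=rooted, outgroup=taxon)
    length = node.edge.length or 0.0
    rooted.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    rooted.is_rooted = True
    # drop a unifactory root artefact if rerooting an already-rooted tree
    rooted.suppress_unifurcations()
    return CladeTree(tree=rooted, outgroup=taxon)


def branch_average_ks(
    m: DistanceMatrix, clade_a: Sequence[str], clade_b: Sequence[str]
) -> float:
    """Mean of all cross-clade pairwise Ks values, to 3 decimals."""
    a, b = set(clade_a), set(clade_b)
    if not a or not b:
        raise ValueError("clades must be non-empty")
    if a & b:
        raise ValueError(f"clades overlap: {sorted(a & b)}")
    unknown = (a | b) - set(m.taxa)
    if unknown:
        raise ValueError(f"taxa not in matrix: {sorted(unknown)}")
    total = sum(m[x, y] for x in a for y in b)
    return round(total / (len(a) * len(b)), 3)


def divergence_time(
    ks: float, clock: ClockRate = ClockRate(), per_lineage: bool = False
) -> float:
    """Age in Mya from a branch-average Ks under the molecular clock.

    By default the pairwise Ks is divided by the rate directly
    (age = Ks / rate, in years), matching the convention the Ks-peak
    ages in this pipeline are calibrated to; ``per_lineage=True``
    applies the textbook two-lineage form Ks / (2 × rate).
    """
    if ks < 0:
        raise ValueError(f"Ks must be nonnegative, got {ks}")
    denom = clock.rate * (2.0 if per_lineage else 1.0)
    return round(ks / denom / 1e6, 1)
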