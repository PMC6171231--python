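"""Synthetic codon-evolution data with known Ks, omega and tree structure.

Sequences evolve under a per-event rejection-sampling process that is
deliberately expressed in the same currency as the NG86 estimator:
candidate single-nucleotide changes arrive uniformly over nucleotide
positions, changes creating a stop codon are never proposed, synonymous
changes are accepted freely and nonsynonymous changes with probability
proportional to omega.  The expected density of accepted synonymous
changes per synonymous site on a branch equals the branch length in Ks
units, and the nonsynonymous density equals omega times that.

The module also produces multi-taxon transcript sets evolved along a
known tree (with per-gene truth tables for round-trip testing),
non-coding decoy sequences, and FASTA/TSV writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np

from .codonrates import BASES, GENETIC_CODE, SENSE_CODONS, STOP_CODONS, _site_fractions

__all__ = [
    "SimulationConfig",
    "TrueParams",
    "random_coding_sequence",
    "evolve",
    "simulate_codon_pair",
    "simulate_clade",
    "write_fasta",
    "write_truth_table",
    "write_config",
]

_SENSE = np.array(SENSE_CODONS)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic-data run.

    ``ks_target`` is the expected synonymous divergence (substitutions
    per synonymous site) between the two tips of a pair, or the scale of
    the tree's branch lengths for clade simulation; ``omega`` the target
    Ka/Ks.  ``tree`` is a newick string with branch lengths in Ks units.
    """

    seed: int
    n_codons: int = 300
    omega: float = 0.2
    ks_target: float = 0.05
    n_genes: int = 100
    tree: Optional[str] = None
    n_decoys: int = 0
    decoy_n_codons: int = 150

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError(f"n_codons must be >= 1, got {self.n_codons}")
        if self.ks_target < 0:
            raise ValueError(f"ks_target must be >= 0, got {self.ks_target}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueParams:
    """Bookkeeping of what actually happened during one simulation."""

    ks_target: float
    omega: float
    syn_events: int = 0
    nonsyn_events: int = 0
    syn_sites: float = 0.0  # NG86 synonymous sites of the ancestral sequence
    nonsyn_sites: float = 0.0

    @property
    def realized_ks(self) -> float:
        """Accepted synonymous events per ancestral synonymous site."""
        return self.syn_events / self.syn_sites if self.syn_sites else 0.0

    @property
    def realized_ka(self) -> float:
        return self.nonsyn_events / self.nonsyn_sites if self.nonsyn_sites else 0.0


def random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """A stop-free codon sequence drawn uniformly from the 61 sense codons."""
    return "".join(rng.choice(_SENSE, size=n_codons))


def _ancestral_sites(seq: str) -> tuple[float, float]:
    syn = nonsyn = 0.0
    for i in range(0, len(seq), 3):
        s, n = _site_fractions(seq[i : i + 3])
        syn += s
        nonsyn += n
    return syn, nonsyn


def evolve(
    seq: str,
    ks: float,
    omega: float,
    rng: np.random.Generator,
    truth: Optional[TrueParams] = None,
) -> str:
    """Evolve a codon sequence along one branch of length ``ks``.

    The number of candidate events is Poisson with mean
    ``3 L × ks × max(1, omega)``; each candidate picks a uniform
    nucleotide position and a uniform non-stop alternative base, and is
    accepted with probability ``1/max(1, omega)`` if synonymous or
    ``omega/max(1, omega)`` if nonsynonymous.  This yields expected
    accepted densities of ``ks`` per synonymous site and
    ``omega × ks`` per nonsynonymous site, with no indels and no
    in-frame stop codons ever introduced.
    """
    if ks < 0:
        raise ValueError(f"branch length must be >= 0, got {ks}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    scale = max(1.0, omega)
    p_syn = 1.0 / scale
    p_nonsyn = omega / scale
    n_nt = (len(seq) // 3) * 3
    n_events = rng.poisson(n_nt * ks * scale)
    chars = list(seq)
    for _ in range(n_events):
        pos = int(rng.integers(n_nt))
        codon_start = pos - pos % 3
        codon = "".join(chars[codon_start : codon_start + 3])
        cur_base = chars[pos]
        within = pos - codon_start
        alts = []
        for b in BASES:
            if b == cur_base:
                continue
            alt_codon = codon[:within] + b + codon[within + 1 :]
            if alt_codon not in STOP_CODONS:
                alts.append((b, alt_codon))
        new_base, new_codon = alts[int(rng.integers(len(alts)))]
        synonymous = GENETIC_CODE[new_codon] == GENETIC_CODE[codon]
        accept_p = p_syn if synonymous else p_nonsyn
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        chars[pos] = new_base
        if truth is not None:
            if synonymous:
                truth.syn_events += 1
            else:
                truth.nonsyn_events += 1
    return "".join(chars)


def simulate_codon_pair(config: SimulationConfig) -> tuple[str, str, TrueParams]:
    """An orthologous sequence pair at total divergence ``ks_target``.

    An ancestral sequence is evolved independently down two branches of
    length ``ks_target / 2`` each, so the pair's expected synonymous
    divergence is ``ks_target`` and its nonsynonymous divergence
    ``omega × ks_target``.
    """
    rng = config.rng()
    ancestor = random_coding_sequence(rng, config.n_codons)
    truth = TrueParams(ks_target=config.ks_target, omega=config.omega)
    truth.syn_sites, truth.nonsyn_sites = _ancestral_sites(ancestor)
    half = config.ks_target / 2.0
    seq_a = evolve(ancestor, half, config.omega, rng, truth)
    seq_b = evolve(ancestor, half, config.omega, rng, truth)
    return seq_a, seq_b, truth


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("simulation tree must have at least 2 taxa")
    return tree


def simulate_clade(
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[str, str]]], list[dict]]:
    """Per-taxon transcript sets evolved independently along a known tree.

    Returns ``(records, truth_rows)``: FASTA-ready ``(id, sequence)``
    records per taxon, where every orthologue of gene *k* carries the
    shared label ``g<k>`` in its id, plus a per-record truth table
    (gene, taxon, true Ks from root, omega).  ``config.n_decoys`` random
    codon strings (non-orthologous decoys) are appended per taxon.
    """
    if config.tree is None:
        raise ValueError("simulate_clade requires a tree")
    tree = _parse_tree(config.tree)
    rng = config.rng()
    taxa = [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]
    records: dict[str, list[tuple[str, str]]] = {t: [] for t in taxa}
    truth_rows: list[dict] = []
    for g in range(config.n_genes):
        gene = f"g{g:04d}"
        root_seq = random_coding_sequence(rng, config.n_codons)
        seqs: dict[int, tuple[str, float]] = {id(tree.seed_node): (root_seq, 0.0)}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_seq, parent_depth = seqs[id(node.parent_node)]
            bl = node.edge.length or 0.0
            seqs[id(node)] = (evolve(parent_seq, bl, config.omega, rng), parent_depth + bl)
        for leaf in tree.leaf_node_iter():
            taxon = leaf.taxon.label.replace(" ", "_")
            seq, depth = seqs[id(leaf)]
            rec_id = f"{gene}_{taxon}"
            records[taxon].append((rec_id, seq))
            truth_rows.append(
                {
                    "gene": gene,
                    "taxon": taxon,
                    "record_id": rec_id,
                    "ks_to_root": depth,
                    "omega": config.omega,
                }
            )
    for taxon in taxa:
        for d in range(config.n_decoys):
            rec_id = f"decoy{d:03d}_{taxon}"
            records[taxon].append((rec_id, random_coding_sequence(rng, config.decoy_n_codons)))
            truth_rows.append(
                {
                    "gene": "",
                    "taxon": taxon,
                    "record_id": rec_id,
                    "ks_to_root": float("nan"),
                    "omega": float("nan"),
                }
            )
    return records, truth_rows


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path: Path, seed: Optional[int] = None) -> None:
    """Plain FASTA; the generating seed is recorded in every header."""
    tag = f" seed={seed}" if seed is not None else ""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}{tag}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_truth_table(truth_rows: list[dict], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(path, sep="\t", index=False)


def write_config(config: SimulationConfig, path: Path) -> None:
    with open(path, "w") as fh:
        for key, value in vars(config).items():
            fh.write(f"{key}={value}\n")
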