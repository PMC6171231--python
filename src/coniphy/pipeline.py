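"""End-to-end driver: collapse → pair → rates → peaks → tree → dating → selection.

Every stage writes a plain TSV with a header into the output directory,
one stage per file, plus a manifest recording the package version, the
configuration (and its hash) and the seed, so a rerun with the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .codonrates import codon_align, infer_frame, ng86, RateEstimate
from .kspeaks import KsPeak, ks_peak, peak_matrix
from .orthopairs import (
    TranscriptSet,
    collapse_redundant,
    pair_orthologues,
    read_fasta_set,
    write_pairs_tsv,
)
from .selscan import (
    annotate_candidates,
    load_annotation_tsv,
    screen_positive,
    selection_counts,
    write_calls_tsv,
)
from .treeclock import ClockRate, root_with_outgroup, nj_tree

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "rates_to_tsv", "rates_from_tsv"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run."""

    fasta_by_taxon: dict[str, Path]
    output_dir: Path
    outgroup: Optional[str] = None
    redundancy_threshold: float = 0.95
    orthology_threshold: float = 0.90
    bin_width: float = 0.01
    ks_cap: float = 2.0
    clock_rate: float = 0.68e-9
    min_orf_codons: int = 50
    prefilter: bool = True
    seed: int = 0
    annotation_tsv: Optional[Path] = None

    def __post_init__(self) -> None:
        for name, val, lo, hi in (
            ("redundancy_threshold", self.redundancy_threshold, 0, 1),
            ("orthology_threshold", self.orthology_threshold, 0, 1),
        ):
            if not lo <= val <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {val}")
        if self.bin_width <= 0 or self.ks_cap <= 0:
            raise ValueError("bin_width and ks_cap must be positive")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")
        if self.outgroup is not None and self.outgroup not in self.fasta_by_taxon:
            raise ValueError(f"outgroup {self.outgroup!r} not among input taxa")

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    output_dir: Path
    peak_matrix: object
    newick: Optional[str]
    node_table: Optional[pd.DataFrame]
    n_pairs_total: int
    n_selected: int


def rates_to_tsv(rates: list[RateEstimate], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "taxon_a\tid_a\ttaxon_b\tid_b\tn_codons\tS\tN\tSd\tNd\t"
            "ka\tks\tka_ks\tflags\n"
        )
        for r in rates:
            fh.write(
                f"{r.taxon_a}\t{r.id_a}\t{r.taxon_b}\t{r.id_b}\t{r.n_codons}\t"
                f"{r.S:.4f}\t{r.N:.4f}\t{r.Sd:.4f}\t{r.Nd:.4f}\t"
                f"{r.ka:.6f}\t{r.ks:.6f}\t{r.omega_label}\t{','.join(r.flags)}\n"
            )


def rates_from_tsv(path: Path) -> list[RateEstimate]:
    df = pd.read_csv(path, sep="\t", dtype={"flags": str}).fillna({"flags": ""})
    out = []
    for row in df.itertuples():
        ka, ks = float(row.ka), float(row.ks)
        if ks > 0:
            omega: float = ka / ks
        elif ka > 0:
            omega = math.inf
        else:
            omega = math.nan
        flags = tuple(f for f in str(row.flags).split(",") if f)
        ps = row.Sd / row.S if row.S else 0.0
        pn = row.Nd / row.N if row.N else 0.0
        out.append(
            RateEstimate(
                id_a=row.id_a, id_b=row.id_b, S=row.S, N=row.N,
                Sd=row.Sd, Nd=row.Nd, ps=ps, pn=pn,
                ka=ka, ks=ks, omega=omega, n_codons=int(row.n_codons),
                flags=flags, taxon_a=row.taxon_a, taxon_b=row.taxon_b,
            )
        )
    return out


def _estimate_pair_rates(
    pairs, sets: dict[str, TranscriptSet], min_orf_codons: int
) -> list[RateEstimate]:
    seqs = {
        taxon: dict(ts.records) for taxon, ts in sets.items()
    }
    frames: dict[tuple[str, str], object] = {}

    def frame(taxon: str, rec_id: str):
        key = (taxon, rec_id)
        if key not in frames:
            frames[key] = infer_frame(seqs[taxon][rec_id], id=rec_id, min_codons=min_orf_codons)
        return frames[key]

    rates: list[RateEstimate] = []
    n_noncoding = n_unalignable = n_saturated = 0
    for p in pairs:
        cs_a = frame(p.taxon_a, p.id_a)
        cs_b = frame(p.taxon_b, p.id_b)
        if cs_a is None or cs_b is None:
            n_noncoding += 1
            continue
        aln = codon_align(cs_a, cs_b)
        if aln is None:
            n_unalignable += 1
            continue
        est = ng86(aln)
        est.taxon_a, est.taxon_b = p.taxon_a, p.taxon_b
        if "saturated" in est.flags:
            n_saturated += 1
            continue
        rates.append(est)
    logger.info(
        "rates: %d estimated, %d non-coding, %d unalignable, %d saturated dropped",
        len(rates), n_noncoding, n_unalignable, n_saturated,
    )
    return rates


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write per-stage TSV artifacts plus a manifest."""
    if not config.fasta_by_taxon:
        raise ValueError("no input FASTA files configured")
    for taxon, path in config.fasta_by_taxon.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input FASTA for {taxon} missing: {path}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1+2: read and collapse
    sets: dict[str, TranscriptSet] = {}
    for taxon in sorted(config.fasta_by_taxon):
        ts = read_fasta_set(Path(config.fasta_by_taxon[taxon]), taxon=taxon)
        if len(ts) == 0:
            raise ValueError(f"input FASTA for {taxon} contains no records")
        sets[taxon] = collapse_redundant(ts, threshold=config.redundancy_threshold)

    # stage 3: orthologue pairing for every taxon pair
    taxa = sorted(sets)
    all_pairs = []
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            all_pairs.extend(
                pair_orthologues(
                    sets[ta], sets[tb],
                    threshold=config.orthology_threshold,
                    prefilter=config.prefilter,
                )
            )
    write_pairs_tsv(all_pairs, out / "orthologue_pairs.tsv")

    # stage 4: Ka/Ks
    rates = _estimate_pair_rates(all_pairs, sets, config.min_orf_codons)
    rates_to_tsv(rates, out / "rates.tsv")

    # stage 5: Ks peaks per species pair
    by_pair: dict[tuple[str, str], list[float]] = {}
    for r in rates:
        by_pair.setdefault((r.taxon_a, r.taxon_b), []).append(r.ks)
    peaks: list[KsPeak] = []
    for (ta, tb), values in sorted(by_pair.items()):
        peaks.append(
            ks_peak(values, bin_width=config.bin_width, cap=config.ks_cap,
                    taxon_a=ta, taxon_b=tb)
        )
    pm = peak_matrix(peaks) if peaks else None
    if pm is not None:
        pm.write_tsv(out / "ks_peaks.tsv")
        pm.peaks.to_csv(out / "ks_peak_matrix.tsv", sep="\t", index_label="taxon")

    # stage 6: tree + dating
    newick = None
    node_table = None
    if pm is not None and len(pm.taxa) >= 3 and not pm.missing_pairs():
        dm = pm.to_distance_matrix()
        tree = nj_tree(dm)
        clock = ClockRate(config.clock_rate)
        if config.outgroup is not None:
            clade_tree = root_with_outgroup(tree, config.outgroup)
            newick = clade_tree.newick()
            node_table = clade_tree.node_table(dm, clock=clock)
            node_table.to_csv(out / "node_ages.tsv", sep="\t", index=False)
        else:
            newick = tree.as_string(schema="newick").strip()
        (out / "tree.nwk").write_text(newick + "\n")

    # stage 7: positive-selection screen
    calls = screen_positive(rates)
    if config.annotation_tsv is not None:
        calls = annotate_candidates(calls, load_annotation_tsv(Path(config.annotation_tsv)))
    write_calls_tsv(calls, out / "positive_selection.tsv")
    counts = selection_counts(calls)
    counts.to_csv(out / "selection_counts.tsv", sep="\t", index=False)
    n_selected = int(sum(c.selected for c in calls))

    manifest = {
        "package": "coniphy",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: str(v) for k, v in asdict(config).items()},
        "n_taxa": len(taxa),
        "n_orthologue_pairs": len(all_pairs),
        "n_rate_estimates": len(rates),
        "n_positive_selection": n_selected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        output_dir=out,
        peak_matrix=pm,
        newick=newick,
        node_table=node_table,
        n_pairs_total=len(all_pairs),
        n_selected=n_selected,
    )
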