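"""Positive-selection screen on Ka/Ks and annotation join.

A pair is called positively selected when Ka/Ks is strictly greater
than 1, including the boundary convention Ks = 0 with Ka > 0 (reported
as "> 1"); Ka = Ks = 0 is undefined and never selected.  No
significance test is applied — the screen is the raw ratio, a
documented limitation.  Functional labels (e.g. salt / drought /
abscisic-acid stress) are joined from a user-supplied annotation map;
database searches are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .codonrates import RateEstimate

__all__ = [
    "SelectionCall",
    "screen_positive",
    "selection_counts",
    "annotate_candidates",
    "load_annotation_tsv",
    "write_calls_tsv",
]


@dataclass(frozen=True)
class SelectionCall:
    """One orthologue pair with its selection verdict and annotation."""

    taxon_a: str
    id_a: str
    taxon_b: str
    id_b: str
    ka: float
    ks: float
    omega: float  # inf encodes the Ks = 0 < Ka convention
    selected: bool
    annotation_accession: str = ""
    annotation_label: str = ""
    conflict: bool = False

    @property
    def omega_label(self) -> str:
        if math.isinf(self.omega):
            return "> 1"
        if math.isnan(self.omega):
            return "undefined"
        return f"{self.omega:.4f}"


def _call(est: RateEstimate) -> SelectionCall:
    selected = (est.ks > 0 and est.ka / est.ks > 1) or (est.ks == 0 and est.ka > 0)
    if "saturated" in est.flags:
        selected = False
    return SelectionCall(
        taxon_a=est.taxon_a, id_a=est.id_a,
        taxon_b=est.taxon_b, id_b=est.id_b,
        ka=est.ka, ks=est.ks, omega=est.omega, selected=selected,
    )


def screen_positive(pairs: Iterable[RateEstimate]) -> list[SelectionCall]:
    """Calls for every input pair; ``selected`` marks omega > 1.

    The output covers the whole input (nothing is dropped), so the
    selected calls and their complement partition the rate table.
    """
    return [_call(est) for est in pairs]


def selection_counts(calls: Iterable[SelectionCall]) -> pd.DataFrame:
    """Positively selected pair counts per species pair."""
    rows: dict[tuple[str, str], int] = {}
    for c in calls:
        key = tuple(sorted((c.taxon_a, c.taxon_b)))
        rows.setdefault(key, 0)
        if c.selected:
            rows[key] += 1
    return pd.DataFrame(
        [
            {"taxon_a": a, "taxon_b": b, "n_positive": n}
            for (a, b), n in sorted(rows.items())
        ]
    )


def annotate_candidates(
    calls: Iterable[SelectionCall],
    mapping: Mapping[str, tuple[str, str]],
) -> list[SelectionCall]:
    """Left-join functional labels onto calls by either member's id.

    ``mapping`` is transcript id -> (accession, label).  Unmatched
    calls keep empty labels; when both members map to conflicting
    labels, both are retained (semicolon-joined) and the call is
    flagged as a conflict.
    """
    out = []
    for c in calls:
        hits = [mapping[i] for i in (c.id_a, c.id_b) if i in mapping]
        if not hits:
            out.append(c)
            continue
        accessions = [h[0] for h in hits]
        labels = [h[1] for h in hits]
        conflict = len(set(labels)) > 1
        out.append(
            replace(
                c,
                annotation_accession=";".join(dict.fromkeys(accessions)),
                annotation_label=";".join(dict.fromkeys(labels)),
                conflict=conflict,
            )
        )
    return out


def load_annotation_tsv(path: Path) -> dict[str, tuple[str, str]]:
    """Read an annotation map TSV (id, accession, label); ids must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"duplicate annotation ids: {dups}")
    return {r.id: (r.accession, r.label) for r in df.itertuples()}


def write_calls_tsv(calls: Iterable[SelectionCall], path: Path, selected_only: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(
            "taxon_a\tid_a\ttaxon_b\tid_b\tka\tks\tka_ks\tselected\t"
            "accession\tlabel\tconflict\n"
        )
        for c in calls:
            if selected_only and not c.selected:
                continue
            fh.write(
                f"{c.taxon_a}\t{c.id_a}\t{c.taxon_b}\t{c.id_b}\t"
                f"{c.ka:.4f}\t{c.ks:.4f}\t{c.omega_label}\t{int(c.selected)}\t"
                f"{c.annotation_accession}\t{c.annotation_label}\t{int(c.conflict)}\n"
            )
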