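"""Packaged reference data: the published 13-conifer Ks-peak matrix.

Orthologue counts and modal Ks values for every pair of 12 *Pinus*
species and the outgroup *Picea glauca*, as published for this species
panel.  The matrix is the input for the divergence-dating worked
example: Ks-peak distances give the NJ topology, and branch-average Ks
values for the classical splits (genus, subgenus, section) convert to
ages under the 0.68 × 10⁻⁹ /site/year synonymous clock.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .treeclock import DistanceMatrix

__all__ = [
    "CONIFER_TAXA",
    "OUTGROUP",
    "SUBGENUS_STROBUS",
    "SUBGENUS_PINUS",
    "SECTION_TRIFOLIAE",
    "SECTION_PINUS",
    "conifer_peak_table",
    "conifer_ks_matrix",
    "conifer_count_matrix",
]

# taxon panel in publication order; Picea glauca is the outgroup
CONIFER_TAXA = (
    "P_kesiya",
    "P_tabuliformis",
    "P_sylvestris",
    "P_pinea",
    "P_halepensis",
    "P_pinaster",
    "P_contorta",
    "P_banksiana",
    "P_taeda",
    "P_palustris",
    "P_monticola",
    "P_lambertiana",
    "Picea_glauca",
)

OUTGROUP = "Picea_glauca"

# classical subdivisions of the 12 pines
SUBGENUS_STROBUS = ("P_monticola", "P_lambertiana")
SUBGENUS_PINUS = (
    "P_kesiya", "P_tabuliformis", "P_sylvestris", "P_pinea",
    "P_halepensis", "P_pinaster", "P_contorta", "P_banksiana",
    "P_taeda", "P_palustris",
)
SECTION_TRIFOLIAE = ("P_contorta", "P_banksiana", "P_taeda", "P_palustris")
SECTION_PINUS = (
    "P_kesiya", "P_tabuliformis", "P_sylvestris",
    "P_pinea", "P_halepensis", "P_pinaster",
)

# lower triangle, one row per taxon vs all earlier taxa: "n_pairs/ks_peak"
_PEAK_TABLE_TSV = """\
taxon_a\ttaxon_b\tn_pairs\tks_peak
P_tabuliformis\tP_kesiya\t6351\t0.01
P_sylvestris\tP_kesiya\t4331\t0.01
P_sylvestris\tP_tabuliformis\t898\t0.01
P_pinea\tP_kesiya\t8112\t0.03
P_pinea\tP_tabuliformis\t4144\t0.03
P_pinea\tP_sylvestris\t1153\t0.02
P_halepensis\tP_kesiya\t16051\t0.03
P_halepensis\tP_tabuliformis\t5498\t0.03
P_halepensis\tP_sylvestris\t727\t0.02
P_halepensis\tP_pinea\t5839\t0.03
P_pinaster\tP_kesiya\t7561\t0.02
P_pinaster\tP_tabuliformis\t3311\t0.03
P_pinaster\tP_sylvestris\t944\t0.02
P_pinaster\tP_pinea\t3844\t0.03
P_pinaster\tP_halepensis\t6419\t0.03
P_contorta\tP_kesiya\t8922\t0.03
P_contorta\tP_tabuliformis\t3953\t0.03
P_contorta\tP_sylvestris\t1129\t0.03
P_contorta\tP_pinea\t4392\t0.04
P_contorta\tP_halepensis\t6578\t0.04
P_contorta\tP_pinaster\t4011\t0.03
P_banksiana\tP_kesiya\t7784\t0.03
P_banksiana\tP_tabuliformis\t3577\t0.03
P_banksiana\tP_sylvestris\t1374\t0.03
P_banksiana\tP_pinea\t3815\t0.04
P_banksiana\tP_halepensis\t5642\t0.04
P_banksiana\tP_pinaster\t3610\t0.04
P_banksiana\tP_contorta\t4996\t0.01
P_taeda\tP_kesiya\t13493\t0.04
P_taeda\tP_tabuliformis\t4981\t0.03
P_taeda\tP_sylvestris\t2624\t0.03
P_taeda\tP_pinea\t6114\t0.04
P_taeda\tP_halepensis\t14088\t0.04
P_taeda\tP_pinaster\t6496\t0.04
P_taeda\tP_contorta\t6836\t0.01
P_taeda\tP_banksiana\t5744\t0.01
P_palustris\tP_kesiya\t9311\t0.03
P_palustris\tP_tabuliformis\t3514\t0.03
P_palustris\tP_sylvestris\t1092\t0.03
P_palustris\tP_pinea\t4097\t0.04
P_palustris\tP_halepensis\t8425\t0.04
P_palustris\tP_pinaster\t4035\t0.04
P_palustris\tP_contorta\t4321\t0.01
P_palustris\tP_banksiana\t3994\t0.01
P_palustris\tP_taeda\t7551\t0.01
P_monticola\tP_kesiya\t7472\t0.08
P_monticola\tP_tabuliformis\t3538\t0.08
P_monticola\tP_sylvestris\t1433\t0.06
P_monticola\tP_pinea\t4481\t0.08
P_monticola\tP_halepensis\t5940\t0.08
P_monticola\tP_pinaster\t3790\t0.09
P_monticola\tP_contorta\t4773\t0.07
P_monticola\tP_banksiana\t4769\t0.06
P_monticola\tP_taeda\t4847\t0.09
P_monticola\tP_palustris\t5087\t0.08
P_lambertiana\tP_kesiya\t11185\t0.08
P_lambertiana\tP_tabuliformis\t4477\t0.08
P_lambertiana\tP_sylvestris\t1964\t0.06
P_lambertiana\tP_pinea\t5233\t0.08
P_lambertiana\tP_halepensis\t8269\t0.09
P_lambertiana\tP_pinaster\t4783\t0.08
P_lambertiana\tP_contorta\t5308\t0.08
P_lambertiana\tP_banksiana\t4722\t0.08
P_lambertiana\tP_taeda\t8349\t0.08
P_lambertiana\tP_palustris\t6428\t0.08
P_lambertiana\tP_monticola\t7169\t0.01
Picea_glauca\tP_kesiya\t13691\t0.14
Picea_glauca\tP_tabuliformis\t4808\t0.15
Picea_glauca\tP_sylvestris\t959\t0.14
Picea_glauca\tP_pinea\t6493\t0.15
Picea_glauca\tP_halepensis\t12041\t0.15
Picea_glauca\tP_pinaster\t5082\t0.15
Picea_glauca\tP_contorta\t7999\t0.14
Picea_glauca\tP_banksiana\t7092\t0.14
Picea_glauca\tP_taeda\t9724\t0.15
Picea_glauca\tP_palustris\t6019\t0.14
Picea_glauca\tP_monticola\t7710\t0.15
Picea_glauca\tP_lambertiana\t9969\t0.15
"""


def conifer_peak_table() -> pd.DataFrame:
    """Long-form table: taxon_a, taxon_b, n_pairs, ks_peak (one row/pair)."""
    return pd.read_csv(io.StringIO(_PEAK_TABLE_TSV), sep="\t")


def _square(column: str) -> pd.DataFrame:
    df = conifer_peak_table()
    out = pd.DataFrame(np.nan, index=CONIFER_TAXA, columns=CONIFER_TAXA)
    for row in df.itertuples():
        out.loc[row.taxon_a, row.taxon_b] = getattr(row, column)
        out.loc[row.taxon_b, row.taxon_a] = getattr(row, column)
    return out


def conifer_ks_matrix() -> DistanceMatrix:
    """The Ks-peak distance matrix over the 13-taxon panel."""
    peaks = _square("ks_peak")
    vals = peaks.to_numpy(dtype=float)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(taxa=CONIFER_TAXA, values=vals)


def conifer_count_matrix() -> pd.DataFrame:
    """Orthologue-pair counts in the same square layout (NaN diagonal)."""
    return _square("n_pairs")
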