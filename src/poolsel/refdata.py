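"""Bundled case-study tallies for report demos and benchmark checks.

These are the published per-gene-set and per-receptor substitution
tallies from a pooled antennal RNA-seq comparison of two sibling bee
species (40 haploid males per pool).  They serve as fixed inputs for the
statistics and domain modules; the underlying read data are not part of
this package.
"""

from __future__ import annotations

import pandas as pd

from .selstats import GeneSetTallies

__all__ = [
    "gene_set_tallies",
    "receptor_substitutions",
    "OR_MEAN_TM_FRACTION",
    "IR_LBD_FRACTIONS",
]

# Mean fraction of OR protein length covered by the seven TM domains
# (per-protein values ranged 0.193-0.358 in the source predictions).
OR_MEAN_TM_FRACTION = 0.305

# S1/S2 ligand-binding-domain coverage of the two IR proteins, keyed by gene.
IR_LBD_FRACTIONS = {"IR03": 0.165, "IR11": 0.147}


def gene_set_tallies() -> dict:
    """Variable-site and gene tallies for the chemosensory and NC sets."""
    return {
        "chemosensory": GeneSetTallies(
            name="chemosensory",
            n_genes=94,
            n_fixed=101,
            n_polymorphic=117,
            n_fixed_syn=25,
            n_fixed_nonsyn=76,
            n_omega_gt1=12,
        ),
        "NC": GeneSetTallies(
            name="NC",
            n_genes=3091,
            n_fixed=376,
            n_polymorphic=613,
            n_fixed_syn=277,
            n_fixed_nonsyn=99,
            n_omega_gt1=23,
        ),
    }


def receptor_substitutions() -> pd.DataFrame:
    """Per-receptor substitution counts for the 12 genes with dN/dS > 1.

    Columns: family, fixed/polymorphic nonsynonymous and synonymous
    counts, dN, dS, and the number of fixed nonsynonymous substitutions
    inside the ligand-binding domains (TM regions for ORs, S1/S2 for IRs).
    """
    rows = [
        # gene, family, fx_nonsyn, poly_nonsyn, fx_syn, poly_syn, dn, ds, in_lbd
        ("OR41", "OR", 18, 1, 1, 5, 0.0213, 0.0028, 9),
        ("OR12", "OR", 10, 6, 1, 2, 0.0097, 0.0040, 3),
        ("OR45", "OR", 5, 1, 0, 0, 0.0053, 0.0000, 5),
        ("OR14", "OR", 3, 2, 0, 4, 0.0021, 0.0000, 1),
        ("OR01", "OR", 3, 1, 0, 3, 0.0031, 0.0000, 2),
        ("OR16", "OR", 2, 5, 0, 1, 0.0032, 0.0000, 1),
        ("OR71", "OR", 2, 5, 0, 0, 0.0029, 0.0000, 1),
        ("OR49", "OR", 2, 2, 1, 1, 0.0026, 0.0025, 2),
        ("OR11", "OR", 1, 0, 0, 1, 0.0012, 0.0000, 0),
        ("OR19", "OR", 1, 0, 0, 0, 0.0012, 0.0000, 0),
        ("IR03", "IR", 7, 2, 1, 1, 0.0046, 0.0021, 3),
        ("IR11", "IR", 1, 0, 0, 1, 0.0006, 0.0000, 0),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "family", "n_fixed_nonsyn", "n_poly_nonsyn",
            "n_fixed_syn", "n_poly_syn", "dn", "ds", "in_lbd",
        ],
    )
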