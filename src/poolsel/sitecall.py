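"""Per-site classification of two species' pooled pileups.

Each ORF site is classified as a fixed interspecific difference, a
within-species polymorphism, invariant, or unclassifiable (insufficient
depth), using read-count presence rules:

* an allele is *present* when supported by at least ``max(floor, frac *
  depth)`` reads (defaults 5 reads / 5 %);
* a site is *fixed* when one species shows a single base at >= 95 % of
  reads and that base is not present in the other species.

Fixed and polymorphic sites are annotated as synonymous or nonsynonymous
against the major-allele consensus, and fixed-difference-only codon
alignments are produced for downstream dN/dS estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "BASES",
    "PileupColumn",
    "SiteCall",
    "GeneVariation",
    "allele_presence",
    "classify_site",
    "annotate_effect",
    "classify_gene",
    "build_fixed_alignment",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class PileupColumn:
    """Base counts for one species' read pool at one ORF position (1-based)."""

    gene_id: str
    pos: int
    species: str
    counts: dict

    @property
    def depth(self) -> int:
        return int(sum(self.counts.values()))

    def count(self, base: str) -> int:
        return int(self.counts.get(base, 0))


@dataclass
class SiteCall:
    """Classification of one homologous site across the two pools."""

    gene_id: str
    pos: int
    site_class: str  # fixed | polymorphic | invariant | unclassifiable
    present_a: frozenset = frozenset()
    present_b: frozenset = frozenset()
    major_a: str | None = None
    major_b: str | None = None
    minor_a: str | None = None
    minor_b: str | None = None
    direction: str = "none"  # A | B | both (fixed sites only)
    effect: str = "none"  # syn | nonsyn | none
    polymorphic_in: str = "none"  # A | B | both | none
    tie_flag: bool = False


@dataclass
class GeneVariation:
    """Per-gene site tallies mirroring the per-family accounting columns."""

    gene_id: str
    family_tag: str
    mean_cov_a: float
    mean_cov_b: float
    n_fixed_syn: int = 0
    n_fixed_nonsyn: int = 0
    n_poly_syn: int = 0
    n_poly_nonsyn: int = 0
    passes_coverage: bool = True

    @property
    def n_fixed(self) -> int:
        return self.n_fixed_syn + self.n_fixed_nonsyn

    @property
    def n_polymorphic(self) -> int:
        return self.n_poly_syn + self.n_poly_nonsyn

    @property
    def n_variable(self) -> int:
        return self.n_fixed + self.n_polymorphic


def allele_presence(counts, presence_floor: int = 5, presence_frac: float = 0.05) -> frozenset:
    """Bases supported by ``>= max(presence_floor, presence_frac * depth)`` reads.

    Zero depth yields the empty set.
    """
    depth = sum(counts.get(b, 0) for b in BASES)
    if depth == 0:
        return frozenset()
    threshold = max(presence_floor, presence_frac * depth)
    return frozenset(b for b in BASES if counts.get(b, 0) >= threshold)


def _major_minor(counts) -> tuple[str, str | None, bool]:
    """Major allele (ties broken A<C<G<T, flagged) and runner-up base."""
    ordered = sorted(BASES, key=lambda b: (-counts.get(b, 0), b))
    major = ordered[0]
    tie = counts.get(ordered[1], 0) == counts.get(major, 0) and counts.get(major, 0) > 0
    minor = ordered[1] if counts.get(ordered[1], 0) > 0 else None
    return major, minor, tie


def classify_site(
    col_a: PileupColumn,
    col_b: PileupColumn,
    min_site_depth: int = 10,
    fixed_major_freq: float = 0.95,
    presence_floor: int = 5,
    presence_frac: float = 0.05,
    require_bidirectional: bool = False,
) -> SiteCall:
    """Classify one site from the two species' pileup columns.

    A direction "A" means species A carries the >= ``fixed_major_freq``
    majority base that is absent from species B.  With
    ``require_bidirectional`` the rule must hold in both directions.
    """
    if col_a.gene_id != col_b.gene_id or col_a.pos != col_b.pos:
        raise ValueError("pileup columns refer to different sites")
    if col_a.species == col_b.species:
        raise ValueError("pileup columns must come from different species")

    depth_a, depth_b = col_a.depth, col_b.depth
    if depth_a < min_site_depth or depth_b < min_site_depth:
        return SiteCall(col_a.gene_id, col_a.pos, "unclassifiable")

    present_a = allele_presence(col_a.counts, presence_floor, presence_frac)
    present_b = allele_presence(col_b.counts, presence_floor, presence_frac)
    major_a, minor_a, tie_a = _major_minor(col_a.counts)
    major_b, minor_b, tie_b = _major_minor(col_b.counts)

    # A fixed call additionally requires the two majority bases to differ;
    # without this, a site where neither base passes presence in the other
    # pool could be called fixed for the same nucleotide in both species.
    dir_a = (
        col_a.count(major_a) >= fixed_major_freq * depth_a
        and major_a not in present_b
        and major_a != major_b
    )
    dir_b = (
        col_b.count(major_b) >= fixed_major_freq * depth_b
        and major_b not in present_a
        and major_b != major_a
    )
    fixed = (dir_a and dir_b) if require_bidirectional else (dir_a or dir_b)

    call = SiteCall(
        col_a.gene_id,
        col_a.pos,
        "invariant",
        present_a=present_a,
        present_b=present_b,
        major_a=major_a,
        major_b=major_b,
        minor_a=minor_a,
        minor_b=minor_b,
        tie_flag=tie_a or tie_b,
    )
    if fixed:
        call.site_class = "fixed"
        call.direction = "both" if (dir_a and dir_b) else ("A" if dir_a else "B")
        return call
    poly_a, poly_b = len(present_a) >= 2, len(present_b) >= 2
    if poly_a or poly_b:
        call.site_class = "polymorphic"
        call.polymorphic_in = "both" if (poly_a and poly_b) else ("A" if poly_a else "B")
    return call


def annotate_effect(site: SiteCall, consensus_a: str, consensus_b: str) -> str:
    """Synonymous/nonsynonymous label for a fixed or polymorphic site.

    The codon containing the site is taken from the relevant species'
    major-allele consensus with all other positions held at consensus;
    for fixed sites the two species' major alleles are compared, for
    polymorphic sites the minor allele is compared against the major.
    """
    if site.site_class not in ("fixed", "polymorphic"):
        raise ValueError(f"cannot annotate a {site.site_class} site")
    pos0 = site.pos - 1
    if pos0 < 0 or pos0 >= len(consensus_a):
        raise ValueError(f"position {site.pos} outside the ORF")
    ci, off = divmod(pos0, 3)
    if site.site_class == "fixed":
        codon = list(consensus_a[3 * ci : 3 * ci + 3])
        codon[off] = site.major_a
        ref = "".join(codon)
        codon[off] = site.major_b
        alt = "".join(codon)
    else:
        species = "A" if site.polymorphic_in in ("A", "both") else "B"
        consensus = consensus_a if species == "A" else consensus_b
        major = site.major_a if species == "A" else site.major_b
        minor = site.minor_a if species == "A" else site.minor_b
        if minor is None:
            present = site.present_a if species == "A" else site.present_b
            minor = sorted(present - {major})[0]
        codon = list(consensus[3 * ci : 3 * ci + 3])
        codon[off] = major
        ref = "".join(codon)
        codon[off] = minor
        alt = "".join(codon)
    effect = "syn" if Seq(ref).translate() == Seq(alt).translate() else "nonsyn"
    site.effect = effect
    return effect


def _count_matrix(pileups: pd.DataFrame, length: int) -> np.ndarray:
    """Pileup rows for one gene/species -> (length, 4) count matrix."""
    m = np.zeros((length, 4), dtype=np.int64)
    if len(pileups) == 0:
        return m
    pos = pileups["pos"].to_numpy(dtype=np.int64)
    if pos.min() < 1 or pos.max() > length:
        raise ValueError("pileup position outside the ORF")
    for b in BASES:
        m[pos - 1, _BASE_INDEX[b]] = pileups[b].to_numpy(dtype=np.int64)
    return m


def _consensus(matrix: np.ndarray, orf: str) -> str:
    """Per-site major-allele consensus, falling back to the ORF at depth 0."""
    out = []
    for i, row in enumerate(matrix):
        if row.sum() == 0:
            out.append(orf[i])
        else:
            out.append(BASES[int(np.argmax(row))])  # argmax ties -> A<C<G<T
    return "".join(out)


def classify_gene(
    pileups_a: pd.DataFrame,
    pileups_b: pd.DataFrame,
    orf: str,
    gene_id: str,
    family_tag: str = "unknown",
    min_mean_cov: float = 10.0,
    **site_kwargs,
) -> tuple[GeneVariation, list[SiteCall]]:
    """Classify every ORF site of one gene and tally its variation.

    ``pileups_a``/``pileups_b`` are data frames with ``pos, A, C, G, T``
    columns (missing positions count as depth 0).  Genes whose mean
    per-base coverage falls below ``min_mean_cov`` in either species are
    excluded: ``passes_coverage`` is False and no site calls are emitted.
    """
    length = len(orf)
    ma = _count_matrix(pileups_a, length)
    mb = _count_matrix(pileups_b, length)
    mean_a = float(ma.sum()) / length
    mean_b = float(mb.sum()) / length
    variation = GeneVariation(gene_id, family_tag, mean_a, mean_b)
    if mean_a < min_mean_cov or mean_b < min_mean_cov:
        variation.passes_coverage = False
        return variation, []

    consensus_a = _consensus(ma, orf)
    consensus_b = _consensus(mb, orf)
    calls = []
    for pos in range(1, length + 1):
        col_a = PileupColumn(gene_id, pos, "A", dict(zip(BASES, ma[pos - 1].tolist())))
        col_b = PileupColumn(gene_id, pos, "B", dict(zip(BASES, mb[pos - 1].tolist())))
        call = classify_site(col_a, col_b, **site_kwargs)
        if call.site_class in ("fixed", "polymorphic"):
            effect = annotate_effect(call, consensus_a, consensus_b)
            if call.site_class == "fixed":
                if effect == "syn":
                    variation.n_fixed_syn += 1
                else:
                    variation.n_fixed_nonsyn += 1
            else:
                if effect == "syn":
                    variation.n_poly_syn += 1
                else:
                    variation.n_poly_nonsyn += 1
        calls.append(call)
    return variation, calls


def build_fixed_alignment(consensus_a: str, consensus_b: str, site_calls) -> tuple[str, str]:
    """Two-sequence codon alignment differing exactly at fixed sites.

    At every non-fixed site both output sequences carry the species-A
    major allele (or consensus base), so downstream dN/dS estimation sees
    fixed interspecific differences only.
    """
    if len(consensus_a) != len(consensus_b):
        raise ValueError("consensus sequences differ in length")
    out_a = list(consensus_a)
    out_b = list(consensus_a)
    for call in site_calls:
        if call.site_class != "fixed":
            continue
        out_a[call.pos - 1] = call.major_a
        out_b[call.pos - 1] = call.major_b
    return "".join(out_a), "".join(out_b)


def site_calls_frame(calls) -> pd.DataFrame:
    """Site-call TSV schema: gene_id pos class direction effect polymorphic_in."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "pos": c.pos,
                "class": c.site_class,
                "direction": c.direction,
                "effect": c.effect,
                "polymorphic_in": c.polymorphic_in,
            }
            for c in calls
        ],
        columns=["gene_id", "pos", "class", "direction", "effect", "polymorphic_in"],
    )


def gene_variation_frame(variations) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": v.gene_id,
                "family_tag": v.family_tag,
                "mean_cov_a": v.mean_cov_a,
                "mean_cov_b": v.mean_cov_b,
                "n_fixed_syn": v.n_fixed_syn,
                "n_fixed_nonsyn": v.n_fixed_nonsyn,
                "n_poly_syn": v.n_poly_syn,
                "n_poly_nonsyn": v.n_poly_nonsyn,
                "passes_coverage": v.passes_coverage,
            }
            for v in variations
        ],
        columns=[
            "gene_id", "family_tag", "mean_cov_a", "mean_cov_b",
            "n_fixed_syn", "n_fixed_nonsyn", "n_poly_syn", "n_poly_nonsyn",
            "passes_coverage",
        ],
    )
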