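"""Membrane-topology consensus and substitution-to-domain mapping.

Works in 1-based, closed protein-coordinate intervals.  A consensus
topology is built by per-residue voting over several predictors' TM
intervals; ligand-binding-domain annotations are transferred between
proteins through a global pairwise alignment; nonsynonymous substitution
sites are mapped onto domains for enrichment and spatial-profile
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .selstats import TestResult, chisq_gof

__all__ = [
    "TopologyAnnotation",
    "SubstitutionSite",
    "consensus_topology",
    "transfer_lbd",
    "domain_fraction",
    "map_substitutions",
    "lbd_enrichment",
    "spatial_profile",
    "canonical_domain_order",
]


@dataclass(frozen=True)
class TopologyAnnotation:
    """Ordered non-overlapping labelled intervals along one protein."""

    protein_id: str
    length: int
    intervals: tuple  # of (start, end, label), 1-based closed
    predictor: str = "unknown"

    def __post_init__(self):
        prev_end = 0
        for start, end, _label in self.intervals:
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"interval ({start},{end}) outside [1,{self.length}]")
            if start <= prev_end:
                raise ValueError("intervals overlap or are unsorted")
            prev_end = end

    def tm_mask(self) -> np.ndarray:
        """Boolean per-residue membrane membership (labels starting 'TM')."""
        mask = np.zeros(self.length, dtype=bool)
        for start, end, label in self.intervals:
            if label.startswith("TM"):
                mask[start - 1 : end] = True
        return mask

    def label_at(self, residue: int) -> str | None:
        for start, end, label in self.intervals:
            if start <= residue <= end:
                return label
        return None


@dataclass(frozen=True)
class SubstitutionSite:
    """A nonsynonymous substitution mapped to a protein residue."""

    protein_id: str
    residue_pos: int
    source_gene: str = ""
    effect: str = "nonsyn"


def _loop_label(after_tm: int) -> str:
    # Intracellular N-terminus convention: loops alternate EL1, IL1, EL2 ...
    if after_tm % 2 == 1:
        return f"EL{(after_tm + 1) // 2}"
    return f"IL{after_tm // 2}"


def _fill_topology(protein_id, length, tm_intervals, predictor) -> TopologyAnnotation:
    """TM intervals -> full annotation with IN/EL/IL/EC filler segments."""
    intervals = []
    prev_end = 0
    for k, (start, end) in enumerate(tm_intervals, start=1):
        if start > prev_end + 1:
            label = "IN" if k == 1 else _loop_label(k - 1)
            intervals.append((prev_end + 1, start - 1, label))
        intervals.append((start, end, f"TM{k}"))
        prev_end = end
    if prev_end < length:
        label = "IN" if not tm_intervals else "EC"
        intervals.append((prev_end + 1, length, label))
    return TopologyAnnotation(protein_id, length, tuple(intervals), predictor)


def consensus_topology(annotations, min_support: int = 2) -> TopologyAnnotation:
    """Per-residue majority vote over several predictors' TM calls.

    A residue is consensus-TM when at least ``min_support`` predictors
    place it inside a TM interval; maximal runs become TM1.. numbered from
    the N-terminus and the gaps are labelled IN / EL / IL / EC.
    """
    annotations = list(annotations)
    if len(annotations) < min_support:
        raise ValueError(f"need at least {min_support} annotations, got {len(annotations)}")
    ids = {a.protein_id for a in annotations}
    lengths = {a.length for a in annotations}
    if len(ids) > 1 or len(lengths) > 1:
        raise ValueError("annotations refer to different proteins")
    length = annotations[0].length
    votes = np.zeros(length, dtype=int)
    for a in annotations:
        votes += a.tm_mask()
    mask = votes >= min_support
    tm_intervals = []
    i = 0
    while i < length:
        if mask[i]:
            j = i
            while j + 1 < length and mask[j + 1]:
                j += 1
            tm_intervals.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return _fill_topology(annotations[0].protein_id, length, tm_intervals, "consensus")


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def transfer_lbd(query: str, reference: str, reference_intervals,
                 query_id: str = "query") -> tuple[TopologyAnnotation, float, bool]:
    """Project labelled reference intervals onto a query protein.

    A global affine-gap BLOSUM62 alignment maps reference coordinates to
    query coordinates; reference residues aligned to gaps contract the
    interval.  Returns the projected annotation, the alignment identity
    (matches over alignment columns) and a low-identity warning flag
    (identity < 0.15).
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    aligner = _protein_aligner()
    alignment = aligner.align(reference, query)[0]
    ref_blocks, query_blocks = alignment.aligned
    ref_to_query = {}
    matches = 0
    columns = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        for offset in range(re_ - rs):
            ref_to_query[rs + offset] = qs + offset
            columns += 1
            if reference[rs + offset] == query[qs + offset]:
                matches += 1
    total_columns = len(reference) + len(query) - columns  # gaps count as columns
    identity = matches / total_columns if total_columns else 0.0

    projected = []
    for start, end, label in reference_intervals:
        hits = [ref_to_query[p] for p in range(start - 1, end) if p in ref_to_query]
        if not hits:
            continue
        projected.append((min(hits) + 1, max(hits) + 1, label))
    projected.sort()
    annotation = TopologyAnnotation(query_id, len(query), tuple(projected), "transfer")
    return annotation, identity, identity < 0.15


def domain_fraction(topology: TopologyAnnotation, labels) -> float:
    """Fraction of the protein covered by intervals with the given labels.

    Label matching accepts exact names and bare prefixes ('TM' matches
    TM1..TM7).
    """
    labels = set(labels)
    covered = 0
    for start, end, label in topology.intervals:
        if label in labels or any(label.startswith(l) for l in labels if l == "TM"):
            covered += end - start + 1
    return covered / topology.length


def map_substitutions(sites, topology: TopologyAnnotation, lbd_labels=None):
    """Assign each substitution site to its containing domain.

    Returns ``(counts, assignments)`` where ``counts`` maps domain label
    to substitution count and ``assignments`` is a list of
    ``(site, label, in_lbd, flagged)``.  Sites falling into an annotation
    gap take the nearest flanking non-TM label and are flagged.  By
    default the ligand-binding labels are the TM domains when the
    topology has any, otherwise S1/S2.
    """
    if lbd_labels is None:
        has_tm = any(lab.startswith("TM") for _s, _e, lab in topology.intervals)
        lbd_labels = {"TM"} if has_tm else {"S1", "S2"}

    def is_lbd(label):
        return label in lbd_labels or ("TM" in lbd_labels and label.startswith("TM"))

    counts: dict[str, int] = {}
    assignments = []
    for site in sites:
        if site.residue_pos > topology.length or site.residue_pos < 1:
            raise ValueError(
                f"residue {site.residue_pos} outside protein of length {topology.length}"
            )
        label = topology.label_at(site.residue_pos)
        flagged = False
        if label is None:
            flagged = True
            best = None
            for start, end, lab in topology.intervals:
                if lab.startswith("TM"):
                    continue
                dist = min(abs(site.residue_pos - start), abs(site.residue_pos - end))
                if best is None or dist < best[0]:
                    best = (dist, lab)
            label = best[1] if best else "IN"
        counts[label] = counts.get(label, 0) + 1
        assignments.append((site, label, is_lbd(label), flagged))
    return counts, assignments


def lbd_enrichment(per_gene) -> TestResult:
    """Pooled goodness-of-fit test for substitutions inside binding domains.

    ``per_gene`` holds ``(n_sites, n_in_lbd, lbd_fraction)`` triples; the
    observed in-domain count is pooled across genes and compared against
    an expected fraction equal to the unweighted mean of the per-gene
    domain fractions.
    """
    per_gene = list(per_gene)
    if not per_gene:
        raise ValueError("no genes supplied")
    total = sum(n for n, _k, _f in per_gene)
    in_lbd = sum(k for _n, k, _f in per_gene)
    fractions = [f for _n, _k, f in per_gene]
    if any(not (0.0 < f < 1.0) for f in fractions):
        raise ValueError("domain fractions must lie in (0, 1)")
    if total == 0:
        raise ValueError("no substitutions to test")
    expected_fraction = float(np.mean(fractions))
    return chisq_gof(in_lbd, total, expected_fraction)


def canonical_domain_order(n_tm: int = 7) -> list[str]:
    """IN, TM1, EL1, TM2, IL1, ..., TMn, EC — the 15-domain order for n=7."""
    order = ["IN"]
    for k in range(1, n_tm + 1):
        order.append(f"TM{k}")
        if k < n_tm:
            order.append(_loop_label(k))
    order.append("EC")
    return order


@dataclass
class SpatialProfile:
    labels: list
    counts: list
    n_half: int
    c_half: int


def spatial_profile(sites, topology: TopologyAnnotation) -> SpatialProfile:
    """Ordered per-domain substitution histogram plus an N/C-half split."""
    sites = list(sites)
    n_tm = sum(1 for _s, _e, lab in topology.intervals if lab.startswith("TM"))
    order = canonical_domain_order(n_tm) if n_tm else [lab for _s, _e, lab in topology.intervals]
    domain_counts, assignments = map_substitutions(sites, topology)
    counts = [domain_counts.get(label, 0) for label in order]
    midpoint = topology.length / 2.0
    n_half = sum(1 for site in sites if site.residue_pos <= midpoint)
    return SpatialProfile(order, counts, n_half, len(sites) - n_half)
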