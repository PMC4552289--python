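"""ORF extraction, annotation-quality metrics and orthology.

Covers start-to-stop ORF scanning over all six frames, completeness and
contiguity of candidate segments against a reference protein,
reciprocal-best-hit ortholog pairing on equal-length sequences, and an
iterative homology-discovery loop over a pluggable search backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "OrfRecord",
    "OrthologPair",
    "FAMILY_MIN_ORF_LEN",
    "find_orfs",
    "completeness_contiguity",
    "sequence_identity",
    "reciprocal_orthologs",
    "iterative_discovery",
    "make_alignment_search_fn",
]

# default minimum ORF lengths (nt) per gene family
FAMILY_MIN_ORF_LEN = {
    "OBP": 300,
    "CSP": 300,
    "OR": 900,
    "GR": 900,
    "IR": 900,
}

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame extracted from a transcript."""

    id: str
    parent_transcript: str
    strand: str  # + | -
    frame: int  # 0 | 1 | 2
    nt_sequence: str
    aa_sequence: str
    family_tag: str = "unknown"

    def __post_init__(self):
        if len(self.nt_sequence) % 3:
            raise ValueError("ORF length is not a multiple of 3")


@dataclass(frozen=True)
class OrthologPair:
    gene_id: str
    id_a: str
    id_b: str
    seq_a: str
    seq_b: str
    identity: float
    family_tag: str = "unknown"
    tie_flag: bool = False


def _scan_frame(seq: str, frame: int, min_len_nt: int, stop_to_stop: bool):
    """Yield (start0, end0_exclusive) of every qualifying ORF in one frame."""
    codon_starts = range(frame, len(seq) - 2, 3)
    codons = [seq[i : i + 3] for i in codon_starts]
    prev_stop = -1
    for ci, codon in enumerate(codons):
        if codon not in _STOPS:
            continue
        # all in-frame start codons (or the full stop-to-stop stretch)
        if stop_to_stop:
            begin = prev_stop + 1
            if begin < ci:
                yield frame + 3 * begin, frame + 3 * (ci + 1)
        else:
            for si in range(prev_stop + 1, ci):
                if codons[si] == "ATG":
                    length = 3 * (ci - si + 1)
                    if length >= min_len_nt:
                        yield frame + 3 * si, frame + 3 * (ci + 1)
        prev_stop = ci


def find_orfs(
    transcript: str,
    min_len_nt: int,
    transcript_id: str = "transcript",
    stop_to_stop: bool = False,
    family_tag: str = "unknown",
) -> list[OrfRecord]:
    """Every start-codon-to-stop ORF of at least ``min_len_nt`` over 6 frames.

    The reported length includes the stop codon.  ORFs containing ``N``
    are excluded.  Results are sorted by length descending, then id.
    With ``stop_to_stop`` the permissive stop-bounded variant is used.
    """
    if min_len_nt % 3:
        raise ValueError("min_len_nt must be a multiple of 3")
    transcript = transcript.upper().replace("U", "T")
    records = []
    for strand in "+-":
        seq = transcript if strand == "+" else str(Seq(transcript).reverse_complement())
        for frame in range(3):
            for start, end in _scan_frame(seq, frame, min_len_nt, stop_to_stop):
                nt = seq[start:end]
                if len(nt) < min_len_nt or "N" in nt:
                    continue
                aa = str(Seq(nt[:-3]).translate())
                if "*" in aa:  # stop-to-stop stretches may lack a start
                    continue
                orf_id = f"{transcript_id}|{strand}{frame}|{start + 1}-{end}"
                records.append(
                    OrfRecord(orf_id, transcript_id, strand, frame, nt, aa, family_tag)
                )
    records.sort(key=lambda r: (-len(r.nt_sequence), r.id))
    return records


def completeness_contiguity(candidate_segments, reference_length: int) -> tuple[float, float]:
    """Coverage of a reference by aligned segments, as percentages.

    ``candidate_segments`` holds 1-based closed (start, end) intervals in
    reference coordinates.  Completeness is the union coverage; contiguity
    is the coverage of the single longest segment.
    """
    if reference_length <= 0:
        raise ValueError("empty reference")
    covered = set()
    best = 0
    for start, end in candidate_segments:
        start = max(1, start)
        end = min(reference_length, end)
        if end < start:
            continue
        covered.update(range(start, end + 1))
        best = max(best, end - start + 1)
    return 100.0 * len(covered) / reference_length, 100.0 * best / reference_length


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Column-wise identity of two equal-length sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if not seq_a:
        raise ValueError("empty sequences")
    return sum(a == b for a, b in zip(seq_a, seq_b)) / len(seq_a)


def reciprocal_orthologs(set_a, set_b, min_identity: float = 0.95,
                         family_tag: str = "unknown"):
    """Reciprocal-best-identity pairs of identical length.

    ``set_a``/``set_b`` map record ids to sequences.  A pair is kept when
    each member is the other's best identity match among equal-length
    candidates and the identity reaches ``min_identity``.  Best-hit ties
    are broken by lexicographically smallest id and flagged.

    Returns ``(pairs, unpaired_a, unpaired_b)``.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")

    def best_hits(source, target):
        hits = {}
        for sid in sorted(source):
            best_score, best_tid, tie = -1.0, None, False
            for tid in sorted(target):
                if len(source[sid]) != len(target[tid]):
                    continue
                ident = sequence_identity(source[sid], target[tid])
                if ident > best_score:
                    best_score, best_tid, tie = ident, tid, False
                elif ident == best_score and best_tid is not None:
                    tie = True  # keep the lexicographically smaller id
            if best_tid is not None:
                hits[sid] = (best_tid, best_score, tie)
        return hits

    a_best = best_hits(set_a, set_b)
    b_best = best_hits(set_b, set_a)
    pairs = []
    paired_a, paired_b = set(), set()
    for id_a in sorted(a_best):
        id_b, ident, tie_a = a_best[id_a]
        back = b_best.get(id_b)
        if back is None or back[0] != id_a:
            continue
        if ident < min_identity:
            continue
        pairs.append(
            OrthologPair(
                gene_id=id_a,
                id_a=id_a,
                id_b=id_b,
                seq_a=set_a[id_a],
                seq_b=set_b[id_b],
                identity=ident,
                family_tag=family_tag,
                tie_flag=tie_a or back[2],
            )
        )
        paired_a.add(id_a)
        paired_b.add(id_b)
    unpaired_a = sorted(set(set_a) - paired_a)
    unpaired_b = sorted(set(set_b) - paired_b)
    return pairs, unpaired_a, unpaired_b


def make_alignment_search_fn():
    """Default offline search backend: translated local alignment.

    Scores every (query protein, transcript) pair by the best local
    BLOSUM62 affine-gap alignment of the query against the six frame
    translations of the transcript, returning raw alignment scores
    (higher is better).
    """
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"

    def six_frame(transcript: str):
        transcript = transcript.upper().replace("U", "T")
        rc = str(Seq(transcript).reverse_complement())
        for seq in (transcript, rc):
            for frame in range(3):
                sub = seq[frame:]
                sub = sub[: len(sub) - len(sub) % 3]
                if sub:
                    yield str(Seq(sub).translate())

    def search_fn(queries, transcripts):
        hits = []
        for tid in sorted(transcripts):
            frames = list(six_frame(transcripts[tid]))
            for qid in sorted(queries):
                query = queries[qid]
                score = 0.0
                for aa in frames:
                    try:
                        score = max(score, aligner.score(aa.replace("*", "X"), query))
                    except ValueError:
                        continue
                hits.append((qid, tid, float(score)))
        return hits

    return search_fn


def iterative_discovery(
    transcripts,
    seed_queries,
    search_fn,
    score_threshold: float,
    min_orf_len: int,
    max_iterations: int = 20,
    stop_to_stop: bool = False,
    family_tag: str = "unknown",
) -> list[OrfRecord]:
    """Search -> extract -> validate -> re-query until a fixed point.

    ``search_fn(queries, transcripts)`` returns ``(query_id,
    transcript_id, score)`` hits; transcripts hitting at or above
    ``score_threshold`` are scanned for ORFs of at least ``min_orf_len``,
    every new ORF's translation joins the query set, and the loop repeats
    until no new ORF appears.  The query set grows monotonically and is
    bounded, so termination is guaranteed; ``max_iterations`` guards a
    misbehaving backend.
    """
    queries = dict(seed_queries)
    found: dict[str, OrfRecord] = {}
    for _iteration in range(max_iterations):
        hits = search_fn(queries, transcripts)
        hit_transcripts = sorted(
            {tid for _qid, tid, score in hits if score >= score_threshold}
        )
        new = False
        for tid in hit_transcripts:
            for orf in find_orfs(
                transcripts[tid], min_orf_len, transcript_id=tid,
                stop_to_stop=stop_to_stop, family_tag=family_tag,
            ):
                if orf.id not in found:
                    found[orf.id] = orf
                    queries[f"orf:{orf.id}"] = orf.aa_sequence
                    new = True
        if not new:
            return sorted(found.values(), key=lambda r: (-len(r.nt_sequence), r.id))
    raise RuntimeError(f"discovery did not reach a fixed point in {max_iterations} iterations")
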