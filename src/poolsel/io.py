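"""Plain-text readers and writers for the pipeline's artifact formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .topodomains import TopologyAnnotation

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_topologies",
    "write_topologies",
]


def read_fasta(path) -> dict:
    """FASTA file -> ordered {id: sequence} (id is the first header token)."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """{id: sequence} or iterable of (id, sequence) -> FASTA file."""
    items = records.items() if hasattr(records, "items") else records
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for name, seq in items:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def read_topologies(path) -> dict:
    """Interval TSV -> {(protein_id, predictor): TopologyAnnotation}.

    Expects columns ``protein_id start end label predictor`` with 1-based
    closed intervals; protein length is taken as the largest end seen for
    that protein.
    """
    frame = pd.read_csv(path, sep="\t")
    lengths = frame.groupby("protein_id")["end"].max().to_dict()
    out = {}
    for (pid, predictor), sub in frame.groupby(["protein_id", "predictor"]):
        intervals = tuple(
            sorted((int(r.start), int(r.end), str(r.label)) for r in sub.itertuples())
        )
        out[(pid, predictor)] = TopologyAnnotation(
            pid, int(lengths[pid]), intervals, predictor
        )
    return out


def write_topologies(annotations, path) -> None:
    rows = []
    for ann in annotations:
        for start, end, label in ann.intervals:
            rows.append(
                {
                    "protein_id": ann.protein_id,
                    "start": start,
                    "end": end,
                    "label": label,
                    "predictor": ann.predictor,
                }
            )
    write_tsv(pd.DataFrame(rows, columns=["protein_id", "start", "end", "label", "predictor"]), path)
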