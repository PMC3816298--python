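"""Sequence and table I/O: FASTA/FASTQ in, TSV/newick out."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .counting import SequenceRecord


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def _sniff_format(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA (or FASTQ, by extension) into SequenceRecords.

    Record order is preserved and residues are uppercased. Plain or gzipped
    files are accepted. Duplicate ids and leading junk before the first
    header are rejected; FASTQ quality strings are discarded.
    """
    fmt = _sniff_format(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        if fmt == "fasta":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA — line {lineno} precedes any '>' header"
                    )
                break
            fh.seek(0)
        for rec in SeqIO.parse(fh, fmt):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(
                id=rec.id, residues=str(rec.seq), description=rec.description,
            ))
    if not records:
        raise ValueError(f"{path}: no sequence records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_motif_list(path) -> list[str]:
    """Plain-text motif list: one uppercase motif per line, '#' comments allowed."""
    motifs: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            text = line.split("#", 1)[0].strip()
            if text:
                motifs.append(text.upper())
    return motifs


def read_truth_table(path) -> dict[str, str]:
    """Read a fragment_id -> parent_id truth TSV written by the simulator."""
    truth: dict[str, str] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.startswith("fragment_id"):
            raise ValueError(f"{path}: expected a 'fragment_id\\tparent_id' header")
        for line in fh:
            if not line.strip():
                continue
            frag, parent = line.rstrip("\n").split("\t")[:2]
            truth[frag] = parent
    return truth
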