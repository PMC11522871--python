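"""Sequence and table I/O: FASTA/FASTQ streaming, results and truth TSVs.

Formats are sniffed from content rather than file extensions: gzip by its
magic bytes, FASTA vs FASTQ by the first non-blank character.  Qualities
are read and discarded — the classifier is quality-agnostic.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .errors import MnbcError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "read_id",
    "status",
    "species",
    "best_score",
    "num_candidates",
    "shared_fraction_best",
    "reason",
]

TRUTH_COLUMNS = ["read_id", "genome_id", "label"]


@dataclass
class ReadRecord:
    """One query read; quality is carried but never used in scoring."""

    read_id: str
    sequence: str
    quality: str | None = None


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed file as text (gzip sniffed by magic)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def sniff_format(handle: IO[str]) -> str:
    """Peek at a text stream and decide FASTA vs FASTQ."""
    pos = handle.tell()
    first = ""
    for line in handle:
        if line.strip():
            first = line.lstrip()[0]
            break
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise MnbcError("cannot determine sequence format: expected '>' (FASTA) or '@' (FASTQ)")


def read_sequences(path: str | Path) -> Iterator[ReadRecord]:
    """Stream records from a FASTA or FASTQ file, optionally gzipped.

    Record ids are taken up to the first whitespace.  Memory use is
    constant in the number of records.
    """
    handle = _open_text(path)
    try:
        fmt = sniff_format(handle)
        for rec in SeqIO.parse(handle, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield ReadRecord(read_id=rec.id, sequence=str(rec.seq), quality=qual)
    finally:
        handle.close()


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id}\n{rec.sequence}\n")


def write_results(results: Iterable, path: str | Path) -> int:
    """Write classification results as a TSV; returns the row count.

    `results` is an iterable of :class:`mnbc.classify.ReadClassification`.
    Input order is preserved; unclassified rows carry an empty species and
    a reason code.
    """
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for res in results:
            fh.write(
                "\t".join(
                    [
                        res.read_id,
                        res.status,
                        res.species,
                        f"{res.best_score:.6f}" if res.best_score is not None else "",
                        str(len(res.candidate_genomes)),
                        f"{res.shared_fraction_best:.6f}"
                        if res.shared_fraction_best is not None
                        else "",
                        res.reason,
                    ]
                )
                + "\n"
            )
            n += 1
    logger.info("wrote %d result rows to %s", n, path)
    return n


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (string ids, empty-safe)."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "species": str, "reason": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise MnbcError(f"results file {path} missing columns: {sorted(missing)}")
    df["species"] = df["species"].fillna("")
    return df


def write_truth(rows: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write a truth table TSV: read_id, source genome_id, positive|negative."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for read_id, genome_id, label in rows:
            fh.write(f"{read_id}\t{genome_id}\t{label}\n")


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise MnbcError(f"truth file {path} missing columns: {sorted(missing)}")
    return df
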