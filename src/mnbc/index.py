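"""Per-genome minimizer indexes, the taxonomy table, and the database.

The reference database is deliberately simple: one plain-text index file
per genome (its id, k, total k-mer count and sorted unique minimizer
hashes) plus an 8-column taxonomy TSV.  Because every index file is an
independent unit, genomes can be added to or removed from a database
without touching any other file, and database building parallelises
trivially with bit-identical results.

Database directory layout::

    <dir>/indexes/<genome_id>.idx
    <dir>/taxonomy.tsv
    <dir>/meta.tsv
"""

from __future__ import annotations

import datetime
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kmer
from .errors import DatabaseError, GenomeTooShortError, IndexFormatError, TaxonomyError
from .io import read_sequences

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "family", "order", "class", "phylum", "domain")
TAXONOMY_COLUMNS = ("genome_id",) + RANKS


@dataclass(frozen=True)
class Lineage:
    """A 7-rank lineage from species up to domain.

    Species must be non-empty; higher ranks may be empty strings, which
    the evaluator reports as unranked.
    """

    species: str
    genus: str = ""
    family: str = ""
    order: str = ""
    class_: str = ""
    phylum: str = ""
    domain: str = ""

    def taxon_at(self, rank: str) -> str:
        if rank == "class":
            return self.class_
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return getattr(self, rank)

    def as_row(self) -> list[str]:
        return [self.taxon_at(r) for r in RANKS]


@dataclass
class GenomeIndex:
    """One genome's id, total k-mer count count(Gi) and unique minimizers.

    ``minimizers`` is a sorted int64 array of hash values; ``total_kmer_count``
    counts valid all-ACGT k-mer positions on one strand (the denominator of
    the present-minimizer score term), so it is independent of minimizer
    deduplication.
    """

    genome_id: str
    k: int
    total_kmer_count: int
    minimizers: np.ndarray

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeIndex)
            and self.genome_id == other.genome_id
            and self.k == other.k
            and self.total_kmer_count == other.total_kmer_count
            and np.array_equal(self.minimizers, other.minimizers)
        )


def build_genome_index(genome_id: str, records: Sequence[str], k: int) -> GenomeIndex:
    """Index a genome from its sequence records.

    Minimizers are the union over records (each record gets its own end
    windows: contigs are independent sequences); the total k-mer count is
    the sum of valid k-mer positions over records.
    """
    if not any(len(r) >= k for r in records):
        raise GenomeTooShortError(
            f"genome {genome_id!r}: no record of length >= k={k}"
        )
    parts = []
    total = 0
    for rec in records:
        hashes, valid = kmer.canonical_hash_array(rec, k)
        total += int(valid.sum())
        if hashes.size:
            parts.append(kmer.minimizer_array(rec, k))
    mins = np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
    if total < 1 or mins.size < 1:
        raise GenomeTooShortError(
            f"genome {genome_id!r}: no valid (all-ACGT) k-mer of length {k}"
        )
    return GenomeIndex(genome_id=genome_id, k=k, total_kmer_count=total, minimizers=mins)


def write_index(index: GenomeIndex, path: str | Path) -> Path:
    """Write a self-describing plain-text index file (hashes sorted ascending)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#genome_id\t{index.genome_id}\n")
        fh.write(f"#k\t{index.k}\n")
        fh.write(f"#total_kmers\t{index.total_kmer_count}\n")
        fh.write(f"#num_minimizers\t{index.minimizers.size}\n")
        fh.write("\n".join(str(int(h)) for h in index.minimizers))
        if index.minimizers.size:
            fh.write("\n")
    return path


def read_index(path: str | Path) -> GenomeIndex:
    """Parse an index file, validating the header and every hash line.

    Unsorted hash lists are accepted but re-sorted with a logged warning;
    malformed lines raise :class:`IndexFormatError` naming the line.
    """
    path = Path(path)
    header: dict[str, str] = {}
    hashes: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].split("\t", 1)
                except ValueError:
                    raise IndexFormatError(f"{path}:{lineno}: malformed header line {line!r}")
                header[key] = value
            else:
                try:
                    hashes.append(int(line))
                except ValueError:
                    raise IndexFormatError(f"{path}:{lineno}: non-numeric hash line {line!r}")
    for key in ("genome_id", "k", "total_kmers", "num_minimizers"):
        if key not in header:
            raise IndexFormatError(f"{path}: missing header field #{key}")
    try:
        k = int(header["k"])
        total = int(header["total_kmers"])
        n = int(header["num_minimizers"])
    except ValueError as exc:
        raise IndexFormatError(f"{path}: non-numeric header value ({exc})")
    if n != len(hashes):
        raise IndexFormatError(
            f"{path}: header declares {n} minimizers but file has {len(hashes)}"
        )
    arr = np.asarray(hashes, dtype=np.int64)
    if arr.size and np.any(np.diff(arr) < 0):
        logger.warning("index file %s not sorted ascending; re-sorting", path)
        arr = np.unique(arr)
    return GenomeIndex(
        genome_id=header["genome_id"], k=k, total_kmer_count=total, minimizers=arr
    )


def load_taxonomy(tsv_path: str | Path) -> dict[str, Lineage]:
    """Load the genome_id -> lineage table from an 8-column TSV."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise TaxonomyError(f"taxonomy {tsv_path} missing columns: {sorted(missing)}")
    dupes = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dupes:
        raise TaxonomyError(f"duplicate genome_id in taxonomy: {sorted(set(dupes))}")
    out: dict[str, Lineage] = {}
    for _, row in df.iterrows():
        if not row["species"]:
            raise TaxonomyError(f"genome {row['genome_id']!r}: empty species")
        out[row["genome_id"]] = Lineage(
            species=row["species"],
            genus=row["genus"],
            family=row["family"],
            order=row["order"],
            class_=row["class"],
            phylum=row["phylum"],
            domain=row["domain"],
        )
    return out


def write_taxonomy(taxonomy: dict[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAXONOMY_COLUMNS) + "\n")
        for gid in sorted(taxonomy):
            fh.write("\t".join([gid] + taxonomy[gid].as_row()) + "\n")


def genome_id_from_path(path: str | Path) -> str:
    """Genome id = file stem with sequence/compression suffixes stripped."""
    name = Path(path).name
    for suf in (".gz", ".fasta", ".fa", ".fna"):
        if name.endswith(suf):
            name = name[: -len(suf)]
    return name


@dataclass
class Database:
    """A directory-backed reference database held in memory for classification."""

    k: int
    indexes: dict[str, GenomeIndex] = field(default_factory=dict)
    taxonomy: dict[str, Lineage] = field(default_factory=dict)
    path: Path | None = None

    def __post_init__(self):
        for gid, idx in self.indexes.items():
            if idx.k != self.k:
                raise DatabaseError(f"genome {gid!r} indexed with k={idx.k}, database k={self.k}")
            if gid not in self.taxonomy:
                raise DatabaseError(f"genome {gid!r} has no taxonomy entry")

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.indexes)

    def max_kmer_count(self) -> int:
        return max(idx.total_kmer_count for idx in self.indexes.values())

    @classmethod
    def load(cls, path: str | Path) -> "Database":
        path = Path(path)
        taxonomy = load_taxonomy(path / "taxonomy.tsv")
        indexes: dict[str, GenomeIndex] = {}
        k = None
        for idx_file in sorted((path / "indexes").glob("*.idx")):
            idx = read_index(idx_file)
            if idx.genome_id in indexes:
                raise DatabaseError(f"duplicate genome_id {idx.genome_id!r}")
            if k is None:
                k = idx.k
            indexes[idx.genome_id] = idx
        if k is None:
            raise DatabaseError(f"no index files found under {path / 'indexes'}")
        return cls(k=k, indexes=indexes, taxonomy=taxonomy, path=path)


def _filter_records(records: Iterable, min_record_length: int) -> list[str]:
    return [r.sequence for r in records if len(r.sequence) >= min_record_length]


def _write_meta(db: Database) -> None:
    assert db.path is not None
    with open(db.path / "meta.tsv", "w") as fh:
        fh.write("k\tgenome_count\tbuild_date\n")
        fh.write(f"{db.k}\t{len(db.indexes)}\t{datetime.date.today().isoformat()}\n")


def build_database(
    genome_files: Sequence[str | Path],
    taxonomy_file: str | Path,
    k: int,
    out_dir: str | Path,
    *,
    min_record_length: int = 0,
    workers: int = 1,
) -> Database:
    """Build a database directory from genome FASTAs and a taxonomy TSV.

    Each genome is an independent unit of work, so the result is
    byte-identical for any ``workers`` count or input file order.
    ``min_record_length`` optionally drops short records (e.g. plasmids)
    before indexing; the default keeps everything.
    """
    taxonomy = load_taxonomy(taxonomy_file)
    ids = [genome_id_from_path(p) for p in genome_files]
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise DatabaseError(f"duplicate genome ids among inputs: {sorted(dupes)}")
    missing = [g for g in ids if g not in taxonomy]
    if missing:
        raise TaxonomyError(f"genomes without a taxonomy row: {sorted(missing)}")

    out_dir = Path(out_dir)
    (out_dir / "indexes").mkdir(parents=True, exist_ok=True)

    def _build(item: tuple[str, str | Path]) -> GenomeIndex:
        gid, path = item
        records = _filter_records(read_sequences(path), min_record_length)
        return build_genome_index(gid, records, k)

    jobs = sorted(zip(ids, genome_files))
    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            built = list(pool.map(_build, jobs))
    else:
        built = [_build(j) for j in jobs]

    indexes = {}
    for idx in built:
        write_index(idx, out_dir / "indexes" / f"{idx.genome_id}.idx")
        indexes[idx.genome_id] = idx
    db = Database(
        k=k,
        indexes=indexes,
        taxonomy={g: taxonomy[g] for g in indexes},
        path=out_dir,
    )
    write_taxonomy(db.taxonomy, out_dir / "taxonomy.tsv")
    _write_meta(db)
    logger.info("built database with %d genomes at %s", len(indexes), out_dir)
    return db


def add_genome(db: Database, genome_file: str | Path, lineage: Lineage) -> Database:
    """Plug a genome into an existing database; no other index is touched."""
    gid = genome_id_from_path(genome_file)
    if gid in db.indexes:
        raise DatabaseError(f"genome {gid!r} already in database")
    records = [r.sequence for r in read_sequences(genome_file)]
    idx = build_genome_index(gid, records, db.k)
    indexes = dict(db.indexes)
    indexes[gid] = idx
    taxonomy = dict(db.taxonomy)
    taxonomy[gid] = lineage
    new_db = replace(db, indexes=indexes, taxonomy=taxonomy)
    if db.path is not None:
        write_index(idx, db.path / "indexes" / f"{gid}.idx")
        write_taxonomy(taxonomy, db.path / "taxonomy.tsv")
        _write_meta(new_db)
    return new_db


def remove_genome(db: Database, genome_id: str) -> Database:
    """Unplug a genome from a database by dropping its index file."""
    if genome_id not in db.indexes:
        raise DatabaseError(f"genome {genome_id!r} not in database")
    indexes = dict(db.indexes)
    del indexes[genome_id]
    if not indexes:
        raise DatabaseError("cannot remove the last genome of a database")
    taxonomy = dict(db.taxonomy)
    del taxonomy[genome_id]
    new_db = replace(db, indexes=indexes, taxonomy=taxonomy)
    if db.path is not None:
        idx_file = db.path / "indexes" / f"{genome_id}.idx"
        if idx_file.exists():
            idx_file.unlink()
        write_taxonomy(taxonomy, db.path / "taxonomy.tsv")
        _write_meta(new_db)
    return new_db
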