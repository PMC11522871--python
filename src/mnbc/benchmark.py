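"""Benchmarking framework: strain holdout, coverage-based fragment
simulation, synthetic fixture communities and per-rank evaluation.

The workflow mirrors the standard way read classifiers are benchmarked:

1. split strains of each multi-strain species into train / held-out test
   genomes;
2. build a database from the training genomes;
3. simulate "positive" reads as error-free random fragments of the test
   genomes at low coverage (default 0.05), and "negative" reads the same
   way from a genome absent from the database;
4. classify everything and score per-rank precision/recall on positives
   and the unclassified rate (accuracy) on negatives.

Fragments are exact substrings (or reverse complements of substrings) of
their source genome: no sequencing-error model is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MnbcError
from .index import RANKS, Lineage, write_taxonomy
from .io import ReadRecord

logger = logging.getLogger(__name__)


@dataclass
class SimulationParams:
    """Fragment-simulation settings.

    ``coverage`` is the expected sequencing depth (0.05 by default, i.e.
    fragments totalling ~5% of the genome).  Fixed-length mode uses
    ``read_length``; variable-length mode draws from a truncated
    Normal(length_mean, length_sd) clipped to [length_min, length_max]
    (defaults 5500/1500/1000/10000 bp, emulating long-read length spread).
    """

    coverage: float = 0.05
    read_length: int = 150
    length_mean: float = 5500.0
    length_sd: float = 1500.0
    length_min: int = 1000
    length_max: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise MnbcError("coverage must be positive")
        if not self.length_min <= self.length_mean <= self.length_max:
            raise MnbcError("need length_min <= length_mean <= length_max")


def split_train_test(
    strains_by_species: dict[str, Sequence[str]],
    fraction: float,
    rng: np.random.Generator,
) -> tuple[set[str], set[str]]:
    """Hold out ceil(fraction*T) strains per species with T >= 2 strains.

    Species with a single strain contribute it to training only (they
    cannot be both referenced and tested).  Selection is deterministic
    given the generator state; species are visited in sorted order.
    """
    if not strains_by_species:
        raise MnbcError("split_train_test: empty input")
    if not 0.0 < fraction < 1.0:
        raise MnbcError(f"fraction must be in (0, 1), got {fraction}")
    train: set[str] = set()
    test: set[str] = set()
    for species in sorted(strains_by_species):
        strains = sorted(strains_by_species[species])
        if len(strains) < 2:
            train.update(strains)
            continue
        n_test = math.ceil(fraction * len(strains))
        picked = rng.choice(len(strains), size=n_test, replace=False)
        picked_set = {strains[i] for i in picked}
        test.update(picked_set)
        train.update(s for s in strains if s not in picked_set)
    return train, test


def fragment_count(genome_length: int, coverage: float, fragment_length: int) -> int:
    """Number of fragments at a target coverage: ceil(cov * L / frag_len)."""
    if genome_length <= 0 or coverage <= 0 or fragment_length <= 0:
        raise MnbcError("fragment_count arguments must be positive")
    if fragment_length > genome_length:
        logger.warning(
            "fragment length %d exceeds genome length %d; no fragments",
            fragment_length,
            genome_length,
        )
        return 0
    return math.ceil(coverage * genome_length / fragment_length)


def _usable(records: Sequence[tuple[str, str]], length: int) -> tuple[list[int], int]:
    """Per-record count of valid start positions for a fragment length."""
    starts = [max(len(seq) - length + 1, 0) for _, seq in records]
    total_len = sum(len(seq) for _, seq in records if len(seq) >= length)
    return starts, total_len


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _draw_fragment(
    records: Sequence[tuple[str, str]],
    starts: Sequence[int],
    length: int,
    rng: np.random.Generator,
) -> tuple[str, int, str, str]:
    """Pick (record, start, strand) uniformly over valid placements."""
    weights = np.asarray(starts, dtype=float)
    rec_i = int(rng.choice(len(records), p=weights / weights.sum()))
    rec_id, seq = records[rec_i]
    start = int(rng.integers(starts[rec_i]))
    frag = seq[start : start + length]
    strand = "+" if rng.integers(2) == 0 else "-"
    if strand == "-":
        frag = frag.translate(_RC)[::-1]
    return rec_id, start, strand, frag


def simulate_fixed_length_reads(
    records: Sequence[tuple[str, str]],
    genome_id: str,
    length: int,
    params: SimulationParams,
    rng: np.random.Generator,
    label: str = "positive",
) -> tuple[list[ReadRecord], list[tuple[str, str, str]]]:
    """Error-free random fragments of fixed length at the target coverage.

    Records are chosen with probability proportional to their number of
    valid start positions, starts uniformly, strands uniformly.  Read ids
    encode provenance (genome, record, start, strand).
    """
    starts, total_len = _usable(records, length)
    if total_len == 0:
        raise MnbcError(f"{genome_id}: no record of length >= {length}")
    n = fragment_count(total_len, params.coverage, length)
    reads, truth = [], []
    for i in range(n):
        rec_id, start, strand, frag = _draw_fragment(records, starts, length, rng)
        rid = f"{genome_id}|{i}|{rec_id}:{start}:{strand}"
        reads.append(ReadRecord(read_id=rid, sequence=frag))
        truth.append((rid, genome_id if label == "positive" else "", label))
    return reads, truth


def simulate_variable_length_reads(
    records: Sequence[tuple[str, str]],
    genome_id: str,
    params: SimulationParams,
    rng: np.random.Generator,
    label: str = "positive",
) -> tuple[list[ReadRecord], list[tuple[str, str, str]]]:
    """Fragments with truncated-Normal lengths at the target coverage.

    The fragment count is computed at the distribution mean; each length
    is drawn from Normal(length_mean, length_sd) truncated to
    [length_min, length_max] and rounded to whole bases.  Genomes shorter
    than a drawn length get it capped to the longest record (warned).
    """
    longest = max(len(seq) for _, seq in records)
    mean_len = int(round(params.length_mean))
    _, total_len = _usable(records, min(mean_len, longest))
    if total_len == 0:
        raise MnbcError(f"{genome_id}: empty records")
    n = fragment_count(total_len, params.coverage, mean_len)
    a = (params.length_min - params.length_mean) / params.length_sd
    b = (params.length_max - params.length_mean) / params.length_sd
    lengths = stats.truncnorm.rvs(
        a, b, loc=params.length_mean, scale=params.length_sd, size=n, random_state=rng
    )
    lengths = np.rint(lengths).astype(int)
    if longest < params.length_min:
        logger.warning(
            "%s: longest record (%d bp) shorter than length_min; capping", genome_id, longest
        )
    reads, truth = [], []
    for i, length in enumerate(lengths):
        length = int(min(length, longest))
        starts, _ = _usable(records, length)
        rec_id, start, strand, frag = _draw_fragment(records, starts, length, rng)
        rid = f"{genome_id}|{i}|{rec_id}:{start}:{strand}"
        reads.append(ReadRecord(read_id=rid, sequence=frag))
        truth.append((rid, genome_id if label == "positive" else "", label))
    return reads, truth


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """An i.i.d. uniform ACGT sequence."""
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point substitutions at a per-base rate; substituted bases differ
    from the original."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("latin-1"), dtype=np.uint8).copy()
    code = np.zeros(arr.size, dtype=np.int64)
    for b, c in zip(b"ACGT", range(4)):
        code[arr == b] = c
    hit = rng.random(arr.size) < rate
    shift = rng.integers(1, 4, size=arr.size)
    code = np.where(hit, (code + shift) % 4, code)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[code].tobytes().decode("latin-1")


def synthetic_lineage(species_idx: int) -> Lineage:
    """Deterministic synthetic hierarchy: 2 species per genus, 2 genera
    per family, and so on, so every rank is exercised in evaluation."""
    i = species_idx
    return Lineage(
        species=f"Species_{i:03d}",
        genus=f"Genus_{i // 2:03d}",
        family=f"Family_{i // 4:03d}",
        order=f"Order_{i // 8:03d}",
        class_=f"Class_{i // 16:03d}",
        phylum=f"Phylum_{i // 32:03d}",
        domain="Bacteria",
    )


def generate_synthetic_genomes(
    n_species: int,
    strains_per_species: int,
    genome_length: int,
    strain_divergence: float,
    rng: np.random.Generator,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], dict[str, Lineage]]:
    """A synthetic community standing in for a real reference collection.

    Each species gets an i.i.d. random ACGT ancestor; strains are copies
    of the ancestor with point substitutions at ``strain_divergence`` per
    base.  Returns (genome_id -> sequence, genome_id -> lineage); if
    ``out_dir`` is given, one FASTA per genome plus ``taxonomy.tsv`` are
    also written there.
    """
    if not 0.0 <= strain_divergence < 1.0:
        raise MnbcError("strain_divergence must be in [0, 1)")
    genomes: dict[str, str] = {}
    taxonomy: dict[str, Lineage] = {}
    for s in range(n_species):
        ancestor = random_sequence(genome_length, rng)
        lineage = synthetic_lineage(s)
        for t in range(strains_per_species):
            gid = f"sp{s:03d}_st{t}"
            genomes[gid] = _mutate(ancestor, strain_divergence, rng)
            taxonomy[gid] = lineage
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for gid, seq in genomes.items():
            with open(out_dir / f"{gid}.fasta", "w") as fh:
                fh.write(f">{gid}\n{seq}\n")
        write_taxonomy(taxonomy, out_dir / "taxonomy.tsv")
    return genomes, taxonomy


@dataclass
class EvaluationReport:
    """Per-rank precision/recall on positive reads plus negative accuracy.

    All values are percentages in [0, 100].  Precision at a rank counts
    reads whose predicted species agrees with the true source at that
    rank, among classified positives; recall uses all positives as the
    denominator, so recall = precision * (classified / total) holds
    identically per rank.
    """

    precision: dict[str, float] = field(default_factory=dict)
    recall: dict[str, float] = field(default_factory=dict)
    percent_unclassified_positives: float = 0.0
    negative_accuracy: float = float("nan")
    n_positive: int = 0
    n_negative: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"level": lv, "precision": self.precision[lv], "recall": self.recall[lv]}
            for lv in RANKS
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df["percent_unclassified_positives"] = self.percent_unclassified_positives
        df["negative_accuracy"] = self.negative_accuracy
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def evaluate(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    taxonomy: dict[str, Lineage],
) -> EvaluationReport:
    """Score a results table against its truth table.

    A positive read is correct at rank r when its predicted species'
    ancestor at r equals the source genome's ancestor at r and neither
    is empty (an empty taxon is unranked and never counts as correct).
    Negative accuracy is the percentage of negative reads left
    unclassified.
    """
    truth_map = {row.read_id: row for row in truth.itertuples()}
    unknown = [rid for rid in results["read_id"] if rid not in truth_map]
    if unknown:
        raise MnbcError(f"reads in results but not in truth: {unknown[:5]}")

    species_lineage: dict[str, Lineage] = {}
    for lin in taxonomy.values():
        species_lineage.setdefault(lin.species, lin)

    n_pos = n_neg = 0
    n_pos_classified = 0
    n_neg_unclassified = 0
    correct = {lv: 0 for lv in RANKS}
    for row in results.itertuples():
        t = truth_map[row.read_id]
        if t.label == "negative":
            n_neg += 1
            if row.status == "unclassified":
                n_neg_unclassified += 1
            continue
        n_pos += 1
        if row.status != "classified":
            continue
        n_pos_classified += 1
        pred = species_lineage.get(row.species)
        if pred is None:
            raise MnbcError(f"predicted species {row.species!r} not in taxonomy")
        if t.genome_id not in taxonomy:
            raise MnbcError(f"truth genome {t.genome_id!r} not in taxonomy")
        true_lin = taxonomy[t.genome_id]
        for lv in RANKS:
            a, b = pred.taxon_at(lv), true_lin.taxon_at(lv)
            if a and a == b:
                correct[lv] += 1

    report = EvaluationReport(n_positive=n_pos, n_negative=n_neg)
    for lv in RANKS:
        report.precision[lv] = (
            100.0 * correct[lv] / n_pos_classified if n_pos_classified else 0.0
        )
        report.recall[lv] = 100.0 * correct[lv] / n_pos if n_pos else 0.0
    report.percent_unclassified_positives = (
        100.0 * (n_pos - n_pos_classified) / n_pos if n_pos else 0.0
    )
    report.negative_accuracy = (
        100.0 * n_neg_unclassified / n_neg if n_neg else float("nan")
    )
    return report


def strains_by_species(taxonomy: dict[str, Lineage]) -> dict[str, list[str]]:
    """Group genome ids by species name (helper for the holdout split)."""
    out: dict[str, list[str]] = {}
    for gid in sorted(taxonomy):
        out.setdefault(taxonomy[gid].species, []).append(gid)
    return out
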