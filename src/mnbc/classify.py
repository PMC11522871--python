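"""Read classification: μ-cutoff rejection, penalised log-score, θ-gap
candidate selection and species plurality voting.

For a read R with U unique minimizers and a genome G with count(G) k-mer
positions, the score of G is::

    score(G) = sum over read minimizers z of
                   log(1 / count(G))   if z is in G's minimizer set
                   phi                 otherwise

i.e. a naive-Bayes log-likelihood in which every present minimizer
contributes one pseudo-occurrence and every absent minimizer contributes
a flat penalty ``phi`` (which must be smaller than ``log(1/count)`` of
the largest genome, or absence would not penalise).  Before scoring,
genomes sharing fewer than a fraction ``mu`` of the read's minimizers
(or none at all) are rejected; if every genome is rejected the read is
unclassified — this is how reads from organisms absent from the database
are recognised.  Surviving genomes are sorted by score and the candidate
set is extended downwards while the gap between consecutive distinct
score values stays within ``theta``; the species with the most candidate
genomes wins, ties broken by a seeded RNG.  ``theta = 0`` recovers the
plain argmax naive-Bayes rule.
"""

from __future__ import annotations

import math
import zlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from . import kmer
from .errors import ConfigurationError, TaxonomyError
from .index import Database, GenomeIndex, Lineage
from .io import ReadRecord

REASON_OK = "ok"
REASON_NO_MINIMIZERS = "no_minimizers"
REASON_BELOW_MU = "below_mu"


@dataclass
class ClassifierParams:
    """Tuning surface of the classifier.

    k: k-mer length (15 by default; hashes then fit 4-byte unsigned ints).
    mu: minimum shared-minimizer fraction for a genome to stay a candidate.
    phi: negative per-minimizer penalty for absence.
    theta: maximum gap between consecutive distinct sorted scores.
    seed: global seed from which per-read tie-break RNGs are derived.
    log_base: base of the score logarithm (natural log by default; phi and
        theta defaults are calibrated for whichever base is in use).
    """

    k: int = 15
    mu: float = 0.35
    phi: float = -2000.0
    theta: float = 1500.0
    seed: int = 0
    log_base: float = math.e

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigurationError(f"mu must be in [0, 1], got {self.mu}")
        if self.phi >= 0:
            raise ConfigurationError(f"phi must be negative, got {self.phi}")
        if self.theta < 0:
            raise ConfigurationError(f"theta must be >= 0, got {self.theta}")
        if self.k < 1:
            raise ConfigurationError(f"k must be positive, got {self.k}")
        if self.log_base <= 1.0:
            raise ConfigurationError(f"log_base must exceed 1, got {self.log_base}")


@dataclass
class ReadClassification:
    """Per-read verdict: a species (plus diagnostics) or unclassified."""

    read_id: str
    status: str  # "classified" | "unclassified"
    species: str = ""
    best_score: float | None = None
    candidate_genomes: list[str] = field(default_factory=list)
    shared_fraction_best: float | None = None
    reason: str = REASON_OK


def read_minimizers(read_sequence: str, k: int) -> set[int]:
    """Unique minimizer hashes of a read; identical procedure to genomes
    (end windows included).  Empty set when the read is shorter than k."""
    return kmer.extract_minimizers(read_sequence, k)


def shared_fraction(read_mins: set[int] | np.ndarray, genome: GenomeIndex) -> float:
    """|read ∩ genome minimizers| / |read minimizers| (read_mins non-empty)."""
    arr = _as_sorted_array(read_mins)
    if arr.size == 0:
        raise ValueError("shared_fraction undefined for an empty minimizer set")
    return _shared_count(arr, genome.minimizers) / arr.size


def passes_mu(fraction: float, shared_count: int, mu: float) -> bool:
    """μ cutoff: zero shared minimizers always reject (the μ=0 special
    case); otherwise reject strictly below μ."""
    if shared_count == 0:
        return False
    return fraction >= mu


def score_genome(
    read_mins: set[int] | np.ndarray,
    genome: GenomeIndex,
    phi: float,
    log_base: float = math.e,
) -> float:
    """Penalised naive-Bayes log-score of a genome for a read."""
    arr = _as_sorted_array(read_mins)
    if arr.size == 0:
        raise ValueError("score undefined for an empty minimizer set")
    present_term = -math.log(genome.total_kmer_count) / math.log(log_base)
    if phi >= present_term:
        raise ConfigurationError(
            f"phi={phi} must be smaller than log(1/count)={present_term:.6g} "
            f"for genome {genome.genome_id!r}; the penalty would not penalize"
        )
    n_shared = _shared_count(arr, genome.minimizers)
    return n_shared * present_term + (arr.size - n_shared) * phi


def select_candidates(
    scored_genomes: Sequence[tuple[str, float]], theta: float
) -> list[str]:
    """Extend the candidate set downwards from the top score.

    Genomes are grouped by distinct score value (descending).  The top
    group is always included; each next group joins while the gap from
    the previous distinct value is <= theta; the first gap > theta stops
    the walk.  theta=0 therefore returns exactly the argmax tie group.
    """
    if not scored_genomes:
        raise ValueError("select_candidates requires at least one scored genome")
    groups: dict[float, list[str]] = {}
    for gid, score in scored_genomes:
        groups.setdefault(score, []).append(gid)
    out: list[str] = []
    prev = None
    for score in sorted(groups, reverse=True):
        if prev is not None and prev - score > theta:
            break
        out.extend(groups[score])
        prev = score
    return out


def plurality_vote(
    candidates: Sequence[str],
    taxonomy: dict[str, Lineage],
    rng: np.random.Generator,
) -> str:
    """Species with the most candidate genomes; ties broken uniformly at
    random with the supplied seeded generator."""
    if not candidates:
        raise ValueError("plurality_vote requires at least one candidate")
    counts: dict[str, int] = {}
    for gid in candidates:
        if gid not in taxonomy:
            raise TaxonomyError(f"candidate genome {gid!r} missing from taxonomy")
        sp = taxonomy[gid].species
        counts[sp] = counts.get(sp, 0) + 1
    best = max(counts.values())
    tied = sorted(sp for sp, c in counts.items() if c == best)
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.integers(len(tied)))]


def rng_for_read(seed: int, read_id: str) -> np.random.Generator:
    """Deterministic per-read RNG so verdicts are independent of batching,
    ordering and parallelism."""
    derived = zlib.crc32(f"{seed}:{read_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(derived)


class _Scorer:
    """Precomputed per-database state reused across reads."""

    def __init__(self, db: Database, params: ClassifierParams):
        if not db.indexes:
            raise ConfigurationError("database is empty")
        if params.k != db.k:
            raise ConfigurationError(f"params.k={params.k} but database k={db.k}")
        self.db = db
        self.params = params
        log_b = math.log(params.log_base)
        self.present_terms = {
            gid: -math.log(idx.total_kmer_count) / log_b for gid, idx in db.indexes.items()
        }
        worst = min(self.present_terms.values())
        if params.phi >= worst:
            raise ConfigurationError(
                f"phi={params.phi} must be smaller than log(1/count(G_L))={worst:.6g} "
                "of the longest genome"
            )

    def classify(self, read: ReadRecord) -> ReadClassification:
        p = self.params
        mins = kmer.minimizer_array(read.sequence, p.k)
        if mins.size == 0:
            return ReadClassification(
                read.read_id, "unclassified", reason=REASON_NO_MINIMIZERS
            )
        scored: list[tuple[str, float]] = []
        best_frac = 0.0
        for gid in self.db.genome_ids:
            idx = self.db.indexes[gid]
            n_shared = _shared_count(mins, idx.minimizers)
            frac = n_shared / mins.size
            best_frac = max(best_frac, frac)
            if not passes_mu(frac, n_shared, p.mu):
                continue
            score = n_shared * self.present_terms[gid] + (mins.size - n_shared) * p.phi
            scored.append((gid, score))
        if not scored:
            return ReadClassification(
                read.read_id,
                "unclassified",
                shared_fraction_best=best_frac,
                reason=REASON_BELOW_MU,
            )
        candidates = select_candidates(scored, p.theta)
        species = plurality_vote(
            candidates, self.db.taxonomy, rng_for_read(p.seed, read.read_id)
        )
        best_score = max(s for _, s in scored)
        return ReadClassification(
            read.read_id,
            "classified",
            species=species,
            best_score=best_score,
            candidate_genomes=candidates,
            shared_fraction_best=best_frac,
            reason=REASON_OK,
        )


def classify_read(
    read: ReadRecord | str,
    db: Database,
    params: ClassifierParams,
) -> ReadClassification:
    """Classify a single read (a :class:`ReadRecord`, or a bare sequence
    which gets the id ``"read"``)."""
    if isinstance(read, str):
        read = ReadRecord(read_id="read", sequence=read)
    return _Scorer(db, params).classify(read)


def classify_reads(
    reads: Iterable[ReadRecord],
    db: Database,
    params: ClassifierParams,
    threads: int = 1,
) -> Iterator[ReadClassification]:
    """Classify a stream of reads; output order matches input order.

    Each read's tie-break RNG is derived from (seed, read_id), so results
    are identical for any thread count or batching.
    """
    scorer = _Scorer(db, params)
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            yield from pool.map(scorer.classify, reads)
    else:
        for read in reads:
            yield scorer.classify(read)


def _as_sorted_array(mins: set[int] | np.ndarray) -> np.ndarray:
    if isinstance(mins, np.ndarray):
        return mins
    return np.asarray(sorted(mins), dtype=np.int64)


def _shared_count(sorted_read_mins: np.ndarray, sorted_genome_mins: np.ndarray) -> int:
    """Size of the intersection of two sorted unique hash arrays."""
    if sorted_read_mins.size == 0 or sorted_genome_mins.size == 0:
        return 0
    pos = np.searchsorted(sorted_genome_mins, sorted_read_mins)
    pos[pos == sorted_genome_mins.size] = sorted_genome_mins.size - 1
    return int((sorted_genome_mins[pos] == sorted_read_mins).sum())
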