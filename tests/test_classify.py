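"""Tests for scoring, μ rejection, θ-gap candidates and plurality voting."""

import math

import numpy as np
import pytest

import mnbc
from mnbc import classify as clf
from mnbc import kmer
from mnbc.errors import ConfigurationError
from mnbc.index import Database, GenomeIndex, Lineage
from mnbc.io import ReadRecord

from . import oracles
from .conftest import random_dna


def make_genome(gid, minimizers, count, k=5):
    return GenomeIndex(
        genome_id=gid,
        k=k,
        total_kmer_count=count,
        minimizers=np.asarray(sorted(minimizers), dtype=np.int64),
    )


class TestSharedFractionAndMu:
    def test_arithmetic(self):
        g = make_genome("g", {1, 2, 3, 4, 99}, 100)
        assert mnbc.shared_fraction({1, 2, 3, 4, 10, 11, 12, 13, 14, 15}, g) == 0.4

    def test_disjoint_and_subset(self):
        g = make_genome("g", {5, 6}, 10)
        assert mnbc.shared_fraction({1, 2}, g) == 0.0
        assert mnbc.shared_fraction({5, 6}, g) == 1.0

    def test_empty_read_set_undefined(self):
        g = make_genome("g", {5}, 10)
        with pytest.raises(ValueError):
            mnbc.shared_fraction(set(), g)

    @pytest.mark.parametrize(
        "frac,shared,mu,expected",
        [
            (0.0, 0, 0.0, False),  # zero shared always rejects, even at mu=0
            (0.4, 4, 0.35, True),
            (0.34, 34, 0.35, False),  # strictly below mu rejects
            (0.35, 35, 0.35, True),
        ],
    )
    def test_mu_cutoff(self, frac, shared, mu, expected):
        assert clf.passes_mu(frac, shared, mu) is expected


class TestScoreGenome:
    def test_all_present_count_one(self):
        g = make_genome("g", {1, 2, 3}, 1)
        assert mnbc.score_genome({1, 2, 3}, g, phi=-2000.0) == pytest.approx(0.0)

    def test_all_absent(self):
        g = make_genome("g", {9}, 100)
        assert mnbc.score_genome({1, 2, 3}, g, phi=-2000.0) == pytest.approx(-6000.0)

    def test_mixed_natural_log(self):
        g = make_genome("g", {1, 2}, 100)
        score = mnbc.score_genome({1, 2, 3}, g, phi=-2000.0)
        assert score == pytest.approx(2 * math.log(1 / 100) - 2000, abs=1e-9)
        assert score == pytest.approx(-2009.21034, abs=1e-5)

    def test_log_base_configurable(self):
        g = make_genome("g", {1, 2}, 100)
        score10 = mnbc.score_genome({1, 2, 3}, g, phi=-2000.0, log_base=10.0)
        assert score10 == pytest.approx(2 * math.log10(1 / 100) - 2000)

    def test_non_penalizing_phi_rejected(self):
        g = make_genome("g", {1}, 100)
        with pytest.raises(ConfigurationError):
            mnbc.score_genome({1}, g, phi=-math.log(100) / 2)

    def test_adding_shared_minimizer_never_decreases_score(self, rng):
        read = set(range(20))
        count = 10_000
        for n_shared in range(20):
            g1 = make_genome("a", set(range(n_shared)), count)
            g2 = make_genome("b", set(range(n_shared + 1)), count)
            assert mnbc.score_genome(read, g2, -2000.0) > mnbc.score_genome(
                read, g1, -2000.0
            )


class TestSelectCandidates:
    def test_gap_walk(self):
        scored = [("gA", -10.0), ("gB", -10.0), ("gC", -11.0), ("gD", -3000.0)]
        assert sorted(mnbc.select_candidates(scored, 1500.0)) == ["gA", "gB", "gC"]

    def test_theta_zero_is_argmax(self):
        scored = [("gA", -10.0), ("gB", -10.0), ("gC", -10.5)]
        assert sorted(mnbc.select_candidates(scored, 0.0)) == ["gA", "gB"]

    def test_single_genome(self):
        assert mnbc.select_candidates([("g", -5.0)], 1500.0) == ["g"]

    def test_gap_boundary_inclusive(self):
        scored = [("a", 0.0), ("b", -1500.0), ("c", -3000.1)]
        assert sorted(mnbc.select_candidates(scored, 1500.0)) == ["a", "b"]


class TestPluralityVote:
    TAX = {
        "g1": Lineage(species="spA"),
        "g2": Lineage(species="spA"),
        "g3": Lineage(species="spB"),
    }

    def test_strict_plurality(self, rng):
        assert mnbc.plurality_vote(["g1", "g2", "g3"], self.TAX, rng) == "spA"

    def test_tie_is_deterministic_given_seed(self):
        picks = {
            mnbc.plurality_vote(["g1", "g3"], self.TAX, np.random.default_rng(7))
            for _ in range(10)
        }
        assert len(picks) == 1

    def test_tie_uses_rng(self):
        seen = {
            mnbc.plurality_vote(["g1", "g3"], self.TAX, np.random.default_rng(s))
            for s in range(30)
        }
        assert seen == {"spA", "spB"}

    def test_single_candidate(self, rng):
        assert mnbc.plurality_vote(["g3"], self.TAX, rng) == "spB"

    def test_missing_taxonomy_errors(self, rng):
        with pytest.raises(Exception):
            mnbc.plurality_vote(["gX"], self.TAX, rng)


def small_db_from_sequences(seqs: dict[str, str], species: dict[str, str], k: int):
    indexes = {
        gid: mnbc.build_genome_index(gid, [seq], k) for gid, seq in seqs.items()
    }
    taxonomy = {gid: Lineage(species=sp) for gid, sp in species.items()}
    return Database(k=k, indexes=indexes, taxonomy=taxonomy)


class TestClassifyRead:
    def test_short_read_unclassified(self, rng):
        db = small_db_from_sequences(
            {"g": random_dna(rng, 1000)}, {"g": "spA"}, k=15
        )
        res = mnbc.classify_read("ACGT", db, mnbc.ClassifierParams())
        assert res.status == "unclassified"
        assert res.reason == clf.REASON_NO_MINIMIZERS

    def test_exact_fragment_hits_its_species(self, rng):
        genome = random_dna(rng, 20_000)
        db = small_db_from_sequences(
            {"src": genome, "other": random_dna(rng, 20_000)},
            {"src": "spX", "other": "spY"},
            k=15,
        )
        params = mnbc.ClassifierParams(theta=0.0, seed=3)
        read = genome[5_000:5_300]  # interior fragment with >= k-1 bp flanks
        res = mnbc.classify_read(ReadRecord("r1", read), db, params)
        assert res.status == "classified"
        assert res.species == "spX"
        # interior-window minimizers of the fragment are genome minimizers;
        # only the fragment's own end windows can contribute misses
        assert res.shared_fraction_best > 0.9

    def test_read_minimizers_of_interior_fragment_subset_of_genome(self, rng):
        genome = random_dna(rng, 5000)
        k = 15
        gmins = mnbc.extract_minimizers(genome, k)
        frag = genome[1000:1300]
        # interior windows of the fragment are windows of the genome; end
        # windows may pick k-mers that are not genome minimizers, so only
        # interior-window minimizers are guaranteed shared.  With >=k-1 bp
        # flanks the overlap fraction stays high.
        rmins = mnbc.extract_minimizers(frag, k)
        assert len(rmins & gmins) / len(rmins) > 0.8

    def test_unrelated_reads_unclassified(self, rng):
        db = small_db_from_sequences(
            {f"g{i}": random_dna(rng, 20_000) for i in range(3)},
            {f"g{i}": f"sp{i}" for i in range(3)},
            k=15,
        )
        params = mnbc.ClassifierParams(seed=1)
        alien = random_dna(rng, 50_000)
        n_unclassified = 0
        n = 200
        for i in range(n):
            start = int(rng.integers(len(alien) - 150))
            res = mnbc.classify_read(
                ReadRecord(f"r{i}", alien[start : start + 150]), db, params
            )
            n_unclassified += res.status == "unclassified"
        assert n_unclassified / n >= 0.95

    def test_strand_invariant_verdict(self, rng):
        genome = random_dna(rng, 20_000)
        db = small_db_from_sequences(
            {"src": genome, "bg": random_dna(rng, 20_000)},
            {"src": "spX", "bg": "spY"},
            k=15,
        )
        params = mnbc.ClassifierParams(seed=11)
        for _ in range(20):
            start = int(rng.integers(len(genome) - 200))
            seq = genome[start : start + 200]
            a = mnbc.classify_read(ReadRecord("r", seq), db, params)
            b = mnbc.classify_read(
                ReadRecord("r", kmer.reverse_complement(seq)), db, params
            )
            assert (a.status, a.species) == (b.status, b.species)

    def test_phi_validated_against_longest_genome(self, rng):
        db = small_db_from_sequences({"g": random_dna(rng, 5000)}, {"g": "s"}, k=15)
        with pytest.raises(ConfigurationError, match="phi"):
            mnbc.classify_read("A" * 100, db, mnbc.ClassifierParams(phi=-1e-9))


class TestClassifyReads:
    def _fixture(self, rng):
        genome = random_dna(rng, 20_000)
        db = small_db_from_sequences(
            {"src": genome, "bg": random_dna(rng, 20_000)},
            {"src": "spX", "bg": "spY"},
            k=15,
        )
        reads = []
        for i in range(50):
            start = int(rng.integers(len(genome) - 150))
            reads.append(ReadRecord(f"r{i}", genome[start : start + 150]))
        return db, reads

    def test_thread_count_and_order_do_not_matter(self, rng):
        db, reads = self._fixture(rng)
        params = mnbc.ClassifierParams(seed=5)
        serial = list(mnbc.classify_reads(reads, db, params))
        threaded = list(mnbc.classify_reads(reads, db, params, threads=4))
        assert [(r.read_id, r.status, r.species) for r in serial] == [
            (r.read_id, r.status, r.species) for r in threaded
        ]
        shuffled = list(reads[::-1])
        reordered = {r.read_id: r for r in mnbc.classify_reads(shuffled, db, params)}
        for r in serial:
            assert (reordered[r.read_id].status, reordered[r.read_id].species) == (
                r.status,
                r.species,
            )

    def test_empty_input(self, rng):
        db, _ = self._fixture(rng)
        assert list(mnbc.classify_reads([], db, mnbc.ClassifierParams(seed=5))) == []

    def test_mu_monotonicity(self, rng):
        db, reads = self._fixture(rng)
        alien = random_dna(rng, 20_000)
        for i in range(30):
            start = int(rng.integers(len(alien) - 150))
            reads.append(ReadRecord(f"neg{i}", alien[start : start + 150]))
        classified_counts = []
        for mu in [0.0, 0.2, 0.4, 0.6, 0.8]:
            params = mnbc.ClassifierParams(mu=mu, seed=5)
            n = sum(
                r.status == "classified" for r in mnbc.classify_reads(reads, db, params)
            )
            classified_counts.append(n)
        assert classified_counts == sorted(classified_counts, reverse=True)


class TestNaiveOracleAgreement:
    def test_pipeline_matches_naive_reference(self, rng):
        """Full pipeline vs. an independent per-definition implementation
        on tiny random databases (k=5)."""
        k = 5
        for trial in range(30):
            n_genomes = int(rng.integers(2, 6))
            seqs = {
                f"g{j}": random_dna(rng, int(rng.integers(50, 200)))
                for j in range(n_genomes)
            }
            db = small_db_from_sequences(
                seqs, {g: f"sp_{g}" for g in seqs}, k=k
            )
            mu = float(rng.choice([0.0, 0.1, 0.3]))
            theta = float(rng.choice([0.0, 5.0, 50.0]))
            phi = -2000.0
            read = random_dna(rng, int(rng.integers(20, 100)))
            genomes_for_oracle = {
                g: (set(db.indexes[g].minimizers.tolist()), db.indexes[g].total_kmer_count)
                for g in seqs
            }
            expected_candidates, expected_scores = oracles.naive_classify(
                read, genomes_for_oracle, k, mu, phi, theta
            )
            params = mnbc.ClassifierParams(k=k, mu=mu, phi=phi, theta=theta, seed=1)
            res = mnbc.classify_read(ReadRecord("r", read), db, params)
            if not expected_candidates:
                assert res.status == "unclassified"
            else:
                assert sorted(res.candidate_genomes) == expected_candidates
                assert res.best_score == pytest.approx(max(expected_scores.values()))
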