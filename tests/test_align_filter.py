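import sys
import textwrap

import numpy as np
import pytest

from intsite.align_filter import (
    AlignmentHit,
    ExternalAligner,
    InternalAligner,
    enumerate_alignments,
    paired_concordant_unique,
    progressive_unique_filter,
)
from intsite.formats_io import ReferenceGenome
from intsite.primer_trim import TrimmedRead
from intsite.sequtil import revcomp

from conftest import random_genome


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(seq, positions):
    return "".join(
        {"A": "C", "C": "G", "G": "T", "T": "A"}[b] if i in positions else b
        for i, b in enumerate(seq)
    )


def brute_force_placements(query, genome, max_mm):
    """Independent sliding-window Hamming oracle over both strands."""
    out = []
    for contig, seq in genome.contigs.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            for s in range(len(seq) - len(q) + 1):
                window = seq[s : s + len(q)]
                mm = sum(
                    1 for x, y in zip(window, q) if x != y or "N" in (x, y)
                )
                if mm <= max_mm:
                    out.append((contig, s, strand, mm))
    return sorted(out)


def _trimmed(rid, bases, mate=0):
    return TrimmedRead(rid, bases, len(bases), 0, False, mate)


class TestEnumerateAlignments:
    def test_planted_unique_exact_occurrence(self, small_genome):
        query = small_genome.contigs["chr1"][500:540]
        hits = enumerate_alignments(query, small_genome, 0)
        assert [(h.contig, h.start, h.strand, h.mismatches) for h in hits] == [
            ("chr1", 500, "+", 0)
        ]

    def test_reverse_complement_maps_to_same_span(self, small_genome):
        query = revcomp(small_genome.contigs["chr1"][500:540])
        (hit,) = enumerate_alignments(query, small_genome, 0)
        assert (hit.contig, hit.start, hit.end, hit.strand) == ("chr1", 500, 540, "-")

    def test_near_duplicate_found_at_budget_one(self):
        rng = np.random.default_rng(9)
        word = _random_seq(rng, 40)
        copy2 = _mutate(word, {17})
        seq = _random_seq(rng, 300) + word + _random_seq(rng, 200) + copy2 + _random_seq(rng, 100)
        genome = ReferenceGenome({"chr1": seq})
        oracle = brute_force_placements(word, genome, 1)
        hits = enumerate_alignments(word, genome, 1)
        assert [(h.contig, h.start, h.strand, h.mismatches) for h in hits] == oracle
        assert len(hits) == 2

    def test_query_longer_than_contigs_yields_empty(self, small_genome):
        assert enumerate_alignments("A" * 10_000, small_genome, 2) == []

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(30):
            genome = random_genome(100 + trial, lengths=(800, 400))
            n = int(rng.integers(15, 60))
            if rng.random() < 0.7:
                contig = "chr1" if rng.random() < 0.5 else "chr2"
                seq = genome.contigs[contig]
                s = int(rng.integers(0, len(seq) - n))
                query = seq[s : s + n]
                k = int(rng.integers(0, 3))
                query = _mutate(query, set(rng.integers(0, n, k).tolist()))
                if rng.random() < 0.5:
                    query = revcomp(query)
            else:
                query = _random_seq(rng, n)
            max_mm = int(rng.integers(0, 3))
            got = [
                (h.contig, h.start, h.strand, h.mismatches)
                for h in enumerate_alignments(query, genome, max_mm)
            ]
            assert sorted(got) == brute_force_placements(query, genome, max_mm)

    def test_seeded_index_path_matches_scan_path(self):
        # a genome above the indexing threshold exercises the k-mer seeds
        genome = random_genome(77, lengths=(150_000,))
        rng = np.random.default_rng(5)
        aligner = InternalAligner(genome)
        assert aligner._indexes  # indexed path active
        for _ in range(20):
            s = int(rng.integers(0, 150_000 - 50))
            query = _mutate(
                genome.contigs["chr1"][s : s + 50],
                set(rng.integers(0, 50, int(rng.integers(0, 3))).tolist()),
            )
            res = aligner.align([_trimmed("q", query)], 2)["q"]
            got = sorted((h.contig, h.start, h.strand, h.mismatches) for h in res)
            assert got == brute_force_placements(query, genome, 2)


class TestProgressiveFilter:
    def _genome_with(self, rng, *inserts, pad=400):
        seq = _random_seq(rng, pad)
        starts = []
        for ins in inserts:
            starts.append(len(seq))
            seq += ins + _random_seq(rng, pad)
        return ReferenceGenome({"chr1": seq}), starts

    def test_unique_read_survives_all_rounds(self):
        rng = np.random.default_rng(21)
        word = _random_seq(rng, 40)
        genome, (s0,) = self._genome_with(rng, word)
        hits, summary = progressive_unique_filter([_trimmed("r", word)], genome)
        assert (summary.n_unique_mm0, summary.n_unique_mm1, summary.n_unique_mm2) == (1, 1, 1)
        assert hits[0].start == s0 and hits[0].round == 2 and hits[0].mismatches == 0

    def test_exact_duplicate_removed_in_round_one(self):
        rng = np.random.default_rng(22)
        word = _random_seq(rng, 40)
        genome, _ = self._genome_with(rng, word, word)
        hits, summary = progressive_unique_filter([_trimmed("r", word)], genome)
        assert hits == [] and summary.n_unique_mm0 == 0

    def test_one_mismatch_shadow_removed_in_round_two(self):
        rng = np.random.default_rng(23)
        word = _random_seq(rng, 40)
        genome, _ = self._genome_with(rng, word, _mutate(word, {11}))
        hits, summary = progressive_unique_filter([_trimmed("r", word)], genome)
        assert (summary.n_unique_mm0, summary.n_unique_mm1, summary.n_unique_mm2) == (1, 0, 0)
        assert hits == []

    def test_two_mismatch_shadow_removed_in_round_three(self):
        rng = np.random.default_rng(24)
        word = _random_seq(rng, 40)
        genome, _ = self._genome_with(rng, word, _mutate(word, {3, 30}))
        hits, summary = progressive_unique_filter([_trimmed("r", word)], genome)
        assert (summary.n_unique_mm0, summary.n_unique_mm1, summary.n_unique_mm2) == (1, 1, 0)
        assert hits == []

    def test_round_counts_monotone_on_random_inputs(self):
        rng = np.random.default_rng(25)
        for trial in range(50):
            genome = random_genome(500 + trial, lengths=(1200,))
            seq = genome.contigs["chr1"]
            reads = []
            for i in range(6):
                n = int(rng.integers(30, 60))
                s = int(rng.integers(0, len(seq) - n))
                q = _mutate(seq[s : s + n], set(rng.integers(0, n, int(rng.integers(0, 3))).tolist()))
                reads.append(_trimmed(f"r{i}", q))
            _, summary = progressive_unique_filter(reads, genome)
            assert summary.n_unique_mm0 >= summary.n_unique_mm1 >= summary.n_unique_mm2


class TestPairedConcordantUnique:
    def _pair_reads(self, seq, s, frag, l1=40, l2=40):
        m1 = seq[s : s + l1]
        m2 = revcomp(seq[s + frag - l2 : s + frag])
        return _trimmed("p", m1, 1), _trimmed("p", m2, 2)

    def test_planted_pair_within_insert_range(self):
        genome = random_genome(31, lengths=(3000,))
        seq = genome.contigs["chr1"]
        pair = self._pair_reads(seq, 700, 250)
        kept, summary = paired_concordant_unique([pair], genome, 100, 500)
        assert len(kept) == 1
        assert kept[0].fragment_len == 250
        assert (kept[0].mate1.start, kept[0].mate1.strand) == (700, "+")

    def test_fragment_outside_insert_range_discarded(self):
        genome = random_genome(31, lengths=(3000,))
        seq = genome.contigs["chr1"]
        pair = self._pair_reads(seq, 700, 900)
        kept, _ = paired_concordant_unique([pair], genome, 100, 500)
        assert kept == []

    def test_mates_on_different_contigs_discarded(self):
        genome = random_genome(32, lengths=(2000, 2000))
        s1, s2 = genome.contigs["chr1"], genome.contigs["chr2"]
        pair = (_trimmed("p", s1[100:140], 1), _trimmed("p", revcomp(s2[300:340]), 2))
        kept, _ = paired_concordant_unique([pair], genome, 50, 500)
        assert kept == []

    def test_tandem_duplication_makes_pair_ambiguous(self):
        rng = np.random.default_rng(33)
        block = _random_seq(rng, 1000)
        seq = _random_seq(rng, 500) + block + block + _random_seq(rng, 500)
        genome = ReferenceGenome({"chr1": seq})
        # fragment entirely inside the duplicated block: two concordant placements
        pair = self._pair_reads(seq, 600, 300)
        kept, _ = paired_concordant_unique([pair], genome, 100, 500)
        assert kept == []


class TestExternalBackend:
    def test_stub_external_backend_matches_internal(self, tmp_path, small_genome):
        """A SAM-emitting external command reproduces internal alignments."""
        from intsite.formats_io import write_genome_fasta

        fa = tmp_path / "genome.fa"
        write_genome_fasta(small_genome, fa)
        stub = tmp_path / "stub_aligner.py"
        stub.write_text(
            textwrap.dedent(
                """
                import sys
                from intsite.align_filter import InternalAligner
                from intsite.formats_io import (read_fastq, read_genome_fasta,
                                                write_hits_sam)
                from intsite.primer_trim import TrimmedRead
                genome_fa, reads_fq, sam_out, max_mm = sys.argv[1:]
                genome = read_genome_fasta(genome_fa)
                reads = [TrimmedRead(r.read_id, r.bases, len(r.bases), 0, False)
                         for r in read_fastq(reads_fq)]
                hits = InternalAligner(genome).align(reads, int(max_mm))
                write_hits_sam(hits, genome, sam_out)
                """
            )
        )
        cmd = f"{sys.executable} {stub} {fa} {{reads}} {{sam}} {{max_mm}}"
        rng = np.random.default_rng(44)
        seq = small_genome.contigs["chr1"]
        reads = []
        for i in range(8):
            s = int(rng.integers(0, len(seq) - 40))
            q = _mutate(seq[s : s + 40], set(rng.integers(0, 40, int(rng.integers(0, 2))).tolist()))
            reads.append(_trimmed(f"r{i}", q))
        internal_hits, internal_summary = progressive_unique_filter(
            reads, small_genome
        )
        external_hits, external_summary = progressive_unique_filter(
            reads, small_genome, backend=ExternalAligner(cmd)
        )
        assert external_summary == internal_summary
        key = lambda h: (h.read_id, h.contig, h.start, h.strand, h.mismatches)
        assert sorted(map(key, external_hits)) == sorted(map(key, internal_hits))

    def test_failing_command_raises_backend_error(self, small_genome):
        from intsite.align_filter import BackendError

        backend = ExternalAligner("false # {reads} {sam} {max_mm}")
        with pytest.raises(BackendError):
            backend.align([_trimmed("r", "ACGT" * 10)], 0)
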