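"""Reference indexing, tag alignment, clustering."""

import pytest

from helpers_align import oracle_align, run_oracle_trials
from radmap.simcross import AnnotatedGenome, revcomp
from radmap.tagmap import (
    TagAlignment,
    align_tag,
    build_clusters,
    build_reference_index,
)

class TestIndex:
    def test_masked_mode_indexes_non_repeat_bases(self, small_genome):
        idx = build_reference_index(small_genome, "masked")
        masked = sum(
            e - s for iv in small_genome.repeat_intervals.values() for s, e in iv
        )
        assert idx.indexed_bases == small_genome.total_length() - masked

    def test_genemodels_mode_indexes_gene_bases(self, small_genome):
        idx = build_reference_index(small_genome, "genemodels")
        genes = sum(
            e - s for iv in small_genome.gene_intervals.values() for s, e in iv
        )
        assert idx.indexed_bases == genes

    def test_unmasked_mode_indexes_everything(self, small_genome):
        idx = build_reference_index(small_genome, "unmasked")
        assert idx.indexed_bases == small_genome.total_length()

    def test_genemodels_requires_gene_set(self, small_genome):
        empty = AnnotatedGenome(
            scaffolds=small_genome.scaffolds,
            repeat_intervals=small_genome.repeat_intervals,
            gene_intervals={s: [] for s in small_genome.scaffold_ids},
        )
        with pytest.raises(ValueError):
            build_reference_index(empty, "genemodels")

    def test_unknown_mode_rejected(self, small_genome):
        with pytest.raises(ValueError):
            build_reference_index(small_genome, "bogus")


class TestAlignTag:
    def test_exact_unique_match(self, plain_genome):
        idx = build_reference_index(plain_genome, "unmasked")
        seq = plain_genome.sequence("scaffold_1")
        tag = seq[5000:5092]
        a = align_tag(tag, idx)
        assert (a.status, a.scaffold_id, a.position, a.strand, a.n_mismatch) == (
            "unique", "scaffold_1", 5000, "+", 0
        )

    def test_reverse_strand_match(self, plain_genome):
        idx = build_reference_index(plain_genome, "unmasked")
        seq = plain_genome.sequence("scaffold_2")
        tag = revcomp(seq[8000:8092])
        a = align_tag(tag, idx)
        assert (a.status, a.scaffold_id, a.position, a.strand) == (
            "unique", "scaffold_2", 8000, "-"
        )

    def test_two_copy_tag_ambiguous_unmasked_unique_masked(self, rng):
        # identical repeat copy on two scaffolds; masking one rescues the tag
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        bg1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 12000))
        bg2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 11000))
        g = AnnotatedGenome(
            scaffolds=[
                ("s1", bg1[:6000] + unit + bg1[6000:]),
                ("s2", bg2[:4000] + unit + bg2[4000:]),
            ],
            repeat_intervals={"s1": [], "s2": [(4000, 4150)]},
            gene_intervals={"s1": [], "s2": []},
        )
        tag = g.sequence("s1")[6030:6030 + 92]  # fully inside the unit
        assert tag in g.sequence("s2")
        a_un = align_tag(tag, build_reference_index(g, "unmasked"))
        assert a_un.status == "ambiguous"
        a_ma = align_tag(tag, build_reference_index(g, "masked"))
        assert (a_ma.status, a_ma.scaffold_id) == ("unique", "s1")

    def test_three_mismatches_unaligned(self, plain_genome):
        idx = build_reference_index(plain_genome, "unmasked")
        seq = plain_genome.sequence("scaffold_1")
        tag = list(seq[3000:3092])
        for i in (10, 40, 70):
            tag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[i]]
        a = align_tag("".join(tag), idx)
        assert a.status == "unaligned"

    def test_wrong_length_rejected(self, plain_genome):
        idx = build_reference_index(plain_genome, "unmasked")
        with pytest.raises(ValueError):
            align_tag("ACGT" * 10, idx)

    def test_indel_alignment_found(self, plain_genome):
        idx = build_reference_index(plain_genome, "unmasked")
        seq = plain_genome.sequence("scaffold_1")
        base = seq[12000:12094]
        tag = base[:40] + base[42:94]  # 2 bp deletion inside the tag
        assert len(tag) == 92
        a = align_tag(tag, idx)
        assert a.status == "unique"
        assert a.position == 12000
        assert a.indel_len == 2 and a.score == 4

    def test_oracle_equivalence_on_small_genome(self):
        # quick spot check; the full 1000-tag sweep runs in the
        # acceptance suite
        assert run_oracle_trials(150) >= 145

    def test_masked_hits_subset_of_unmasked(self, small_genome, rng):
        idx_u = build_reference_index(small_genome, "unmasked")
        idx_m = build_reference_index(small_genome, "masked")
        for _ in range(15):
            sid = small_genome.scaffold_ids[int(rng.integers(2))]
            seq = small_genome.sequence(sid)
            start = int(rng.integers(0, len(seq) - 92))
            tag = seq[start:start + 92]
            a_m = align_tag(tag, idx_m)
            if a_m.status == "unique":
                a_u = align_tag(tag, idx_u)
                # a unique masked hit is present in the unmasked index too
                hits_u = oracle_align(tag, small_genome)
                assert (a_m.scaffold_id, a_m.position, a_m.strand) in hits_u
                assert a_u.status in ("unique", "ambiguous")


class TestClusters:
    def _aln(self, sample, pos=100, seq="A" * 92, count=1, status="unique"):
        return TagAlignment("t", sample, "s1", pos, "+", 0, 0, status,
                            tag_seq=seq, count=count)

    def test_depth_window_boundaries(self):
        for depth, kept in ((3, 0), (4, 1), (200, 1), (201, 0)):
            alns = [self._aln("mother", count=depth)]
            clusters, stats = build_clusters(alns)
            assert len(clusters) == kept
            assert stats["n_loci"] == 1

    def test_empty_alignments_give_empty_clusters(self):
        clusters, stats = build_clusters([])
        assert clusters == [] and stats["n_loci"] == 0

    def test_ambiguous_alignments_excluded(self):
        alns = [self._aln("mother", count=10, status="ambiguous")]
        clusters, _ = build_clusters(alns)
        assert clusters == []

    def test_depth_accounting_matches_unique_read_count(self):
        alns = [
            self._aln("mother", pos=100, count=4),
            self._aln("father", pos=100, count=3, seq="C" * 92),
            self._aln("p01", pos=100, count=5),
            self._aln("mother", pos=300, count=6),
        ]
        clusters, _ = build_clusters(alns)
        total = sum(c.total_depth for c in clusters)
        assert total == sum(a.count for a in alns)
        by_locus = {c.position: c for c in clusters}
        assert by_locus[100].sample_depth("mother") == 4
        assert by_locus[100].panel_depth() == 7
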