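"""Simulator: digest, genome, parents, gametes, reads."""

import numpy as np
import pytest
from scipy import stats

from radmap import simcross
from radmap.mapfunc import haldane_r
from radmap.simcross import digest_ddrad, revcomp


FILLER = "ACGTCC" * 40  # no NsiI or MseI site, also across junctions


def fragment_construct(length: int) -> str:
    """NsiI site, then spacer, then MseI site, sized so the retained
    fragment (ATGCA|T ... T|TAA) has exactly ``length`` bases."""
    return FILLER + "ATGCAT" + "C" * (length - 2) + "TTAA" + FILLER


class TestDigest:
    def test_no_rare_cutter_site_yields_nothing(self):
        seq = "ACGT" * 200  # no ATGCAT anywhere
        assert digest_ddrad(seq) == []

    def test_constructed_fragment_between_cuts(self):
        seq = fragment_construct(300)
        frags = digest_ddrad(seq)
        assert len(frags) == 1
        frag = frags[0]
        assert frag.length == 300
        assert frag.side5_enzyme == 1 and frag.side3_enzyme == 2
        assert frag.sequence == seq[frag.start:frag.end]
        # starts right after ATGCA|T
        assert seq[frag.start - 5:frag.start + 1] == "ATGCAT"

    @pytest.mark.parametrize("length,retained", [(199, 0), (200, 1), (500, 1), (501, 0)])
    def test_size_selection_boundaries(self, length, retained):
        assert len(digest_ddrad(fragment_construct(length))) == retained

    def test_retained_fragments_have_no_internal_cut_sites(self, small_genome):
        for sid, seq in small_genome.scaffolds:
            for frag in digest_ddrad(seq, scaffold_id=sid)[:50]:
                # re-digesting a retained fragment produces no internal cuts
                assert "ATGCAT" not in frag.sequence[1:-1]
                assert "TTAA" not in frag.sequence[1:-1]


class TestGenome:
    def test_repeat_fraction_hits_target(self):
        # 57% repetitive on a 1 Mb toy genome
        g = simcross.simulate_genome(
            2, [600_000, 400_000],
            repeat_family_specs=[(400, 700, 0.02), (300, 950, 0.05)],
            gene_density=0.03, seed=5,
        )
        assert abs(g.repeat_fraction() - 0.57) < 0.05

    def test_no_repeat_families_gives_empty_intervals(self, plain_genome):
        assert all(not v for v in plain_genome.repeat_intervals.values())

    def test_seeded_determinism(self):
        a = simcross.simulate_genome(2, [20_000, 15_000], [(250, 10, 0.02)], 0.05, seed=3)
        b = simcross.simulate_genome(2, [20_000, 15_000], [(250, 10, 0.02)], 0.05, seed=3)
        assert a.scaffolds == b.scaffolds
        assert a.repeat_intervals == b.repeat_intervals
        assert a.gene_intervals == b.gene_intervals

    def test_excessive_repeat_content_rejected(self):
        with pytest.raises(ValueError):
            simcross.simulate_genome(1, [20_000], [(500, 100, 0.0)], 0.0, seed=1)

    def test_short_scaffold_rejected(self):
        with pytest.raises(ValueError):
            simcross.simulate_genome(1, [5_000], [], 0.05, seed=1)

    def test_intervals_within_bounds_and_disjoint(self, small_genome):
        for table in (small_genome.repeat_intervals, small_genome.gene_intervals):
            for sid, ivs in table.items():
                n = len(small_genome.sequence(sid))
                for (s, e), nxt in zip(ivs, ivs[1:] + [(n, n)]):
                    assert 0 <= s < e <= n
                    assert e <= nxt[0]


class TestParents:
    def test_het_site_count_within_binomial_ci(self):
        g = simcross.simulate_genome(1, [1_000_000], [], 0.0, seed=9)
        p = simcross.simulate_parents(g, het_rate_paternal=0.0037, seed=10,
                                      repeat_insertions_per_mb=0.0)
        n = p.n_het_sites("paternal")
        mean = 1_000_000 * 0.0037
        sd = np.sqrt(mean * (1 - 0.0037))
        assert abs(n - mean) < 2.576 * sd  # 99% binomial interval

    def test_zero_rate_gives_reference_haplotypes(self, plain_genome):
        p = simcross.simulate_parents(plain_genome, 0.0, 0.0, seed=1,
                                      repeat_insertions_per_mb=0.0)
        for sid, seq in plain_genome.scaffolds:
            assert p.haplotype("maternal", 1, sid) == seq
            assert p.haplotype("paternal", 1, sid) == seq

    def test_tiny_expected_count_warns(self, plain_genome):
        with pytest.warns(UserWarning):
            simcross.simulate_parents(plain_genome, 1e-8, 0.0, seed=1,
                                      repeat_insertions_per_mb=0.0)

    def test_rate_out_of_range_rejected(self, plain_genome):
        with pytest.raises(ValueError):
            simcross.simulate_parents(plain_genome, 0.2, 0.0, seed=1)

    def test_het_counts_binomial_over_seeds(self):
        # chi-square goodness of fit of realized counts vs Binomial(L, p)
        g = simcross.simulate_genome(1, [200_000], [], 0.0, seed=11)
        p0 = 0.0037
        zs = []
        for seed in range(20):
            p = simcross.simulate_parents(g, het_rate_paternal=p0, seed=seed,
                                          repeat_insertions_per_mb=0.0)
            n = p.n_het_sites("paternal")
            mean = 200_000 * p0
            zs.append((n - mean) / np.sqrt(mean * (1 - p0)))
        chi2 = float(np.sum(np.square(zs)))
        assert stats.chi2.sf(chi2, df=20) > 0.01


class TestF1:
    def test_poisson_crossover_mean(self):
        g = simcross.simulate_genome(1, [2_000_000], [], 0.0, seed=21)
        p = simcross.simulate_parents(g, 0.0, 0.0, seed=22,
                                      repeat_insertions_per_mb=0.0)
        pr = simcross.simulate_f1(p, truth_cm_per_mb=50.0, n_progeny=500, seed=23)
        # 2 Mb at 50 cM/Mb -> 1.0 expected crossover per gamete
        counts = [
            len(pr.gametes[i][parent]["scaffold_1"].breakpoints)
            for i in range(500) for parent in ("maternal", "paternal")
        ]
        mean = np.mean(counts)
        assert abs(mean - 1.0) < 3 * np.sqrt(1.0 / len(counts))

    def test_zero_rate_gives_no_recombination(self, small_cross):
        parents, _ = small_cross
        pr = simcross.simulate_f1(parents, truth_cm_per_mb=0.0, n_progeny=5, seed=2)
        for g in pr.gametes:
            for parent in ("maternal", "paternal"):
                for gam in g[parent].values():
                    assert gam.breakpoints == []

    def test_single_progeny_rejected(self, small_cross):
        with pytest.raises(ValueError):
            simcross.simulate_f1(small_cross[0], 1.0, n_progeny=1, seed=1)

    def test_recombinant_fraction_matches_poisson_model(self):
        # two markers 10 cM apart; Poisson crossovers imply an expected
        # recombinant fraction of (1 - e^{-0.2})/2 = 0.0906
        ds = simcross.simulate_testcross_dataset(
            n_lgs=1, markers_per_lg=2, spacing_cm=10.0, n_progeny=10_000,
            seed=31, missing_rate=0.0, scaffolds_per_lg=1,
        )
        calls = ds["calls"].to_numpy()
        rec = float((calls[0] != calls[1]).mean())
        expect = haldane_r(10.0)
        assert abs(expect - 0.0906) < 5e-4
        sd = np.sqrt(expect * (1 - expect) / 10_000)
        assert abs(rec - expect) < 3 * sd


class TestReads:
    def _one_fragment(self):
        frags = digest_ddrad(fragment_construct(300))
        assert len(frags) == 1
        return frags

    def test_read_is_barcode_plus_fragment_prefix(self):
        frags = self._one_fragment()
        reads = simcross.generate_reads(
            frags, "ACGT", mean_depth=1.0, depth_dispersion=0.0,
            error_rate=0.0, seed=4,
        )
        for r in reads:
            assert r.sequence.startswith("ACGT")
            assert r.sequence[4:] == frags[0].sequence[:96]

    def test_reverse_oriented_fragment_read_from_nsii_end(self):
        # MseI ... NsiI fragment: the read must come from the NsiI side,
        # i.e. the reverse complement of the fragment
        seq = FILLER + "TTAA" + "C" * 292 + "ATGCAT" + FILLER
        frags = digest_ddrad(seq)
        assert len(frags) == 1 and frags[0].side3_enzyme == 1
        reads = simcross.generate_reads(frags, "AACC", 1.0, 0.0, 0.0, seed=1)
        assert all(
            r.sequence[4:] == revcomp(frags[0].sequence)[:96] for r in reads
        )

    def test_bad_barcode_length_rejected(self):
        frags = self._one_fragment()
        with pytest.raises(ValueError):
            simcross.generate_reads(frags, "ACG", 1.0, seed=1)
        with pytest.raises(ValueError):
            simcross.generate_reads(frags, "ACGTACGTA", 1.0, seed=1)

    def test_parent_depth_twice_progeny(self, small_cross):
        parents, progeny = small_cross
        barcodes = simcross.make_barcodes(
            ["mother", "father"] + [f"p{i+1:02d}" for i in range(progeny.n_progeny)],
            seed=3,
        )
        reads = simcross.simulate_cross_reads(
            progeny, barcodes, mean_depth=6.0, depth_dispersion=0.0,
            error_rate=0.0, parent_depth_multiplier=2.0, seed=5,
        )
        per_sample = {}
        for r in reads:
            sid = r.read_id.split(":")[0]
            per_sample[sid] = per_sample.get(sid, 0) + 1
        parent_mean = (per_sample["mother"] + per_sample["father"]) / 2
        prog_mean = np.mean([
            per_sample.get(f"p{i+1:02d}", 0) for i in range(progeny.n_progeny)
        ])
        assert parent_mean / prog_mean == pytest.approx(2.0, rel=0.15)

    def test_quality_strings_are_phred33(self):
        frags = self._one_fragment()
        reads = simcross.generate_reads(frags, "ACGT", 2.0, 0.0, 0.0, seed=6)
        for r in reads:
            assert len(r.quality) == len(r.sequence)
            assert all(33 <= ord(c) <= 74 for c in r.quality)

    def test_barcode_table_prefix_free(self):
        bcs = simcross.make_barcodes([f"s{i}" for i in range(60)], seed=1)
        vals = list(bcs.values())
        assert len(set(vals)) == 60
        for i, a in enumerate(vals):
            for b in vals[i + 1:]:
                assert not a.startswith(b) and not b.startswith(a)
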