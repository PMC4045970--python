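"""Marker discovery, CP genotyping, and the marker-quality filters."""

import pytest

from radmap import genocall
from radmap.genocall import (
    MISSING,
    SEG_INTERCROSS,
    SEG_MATERNAL,
    SEG_PATERNAL,
    SEG_UNINFORMATIVE,
    MarkerLocus,
    call_locus_alleles,
    call_sample_genotype,
    filter_distortion,
    filter_integrity,
    genotype_progeny,
    type_parental_segregation,
)
from radmap.tagmap import Cluster

A, G = "A" * 92, "G" * 92  # two allele tag sequences


def make_cluster(reads, pos=100):
    return Cluster("s1", pos, "+", reads=reads)


class TestSampleGenotype:
    def test_balanced_counts_call_heterozygote(self):
        assert call_sample_genotype({"A": 10, "G": 10}) == ("A", "G")

    def test_one_stray_read_treated_as_error(self):
        # 1/20 = 5% < 25% threshold
        assert call_sample_genotype({"A": 19, "G": 1}) == ("A",)

    def test_minor_fraction_boundary(self):
        assert call_sample_genotype({"A": 3, "G": 1}) == ("A", "G")  # 25%
        assert call_sample_genotype({"A": 7, "G": 1}) == ("A",)      # 12.5%

    def test_below_min_depth_is_no_call(self):
        assert call_sample_genotype({"A": 2}) is None


class TestLocusAlleles:
    def test_three_alleles_discard_locus(self):
        cl = make_cluster({
            "mother": {A: 6, G: 6},
            "father": {"C" * 92: 8, A: 2},
        })
        assert call_locus_alleles(cl) is None

    def test_union_of_parent_alleles(self):
        cl = make_cluster({"mother": {A: 10}, "father": {A: 5, G: 5}})
        alleles, m_gt, p_gt = call_locus_alleles(cl)
        assert alleles == (A, G)
        assert m_gt == (A,) and p_gt == (A, G)

    def test_no_parent_reads_uncallable(self):
        assert call_locus_alleles(make_cluster({"p01": {A: 9}})) is None


class TestSegregationTyping:
    @pytest.mark.parametrize("mother,father,expected", [
        (("A",), ("A", "G"), SEG_PATERNAL),
        (("A", "G"), ("A",), SEG_MATERNAL),
        (("A", "G"), ("A", "G"), SEG_INTERCROSS),
        (("A",), ("A",), SEG_UNINFORMATIVE),
        (None, ("A", "G"), SEG_UNINFORMATIVE),
    ])
    def test_parental_configurations(self, mother, father, expected):
        assert type_parental_segregation(mother, father) == expected


def paternal_cluster(n_called, n_progeny=51, depth=10, pos=100):
    """Paternal-testcross cluster: alternating nn/np progeny, the first
    ``n_called`` progeny at ``depth``x, the rest at 1x."""
    reads = {"mother": {A: 20}, "father": {A: 10, G: 10}}
    for i in range(n_progeny):
        pid = f"p{i+1:02d}"
        d = depth if i < n_called else 1
        if i % 2 == 0:
            reads[pid] = {A: d}
        else:
            half = max(d // 2, 1)
            reads[pid] = {A: half, G: d - half} if d > 1 else {G: d}
    return make_cluster(reads, pos), [f"p{i+1:02d}" for i in range(n_progeny)]


class TestGenotypeProgeny:
    def test_locus_dropped_at_88_percent_called(self):
        cl, pids = paternal_cluster(45)  # 45/51 = 88.2% <= 90%
        locus, reason = genotype_progeny(cl, pids)
        assert locus is None and reason == "low_called_fraction"

    def test_locus_retained_at_92_percent_called(self):
        cl, pids = paternal_cluster(47)  # 47/51 = 92.2% > 90%
        locus, reason = genotype_progeny(cl, pids)
        assert isinstance(locus, MarkerLocus)
        assert locus.segregation_type == SEG_PATERNAL

    def test_low_depth_progeny_called_missing(self):
        cl, pids = paternal_cluster(51)
        cl.reads["p01"] = {A: 2}  # below 3x
        locus, _ = genotype_progeny(cl, pids)
        assert locus.calls["p01"] == MISSING

    def test_calls_match_truth_at_high_depth(self):
        # error-free reads at >= 10x: calls must equal the constructed truth
        cl, pids = paternal_cluster(51, depth=10)
        locus, _ = genotype_progeny(cl, pids)
        for i, pid in enumerate(pids):
            assert locus.calls[pid] == ("nn" if i % 2 == 0 else "np")

    def test_monomorphic_locus_rejected(self):
        cl = make_cluster({"mother": {A: 10}, "father": {A: 10}})
        locus, reason = genotype_progeny(cl, ["p01"])
        assert locus is None and reason == "monomorphic"


def locus_with_calls(calls, seg=SEG_PATERNAL):
    return MarkerLocus(
        locus_id="l", scaffold_id="s1", position=0, alleles=(A, G),
        maternal_genotype=(A,), paternal_genotype=(A, G),
        segregation_type=seg, calls=dict(calls),
    )


class TestIntegrityFilter:
    def test_six_missing_of_51_dropped(self):
        calls = {f"p{i:02d}": MISSING if i < 6 else "nn" for i in range(51)}
        assert not filter_integrity(locus_with_calls(calls))

    def test_five_missing_of_51_kept(self):
        calls = {f"p{i:02d}": MISSING if i < 5 else "nn" for i in range(51)}
        assert filter_integrity(locus_with_calls(calls))

    def test_complete_locus_kept(self):
        calls = {f"p{i:02d}": "nn" for i in range(51)}
        assert filter_integrity(locus_with_calls(calls))


class TestDistortionFilter:
    def test_testcross_ratio_4_dropped(self):
        calls = ["nn"] * 40 + ["np"] * 10
        keep, reason = filter_distortion(calls, SEG_PATERNAL)
        assert not keep and reason == "distorted_1to1"

    def test_testcross_ratio_2_kept(self):
        calls = ["nn"] * 30 + ["np"] * 15
        keep, _ = filter_distortion(calls, SEG_PATERNAL)
        assert keep

    def test_testcross_boundary_ratio_3_kept(self):
        keep, _ = filter_distortion(["nn"] * 36 + ["np"] * 12, SEG_PATERNAL)
        assert keep

    def test_intercross_dominant_ratio_11_dropped(self):
        calls = ["hh"] * 22 + ["hk"] * 22 + ["kk"] * 4
        keep, reason = filter_distortion(calls, SEG_INTERCROSS)
        assert not keep and reason == "distorted_3to1"

    def test_intercross_mendelian_kept(self):
        calls = ["hh"] * 13 + ["hk"] * 25 + ["kk"] * 13
        keep, _ = filter_distortion(calls, SEG_INTERCROSS)
        assert keep

    def test_too_few_informative_dropped_with_reason(self):
        keep, reason = filter_distortion(["nn"] * 4 + ["np"] * 4, SEG_PATERNAL)
        assert not keep and reason == "too_few_informative"


def test_filter_order_stability():
    """Depth, integrity and distortion are independent per-locus
    predicates: the retained set is the same in any application order."""
    import itertools

    loci = []
    for i, (miss, ratio) in enumerate([(0, 1.0), (10, 1.0), (2, 5.0), (3, 2.0)]):
        n_np = int(40 / (1 + ratio))
        calls = (["nn"] * (40 - n_np) + ["np"] * n_np + [MISSING] * miss)
        calls = {f"p{j:02d}": c for j, c in enumerate(calls)}
        loci.append(locus_with_calls(calls))
    preds = [
        lambda l: filter_integrity(l),
        lambda l: filter_distortion(l)[0],
    ]
    results = set()
    for perm in itertools.permutations(preds):
        kept = [l.locus_id for l in loci if all(p(l) for p in perm)]
        results.add(tuple(kept))
    assert len(results) == 1


def test_score_markers_pipeline_counts():
    clusters = [paternal_cluster(51)[0], paternal_cluster(40, pos=500)[0]]
    pids = [f"p{i+1:02d}" for i in range(51)]
    matrix = genocall.score_markers(clusters, pids)
    assert matrix.n_markers == 1
    assert matrix.n_progeny == 51
    reasons = matrix.filter_log.reason.tolist()
    assert "low_called_fraction" in reasons and "ok" in reasons
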