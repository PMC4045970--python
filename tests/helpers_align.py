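"""Shared brute-force alignment oracle for the aligner tests.

The oracle scans every reference offset on both strands under the same
mismatch/indel budget and scoring as the production aligner, with no
seeding step, so seed sensitivity and tie handling are checked against
exhaustive enumeration.
"""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from radmap import tagmap
from radmap.simcross import AnnotatedGenome, revcomp
from radmap.tagmap import align_tag, build_reference_index


def oracle_align(tag, genome, max_mm=2, max_indel=2):
    """Exhaustive hit enumeration: every (scaffold, offset, strand),
    ungapped or with one internal indel of <= max_indel bases."""
    L = len(tag)
    hits = {}
    for strand, seq_q in (("+", tag), ("-", revcomp(tag))):
        qarr = tagmap.encode(seq_q)
        for sid, seq in genome.scaffolds:
            arr = tagmap.encode(seq)
            n = len(arr)
            if n < L:
                continue
            win = sliding_window_view(arr, L)
            neq = (win != qarr).astype(np.int16)
            mm_ungapped = neq.sum(axis=1)
            cs = np.cumsum(neq, axis=1, dtype=np.int16)
            for p in np.nonzero(mm_ungapped <= max_mm)[0]:
                key = (sid, int(p), strand)
                hits[key] = min(hits.get(key, 99), int(mm_ungapped[p]))
            for g in range(1, max_indel + 1):
                # deletion in tag: span L + g, breakpoint 1..L-1
                if n >= L + g:
                    win2 = sliding_window_view(arr, L + g)
                    neq2 = (win2[:, g:] != qarr).astype(np.int16)
                    cs2 = np.cumsum(neq2, axis=1, dtype=np.int16)
                    tot2 = cs2[:, -1]
                    npos = len(win2)
                    cost = cs[:npos, 0:L - 1] + (tot2[:, None] - cs2[:, 0:L - 1])
                    best_b = cost.min(axis=1)
                    for p in np.nonzero(best_b <= max_mm)[0]:
                        key = (sid, int(p), strand)
                        score = int(best_b[p]) + 2 * g
                        hits[key] = min(hits.get(key, 99), score)
                # insertion in tag: span L - g, breakpoint 1..L-g-1
                if L - g >= 2 and n >= L - g:
                    win3 = sliding_window_view(arr, L - g)
                    neq3 = (win3 != qarr[g:]).astype(np.int16)
                    cs3 = np.cumsum(neq3, axis=1, dtype=np.int16)
                    tot3 = cs3[:, -1]
                    hi = L - g - 1
                    pre3 = np.cumsum(
                        (win3 != qarr[:L - g]).astype(np.int16), axis=1,
                        dtype=np.int16,
                    )
                    cost = pre3[:, 0:hi] + (tot3[:, None] - cs3[:, 0:hi])
                    best_b = cost.min(axis=1)
                    for p in np.nonzero(best_b <= max_mm)[0]:
                        key = (sid, int(p), strand)
                        score = int(best_b[p]) + 2 * g
                        hits[key] = min(hits.get(key, 99), score)
    return hits


def oracle_status(hits):
    if not hits:
        return "unaligned", None, None
    best = min(hits.values())
    at_best = [k for k, v in hits.items() if v == best]
    if len(at_best) == 1:
        return "unique", at_best[0], best
    return "ambiguous", None, best


def make_oracle_genome(seed=77):
    """<= 50 kb two-scaffold genome with a 2 kb internal duplication to
    exercise ambiguous placements."""
    rng = np.random.default_rng(seed)
    s1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 14_000))
    s2 = "".join("ACGT"[i] for i in rng.integers(0, 4, 6_000))
    s2 = s2[:3000] + s1[2000:4000] + s2[3000:]
    return AnnotatedGenome(
        scaffolds=[("s1", s1), ("s2", s2)],
        repeat_intervals={"s1": [], "s2": []},
        gene_intervals={"s1": [], "s2": []},
    )


def run_oracle_trials(n_trials, seed=77):
    """Compare the production aligner against the oracle on planted and
    random tags; returns the number of tags checked (asserts inside)."""
    genome = make_oracle_genome(seed)
    idx = build_reference_index(genome, "unmasked")
    seqs = dict(genome.scaffolds)
    rng = np.random.default_rng(seed + 1)
    n_checked = 0
    for trial in range(n_trials):
        kind = trial % 5
        sid = "s1" if rng.random() < 0.7 else "s2"
        start = int(rng.integers(0, len(seqs[sid]) - 95))
        base = seqs[sid][start:start + 94]
        if kind == 0:  # exact or mismatched copy
            tag = list(base[:92])
            for _ in range(int(rng.integers(0, 3))):
                i = int(rng.integers(92))
                tag[i] = "ACGT"[int(rng.integers(4))]
            tag = "".join(tag)
        elif kind == 1:  # deletion of 1-2 bp
            gl = int(rng.integers(1, 3))
            b = int(rng.integers(1, 92))
            tag = (base[:b] + base[b + gl:])[:92]
        elif kind == 2:  # insertion of 1-2 bp
            gl = int(rng.integers(1, 3))
            b = int(rng.integers(1, 91))
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, gl))
            tag = (base[:b] + ins + base[b:])[:92]
        elif kind == 3:  # reverse strand
            tag = revcomp(base[:92])
        else:  # random sequence, mostly unalignable
            tag = "".join("ACGT"[i] for i in rng.integers(0, 4, 92))
        if len(tag) != 92:
            continue
        got = align_tag(tag, idx)
        status, locus, best = oracle_status(oracle_align(tag, genome))
        assert got.status == status, (trial, tag)
        if status == "unique":
            assert (got.scaffold_id, got.position, got.strand) == locus
            assert got.score == best
        n_checked += 1
    return n_checked
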