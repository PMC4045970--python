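"""Tag alignment against a reference dialect and per-locus clustering.

The three reference dialects of the marker-scoring comparison are
``unmasked`` (full scaffolds), ``masked`` (repeat intervals hard-masked,
so only bases outside repeats are indexed) and ``genemodels`` (only
bases inside gene intervals are indexed).

The aligner is seed-and-verify over the marker model of the protocol:
a 92-base tag matches a locus with up to 2 mismatches and at most one
indel event of 1-2 bases.  Alignment score is
``mismatches + 2 * indel_bases``; a tag is uniquely placed only when a
single locus attains the best score, ties are ambiguous and excluded
downstream.  Seeding uses three non-overlapping 30-mers (offsets 0, 31,
62), which by pigeonhole leaves at least one seed intact for any
alignment within the mismatch budget; verification is vectorized over
all candidate loci at once, which keeps high-copy repeat tags cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .simcross import AnnotatedGenome, revcomp

TAG_LENGTH = 92
SEED_K = 30
SEED_OFFSETS = (0, 31, 62)
MAX_MISMATCH = 2
MAX_INDEL = 2
DEPTH_WINDOW = (4, 200)
_PAD = 100  # N padding between scaffolds in the concatenated array

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """2-bit encode; anything outside ACGT (N, mask) becomes 4 and never
    matches a query base."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class ReferenceIndex:
    mode: str
    scaffold_ids: list[str]
    concat: np.ndarray                # padded concatenated encoded sequence
    offsets: np.ndarray               # global start offset per scaffold
    lengths: np.ndarray               # scaffold lengths
    seed_codes: np.ndarray            # sorted 30-mer codes (valid windows only)
    seed_positions: np.ndarray        # global positions, same order as seed_codes
    k: int = SEED_K

    @property
    def indexed_bases(self) -> int:
        return int((self.concat < 4).sum())

    def locate(self, global_pos: int) -> tuple[int, int]:
        """global position -> (scaffold index, local position)"""
        i = int(np.searchsorted(self.offsets, global_pos, side="right") - 1)
        return i, global_pos - int(self.offsets[i])


def _window_codes(arr: np.ndarray, k: int):
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    code = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        code = (code << np.uint64(2)) | arr[j:j + m].astype(np.uint64)
    invalid = (arr >= 4).astype(np.int32)
    bad = np.cumsum(invalid)
    bad_in_window = bad[k - 1:] - np.concatenate(([0], bad[:m - 1]))
    ok = bad_in_window == 0
    return code[ok], np.nonzero(ok)[0].astype(np.int64)


def _searchable(genome: AnnotatedGenome, mode: str) -> list[str]:
    seqs = []
    for sid, seq in genome.scaffolds:
        if mode == "unmasked":
            seqs.append(seq)
        elif mode == "masked":
            arr = list(seq)
            for s, e in genome.repeat_intervals.get(sid, []):
                arr[s:e] = "N" * (e - s)
            seqs.append("".join(arr))
        elif mode == "genemodels":
            arr = ["N"] * len(seq)
            for s, e in genome.gene_intervals.get(sid, []):
                arr[s:e] = seq[s:e]
            seqs.append("".join(arr))
        else:
            raise ValueError(f"unknown mode: {mode}")
    return seqs


def build_reference_index(genome: AnnotatedGenome, mode: str, k: int = SEED_K) -> ReferenceIndex:
    """Index one reference dialect for seed-and-verify alignment."""
    if mode == "genemodels" and not any(genome.gene_intervals.values()):
        raise ValueError("genemodels mode requires a non-empty gene set")
    seqs = _searchable(genome, mode)
    arrays = [encode(s) for s in seqs]
    pad = np.full(_PAD, 4, dtype=np.int8)
    pieces = []
    offsets = []
    cur = 0
    for arr in arrays:
        offsets.append(cur)
        pieces.append(arr)
        pieces.append(pad)
        cur += len(arr) + _PAD
    concat = np.concatenate(pieces) if pieces else pad.copy()
    offsets = np.asarray(offsets, dtype=np.int64)
    lengths = np.asarray([len(a) for a in arrays], dtype=np.int64)
    codes_all = []
    pos_all = []
    for arr, off in zip(arrays, offsets):
        codes, pos = _window_codes(arr, k)
        codes_all.append(codes)
        pos_all.append(pos + off)
    codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.uint64)
    pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
    order = np.argsort(codes, kind="stable")
    return ReferenceIndex(
        mode=mode,
        scaffold_ids=genome.scaffold_ids,
        concat=concat,
        offsets=offsets,
        lengths=lengths,
        seed_codes=codes[order],
        seed_positions=pos[order],
        k=k,
    )


@dataclass
class TagAlignment:
    tag_id: str
    sample_id: str
    scaffold_id: str | None
    position: int | None
    strand: str | None
    n_mismatch: int
    indel_len: int
    status: str                      # unique | ambiguous | unaligned
    score: int = 0
    tag_seq: str = ""
    count: int = 1


def verify_batch(query: np.ndarray, index: ReferenceIndex, positions: np.ndarray,
                 max_mismatch: int = MAX_MISMATCH, max_indel: int = MAX_INDEL):
    """Score the query at every candidate global start position.

    Alignment model per position: ungapped, or one contiguous internal
    indel of up to ``max_indel`` bases; score = mismatches + 2 * indel
    bases, valid only when mismatches <= ``max_mismatch`` and the
    reference span lies inside one scaffold.  Returns (positions, score,
    mm, indel) arrays for positions with a valid alignment.
    """
    L = len(query)
    if positions.size == 0:
        return (np.empty(0, dtype=np.int64),) * 4
    si = np.searchsorted(index.offsets, positions, side="right") - 1
    lp = positions - index.offsets[si]
    span_max = L + max_indel
    ok = (lp >= 0) & (positions + span_max < len(index.concat))
    positions, si, lp = positions[ok], si[ok], lp[ok]
    if positions.size == 0:
        return (np.empty(0, dtype=np.int64),) * 4
    scLen = index.lengths[si]
    W = index.concat[positions[:, None] + np.arange(span_max)]
    neq0 = W[:, :L] != query
    cs0 = np.cumsum(neq0, axis=1)
    big = 10 * (max_mismatch + 2 * max_indel + 1)

    def cap(mm, g, fits):
        s = np.where((mm <= max_mismatch) & fits, mm + 2 * g, big)
        return s

    mm0 = cs0[:, -1]
    best = cap(mm0, 0, lp + L <= scLen)
    best_mm = np.where(best < big, mm0, 0)
    best_g = np.zeros_like(best)
    for g in range(1, max_indel + 1):
        # deletion in query (reference span L + g), breakpoint 1..L-1
        neq_d = W[:, g:L + g] != query
        csd = np.cumsum(neq_d, axis=1)
        tot_d = csd[:, -1]
        cost_d = cs0[:, 0:L - 1] + (tot_d[:, None] - csd[:, 0:L - 1])
        mm_d = cost_d.min(axis=1)
        s = cap(mm_d, g, lp + L + g <= scLen)
        upd = s < best
        best_mm = np.where(upd, mm_d, best_mm)
        best_g = np.where(upd, g, best_g)
        best = np.minimum(best, s)
        # insertion in query (reference span L - g), breakpoint 1..L-g-1
        if L - g >= 2:
            neq_i = W[:, :L - g] != query[g:]
            csi = np.cumsum(neq_i, axis=1)
            tot_i = csi[:, -1]
            hi = L - g - 1
            cost_i = cs0[:, 0:hi] + (tot_i[:, None] - csi[:, 0:hi])
            mm_i = cost_i.min(axis=1)
            s = cap(mm_i, g, lp + L - g <= scLen)
            upd = s < best
            best_mm = np.where(upd, mm_i, best_mm)
            best_g = np.where(upd, g, best_g)
            best = np.minimum(best, s)
    hit = best < big
    return positions[hit], best[hit], best_mm[hit], best_g[hit]


def verify_alignment(query: np.ndarray, index: ReferenceIndex, global_pos: int,
                     max_mismatch: int = MAX_MISMATCH,
                     max_indel: int = MAX_INDEL):
    """Best (score, mismatches, indel_bases) at one global position, or
    None when no alignment fits the budget."""
    pos, score, mm, g = verify_batch(
        query, index, np.asarray([global_pos], dtype=np.int64),
        max_mismatch, max_indel,
    )
    if pos.size == 0:
        return None
    return int(score[0]), int(mm[0]), int(g[0])


_POW4 = (np.uint64(4) ** np.arange(SEED_K - 1, -1, -1, dtype=np.uint64))


def _candidates(index: ReferenceIndex, query: np.ndarray, max_indel: int) -> np.ndarray:
    k = index.k
    parts = []
    for off in SEED_OFFSETS:
        seed = query[off:off + k]
        if (seed >= 4).any():
            continue
        code = np.uint64(np.dot(seed.astype(np.uint64), _POW4))
        lo = int(np.searchsorted(index.seed_codes, code, side="left"))
        hi = int(np.searchsorted(index.seed_codes, code, side="right"))
        if hi > lo:
            base = index.seed_positions[lo:hi] - off
            # an indel can only shift seeds downstream of it; the first
            # seed starts at the tag's 5' end, so needs no shift search
            shifts = (0,) if off == 0 else tuple(range(-max_indel, max_indel + 1))
            for d in shifts:
                parts.append(base + d)
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def align_tag(
    tag: str,
    index: ReferenceIndex,
    max_mismatch: int = MAX_MISMATCH,
    max_indel: int = MAX_INDEL,
    tag_id: str = "tag",
    sample_id: str = "",
    count: int = 1,
    tag_length: int = TAG_LENGTH,
) -> TagAlignment:
    """Seed-and-verify alignment of one tag against both strands.

    unique: exactly one best-scoring locus; ambiguous: tied best score
    at more than one locus; unaligned: no locus within budget.
    """
    if len(tag) != tag_length:
        raise ValueError(f"tag length {len(tag)} != {tag_length}")
    hits = []  # (score, mm, indel, global_pos, strand)
    for strand, seq in (("+", tag), ("-", revcomp(tag))):
        query = encode(seq)
        cands = _candidates(index, query, max_indel)
        cands = cands[cands >= 0]
        pos, score, mm, g = verify_batch(query, index, cands, max_mismatch, max_indel)
        for p, s, m, gg in zip(pos, score, mm, g):
            hits.append((int(s), int(m), int(gg), int(p), strand))
    if not hits:
        return TagAlignment(tag_id, sample_id, None, None, None, 0, 0,
                            "unaligned", tag_seq=tag, count=count)
    hits.sort(key=lambda h: (h[0], h[3], h[4]))
    best = hits[0]
    n_best = sum(1 for h in hits if h[0] == best[0])
    status = "unique" if n_best == 1 else "ambiguous"
    si, local = index.locate(best[3])
    return TagAlignment(
        tag_id=tag_id,
        sample_id=sample_id,
        scaffold_id=index.scaffold_ids[si],
        position=local,
        strand=best[4],
        n_mismatch=best[1],
        indel_len=best[2],
        status=status,
        score=best[0],
        tag_seq=tag,
        count=count,
    )


def align_sample_tags(demux_result, index, max_mismatch: int = MAX_MISMATCH,
                      max_indel: int = MAX_INDEL) -> list[TagAlignment]:
    """Align every retained tag of every sample, deduplicating identical
    sequences so each distinct 92-mer is verified once."""
    from collections import Counter

    distinct: Counter[str] = Counter()
    per_sample: dict[str, Counter] = {}
    for sid, sample in demux_result.samples.items():
        c = Counter(t.sequence for t in sample.tags)
        per_sample[sid] = c
        distinct.update(c)
    cache: dict[str, TagAlignment] = {}
    for i, seq in enumerate(distinct):
        cache[seq] = align_tag(seq, index, max_mismatch, max_indel, tag_id=f"t{i}")
    out = []
    for sid, counts in per_sample.items():
        for seq, n in counts.items():
            a = cache[seq]
            out.append(
                TagAlignment(
                    tag_id=a.tag_id, sample_id=sid, scaffold_id=a.scaffold_id,
                    position=a.position, strand=a.strand, n_mismatch=a.n_mismatch,
                    indel_len=a.indel_len, status=a.status, score=a.score,
                    tag_seq=seq, count=n,
                )
            )
    return out


@dataclass
class Cluster:
    """All uniquely aligned reads sharing one locus (scaffold, position,
    strand)."""

    scaffold_id: str
    position: int
    strand: str
    reads: dict[str, dict[str, int]] = field(default_factory=dict)  # sample -> tag seq -> count

    @property
    def locus_id(self) -> str:
        return f"{self.scaffold_id}:{self.position}:{self.strand}"

    def sample_depth(self, sample_id: str) -> int:
        return sum(self.reads.get(sample_id, {}).values())

    @property
    def total_depth(self) -> int:
        return sum(sum(v.values()) for v in self.reads.values())

    def panel_depth(self, panel=("mother", "father")) -> int:
        return sum(self.sample_depth(s) for s in panel)


def build_clusters(
    alignments: list[TagAlignment],
    min_depth: int = DEPTH_WINDOW[0],
    max_depth: int = DEPTH_WINDOW[1],
    panel: tuple[str, ...] = ("mother", "father"),
) -> tuple[list[Cluster], dict]:
    """Group unique alignments by locus; drop clusters whose pooled
    discovery-panel depth falls outside [min_depth, max_depth].

    Returns (clusters, stats) where stats counts dropped loci.
    """
    loci: dict[tuple, Cluster] = {}
    for a in alignments:
        if a.status != "unique":
            continue
        key = (a.scaffold_id, a.position, a.strand)
        cl = loci.get(key)
        if cl is None:
            cl = loci[key] = Cluster(a.scaffold_id, a.position, a.strand)
        per = cl.reads.setdefault(a.sample_id, {})
        per[a.tag_seq] = per.get(a.tag_seq, 0) + a.count
    kept = []
    stats = {"n_loci": len(loci), "dropped_low": 0, "dropped_high": 0}
    for key in sorted(loci):
        cl = loci[key]
        d = cl.panel_depth(panel)
        if d < min_depth:
            stats["dropped_low"] += 1
        elif d > max_depth:
            stats["dropped_high"] += 1
        else:
            kept.append(cl)
    stats["n_kept"] = len(kept)
    return kept, stats


def write_alignment_dump(alignments: list[TagAlignment], path: str | Path) -> None:
    """TSV dump; positions exported 1-based as in all text reports."""
    with open(path, "w") as fh:
        fh.write("tag_id\tsample\tscaffold\tpos\tstrand\tmm\tindel\tstatus\tcount\n")
        for a in alignments:
            pos = "" if a.position is None else a.position + 1
            fh.write(
                f"{a.tag_id}\t{a.sample_id}\t{a.scaffold_id or ''}\t{pos}\t"
                f"{a.strand or ''}\t{a.n_mismatch}\t{a.indel_len}\t{a.status}\t{a.count}\n"
            )
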