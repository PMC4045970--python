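"""Synthetic F1 cross and ddRAD read generator.

Emulates the data a double-digest RAD mapping study produces: a draft
genome with repeat families and gene models, a near-homozygous maternal
parent (the assembly individual) crossed to a heterozygous paternal
parent, 51 F1 progeny, an in-silico NsiI + MseI digest with 200-500 bp
size selection, and barcoded 100 bp single-end reads with per-sample
depth variation.

Two layers are provided:

* a sequence-level simulator (genome -> parents -> gametes -> fragments
  -> FASTQ) used to exercise the full pipeline, and
* a marker-level simulator (``simulate_testcross_dataset``) that draws CP
  genotype matrices directly from the crossover model, used for the
  map-construction and anchoring recovery suites where read-level detail
  is irrelevant.

Crossovers are a Poisson process along the chromosome (no interference),
so truth recombinant fractions between markers follow Haldane's formula;
Kosambi is used only on the estimation side, mirroring the mapping
protocol being modelled.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapfunc import haldane_r

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

NSI_I = ("ATGCAT", 5)   # ATGCA/T
MSE_I = ("TTAA", 1)     # T/TAA

DEFAULT_SIZE_RANGE = (200, 500)
DEFAULT_READ_LEN = 100


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def merge_intervals(intervals):
    """Merge half-open intervals; returns a sorted non-overlapping list."""
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Genome


@dataclass
class RepeatFamilySpec:
    """A repeat family: unit length, copy number, per-base copy divergence.

    ``site_retention`` is the probability that a genomic copy keeps the
    family's internal ddRAD cut sites intact; in decayed copies one base
    of each site is mutated, so most repeat copies contribute alignment
    targets but no fragments, as site loss by mutation does in real
    repeat families.
    """

    unit_length: int
    copy_number: int
    divergence: float
    site_retention: float = 0.15


@dataclass
class AnnotatedGenome:
    """Scaffold sequences plus repeat and gene annotation.

    ``repeat_intervals`` and ``gene_intervals`` are per-scaffold lists of
    0-based half-open intervals, non-overlapping after merge.
    ``repeat_families`` holds the family consensus sequences so that
    downstream simulation can create novel (non-reference) insertions of
    an existing family.
    """

    scaffolds: list[tuple[str, str]]
    repeat_intervals: dict[str, list[tuple[int, int]]]
    gene_intervals: dict[str, list[tuple[int, int]]]
    truth_map: dict[str, list] | None = None
    repeat_families: list[str] = field(default_factory=list)
    repeat_family_sites: list[tuple[int, int]] = field(default_factory=list)

    @property
    def scaffold_ids(self) -> list[str]:
        return [sid for sid, _ in self.scaffolds]

    def sequence(self, scaffold_id: str) -> str:
        for sid, seq in self.scaffolds:
            if sid == scaffold_id:
                return seq
        raise KeyError(scaffold_id)

    def scaffold_lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.scaffolds}

    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.scaffolds)

    def repeat_fraction(self) -> float:
        masked = sum(
            e - s for iv in self.repeat_intervals.values() for s, e in iv
        )
        return masked / self.total_length()


def _place_intervals(rng, length, sizes, occupied):
    """Place non-overlapping intervals of the given sizes on [0, length).

    ``occupied`` is consulted and extended; rejection sampling with a
    bisect neighbour check keeps dense placements fast.
    """
    from bisect import bisect_left, insort

    placed = []
    taken = sorted(occupied)
    for size in sizes:
        if size >= length:
            continue
        for _ in range(200):  # rejection sampling
            s = int(rng.integers(0, length - size))
            e = s + size
            i = bisect_left(taken, (s, e))
            if i > 0 and taken[i - 1][1] > s:
                continue
            if i < len(taken) and taken[i][0] < e:
                continue
            placed.append((s, e))
            insort(taken, (s, e))
            break
    occupied.extend(placed)
    return placed


def _family_consensus(rng: np.random.Generator, unit_length: int) -> tuple[str, int, int]:
    """Random repeat-unit consensus carrying one internal NsiI/MseI ddRAD
    fragment (families without cut sites are invisible to the assay and
    would only dilute the simulation).  Returns (sequence, NsiI site
    position, MseI site position)."""
    site1, site2 = NSI_I[0], MSE_I[0]
    lo = max(10, min(220, unit_length - len(site1) - len(site2) - 30))
    hi = min(unit_length - len(site1) - len(site2) - 12, 420)
    while True:
        seq = _random_seq(rng, unit_length)
        # strip accidental sites, then implant one of each
        seq = seq.replace(site1, "ACGTCA").replace(site2, "GGCC")
        gap = int(rng.integers(lo, max(lo + 1, hi)))
        p1 = int(rng.integers(2, unit_length - gap - len(site1) - len(site2) - 2))
        p2 = p1 + len(site1) + gap
        seq = seq[:p1] + site1 + seq[p1 + len(site1):p2] + site2 + seq[p2 + len(site2):]
        if len(seq) == unit_length:
            return seq, p1, p2


def _repeat_copy(rng: np.random.Generator, consensus: str, p1: int, p2: int,
                 divergence: float, keep_sites: bool) -> str:
    """One genomic copy: per-base divergence, with the internal cut sites
    either restored intact or deliberately decayed."""
    copy = _mutate(rng, consensus, divergence)
    site1, site2 = NSI_I[0], MSE_I[0]
    if keep_sites:
        copy = copy[:p1] + site1 + copy[p1 + len(site1):p2] + site2 + copy[p2 + len(site2):]
    else:
        for p, site in ((p1, site1), (p2, site2)):
            i = p + int(rng.integers(len(site)))
            base = copy[i]
            repl = str(rng.choice([b for b in "ACGT" if b != base]))
            copy = copy[:i] + repl + copy[i + 1:]
    return copy


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_genome(
    n_scaffolds: int = 5,
    scaffold_lengths: int | list[int] = 2_000_000,
    repeat_family_specs: list[RepeatFamilySpec] | list[tuple] | None = None,
    gene_density: float = 0.05,
    seed: int = 0,
) -> AnnotatedGenome:
    """Simulate a draft genome with repeat families and gene models.

    Repeat copies are mutated instances of a per-family consensus placed
    at recorded, non-overlapping intervals.  Gene intervals are placed
    outside repeats to approximately ``gene_density`` of the genome.
    """
    rng = np.random.default_rng(seed)
    if isinstance(scaffold_lengths, int):
        scaffold_lengths = [scaffold_lengths] * n_scaffolds
    if len(scaffold_lengths) != n_scaffolds:
        raise ValueError("scaffold_lengths must match n_scaffolds")
    if min(scaffold_lengths) < 10_000:
        raise ValueError("scaffold lengths must be >= 10 kb")
    specs = [
        s if isinstance(s, RepeatFamilySpec) else RepeatFamilySpec(*s)
        for s in (repeat_family_specs or [])
    ]
    total = sum(scaffold_lengths)
    repeat_bases = sum(s.unit_length * s.copy_number for s in specs)
    if repeat_bases > 0.95 * total:
        raise ValueError("requested repeat content exceeds 95% of genome")

    scaffolds = []
    seqs = {}
    for i, length in enumerate(scaffold_lengths):
        sid = f"scaffold_{i + 1}"
        seqs[sid] = _random_seq(rng, length)
        scaffolds.append(sid)

    fam_data = [_family_consensus(rng, s.unit_length) for s in specs]
    families = [f[0] for f in fam_data]

    # distribute copies over scaffolds proportionally to length
    repeat_intervals: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    weights = np.array(scaffold_lengths, dtype=float)
    weights /= weights.sum()
    for spec, (consensus, p1, p2) in zip(specs, fam_data):
        homes = rng.choice(len(scaffolds), size=spec.copy_number, p=weights)
        by_scaffold: dict[int, int] = {}
        for sc_idx in homes:
            by_scaffold[sc_idx] = by_scaffold.get(sc_idx, 0) + 1
        for sc_idx, n_copies in by_scaffold.items():
            sid = scaffolds[sc_idx]
            placed = _place_intervals(
                rng, scaffold_lengths[sc_idx], [spec.unit_length] * n_copies,
                repeat_intervals[sid],
            )
            arr = seqs[sid]
            pieces = []
            cur = 0
            for s, e in sorted(placed):
                keep = bool(rng.random() < spec.site_retention)
                pieces.append(arr[cur:s])
                pieces.append(
                    _repeat_copy(rng, consensus, p1, p2, spec.divergence, keep)
                )
                cur = e
            pieces.append(arr[cur:])
            seqs[sid] = "".join(pieces)
    repeat_intervals = {s: merge_intervals(v) for s, v in repeat_intervals.items()}

    gene_intervals: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    if gene_density > 0:
        for sid, length in zip(scaffolds, scaffold_lengths):
            target = gene_density * length
            covered = 0
            occupied = list(repeat_intervals[sid])
            guard = 0
            while covered < target and guard < 10_000:
                guard += 1
                size = int(np.clip(rng.lognormal(8.0, 0.4), 500, length // 4))
                size = min(size, int(target - covered) + 500)
                got = _place_intervals(rng, length, [size], occupied)
                for s, e in got:
                    gene_intervals[sid].append((s, e))
                    covered += e - s
            gene_intervals[sid] = merge_intervals(gene_intervals[sid])

    return AnnotatedGenome(
        scaffolds=[(s, seqs[s]) for s in scaffolds],
        repeat_intervals=repeat_intervals,
        gene_intervals=gene_intervals,
        repeat_families=families,
        repeat_family_sites=[(f[1], f[2]) for f in fam_data],
    )


# ---------------------------------------------------------------------------
# Parents


Variant = tuple[int, str, str]  # (ref pos, ref allele, alt allele); anchored like VCF


def apply_variants(seq: str, variants: list[Variant]) -> str:
    """Apply non-overlapping, position-sorted variants to a sequence."""
    out = []
    cur = 0
    for pos, ref, alt in variants:
        out.append(seq[cur:pos])
        out.append(alt)
        cur = pos + len(ref)
    out.append(seq[cur:])
    return "".join(out)


def hap_to_ref(variants: list[Variant], hap_pos: int) -> int:
    """Map a haplotype coordinate back to the reference coordinate."""
    shift = 0
    for pos, ref, alt in variants:
        hap_start = pos + shift
        if hap_start + len(alt) > hap_pos:
            break
        shift += len(alt) - len(ref)
    return hap_pos - shift


@dataclass
class ParentPair:
    """Two parental diploids over one reference genome.

    Haplotype 0 of each parent is the reference itself (the maternal
    parent is the assembly individual); haplotype 1 carries that parent's
    heterozygous variants.  Repeat-insertion presence/absence variants on
    the paternal haplotype model young transposon copies absent from the
    reference assembly.
    """

    genome: AnnotatedGenome
    maternal_variants: dict[str, list[Variant]]
    paternal_variants: dict[str, list[Variant]]
    het_rate_maternal: float
    het_rate_paternal: float

    def variants(self, parent: str, scaffold: str) -> list[Variant]:
        table = self.maternal_variants if parent == "maternal" else self.paternal_variants
        return table.get(scaffold, [])

    def haplotype(self, parent: str, hap: int, scaffold: str) -> str:
        ref = self.genome.sequence(scaffold)
        if hap == 0:
            return ref
        return apply_variants(ref, self.variants(parent, scaffold))

    def het_sites(self) -> pd.DataFrame:
        rows = []
        for parent, table in (
            ("maternal", self.maternal_variants),
            ("paternal", self.paternal_variants),
        ):
            for sid, variants in table.items():
                for pos, ref, alt in variants:
                    if len(ref) == 1 and len(alt) == 1:
                        kind = "snp"
                    elif len(alt) > len(ref) and len(alt) - len(ref) <= 2:
                        kind = "ins"
                    elif len(ref) > len(alt) and len(ref) - len(alt) <= 2:
                        kind = "del"
                    else:
                        kind = "repeat_insertion"
                    rows.append((parent, sid, pos, ref, alt, kind))
        return pd.DataFrame(
            rows, columns=["parent", "scaffold", "pos", "ref", "alt", "kind"]
        )

    def n_het_sites(self, parent: str) -> int:
        table = self.maternal_variants if parent == "maternal" else self.paternal_variants
        return sum(len(v) for v in table.values())


def _draw_variants(rng, seq, rate, snp_frac, min_gap=6):
    length = len(seq)
    n = rng.binomial(length, rate)
    positions = np.sort(rng.choice(length - 4, size=min(n, length // min_gap), replace=False))
    variants: list[Variant] = []
    last_end = -min_gap
    for pos in positions:
        pos = int(pos)
        if pos - last_end < min_gap:
            continue
        ref1 = seq[pos]
        if ref1 == "N":
            continue
        if rng.random() < snp_frac:
            alt = rng.choice([b for b in "ACGT" if b != ref1])
            variants.append((pos, ref1, str(alt)))
            last_end = pos + 1
        else:
            ilen = int(rng.integers(1, 3))  # 1-2 bp
            if rng.random() < 0.5:
                ins = _random_seq(rng, ilen)
                variants.append((pos, ref1, ref1 + ins))
                last_end = pos + 1
            else:
                refseg = seq[pos:pos + 1 + ilen]
                if "N" in refseg or len(refseg) < 1 + ilen:
                    continue
                variants.append((pos, refseg, refseg[0]))
                last_end = pos + 1 + ilen
    return variants


def _fragment_bearing_repeat_copies(genome: AnnotatedGenome) -> list[tuple[str, int]]:
    """Genomic repeat copies whose sequence yields a retained ddRAD
    fragment; returns (copy sequence, tag start within copy) per copy."""
    out = []
    for sid, intervals in genome.repeat_intervals.items():
        seq = genome.sequence(sid)
        for s, e in intervals:
            sub = seq[s:e]
            for frag in digest_ddrad(sub, scaffold_id=sid):
                if frag.side5_enzyme == 1:
                    out.append((sub, frag.start))
                else:
                    out.append((revcomp(sub), len(sub) - frag.end))
                break
    return out


def simulate_parents(
    genome: AnnotatedGenome,
    het_rate_maternal: float = 0.0003,
    het_rate_paternal: float = 0.0037,
    seed: int = 0,
    snp_frac: float = 0.9,
    repeat_insertions_per_mb: float = 8.0,
) -> ParentPair:
    """Draw parental heterozygous variants on top of the reference.

    Rates are per-base heterozygous-site densities (0.03% maternal /
    0.37% paternal by default, the twelve-fold contrast this design
    assumes).  ``repeat_insertions_per_mb`` adds paternal heterozygous
    presence/absence insertions of an existing repeat family (0 when the
    genome has no repeat families).
    """
    import warnings

    for rate in (het_rate_maternal, het_rate_paternal):
        if not 0 <= rate <= 0.05:
            raise ValueError("heterozygosity rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    total = genome.total_length()
    if 0 < het_rate_maternal * total < 1 or 0 < het_rate_paternal * total < 1:
        warnings.warn("expected heterozygous-site count below 1; proceeding")

    maternal: dict[str, list[Variant]] = {}
    paternal: dict[str, list[Variant]] = {}
    for sid, seq in genome.scaffolds:
        maternal[sid] = _draw_variants(rng, seq, het_rate_maternal, snp_frac)
        paternal[sid] = _draw_variants(rng, seq, het_rate_paternal, snp_frac)

    if genome.repeat_families and repeat_insertions_per_mb > 0:
        # heterozygous transposition events on the paternal haplotype:
        # a young copy derives from one genomic source element (keeping
        # its private substitutions) plus 1-2 new substitutions inside
        # the ddRAD tag, so its reads best-match the source copy
        n_ins = rng.poisson(repeat_insertions_per_mb * total / 1e6)
        lengths = genome.scaffold_lengths()
        sids = genome.scaffold_ids
        weights = np.array([lengths[s] for s in sids], dtype=float)
        weights /= weights.sum()
        sources = _fragment_bearing_repeat_copies(genome)
        for _ in range(min(n_ins, len(sources)) if sources else 0):
            src_seq, tag_start = sources[int(rng.integers(len(sources)))]
            copy = list(src_seq)
            lo = tag_start + 2
            hi = min(tag_start + 90, len(copy) - 1)
            if hi <= lo:
                continue
            for _k in range(int(rng.integers(1, 3))):
                i = int(rng.integers(lo, hi))
                copy[i] = str(rng.choice([b for b in "ACGT" if b != copy[i]]))
            copy = "".join(copy)
            sid = sids[int(rng.choice(len(sids), p=weights))]
            pos = int(rng.integers(10, lengths[sid] - 10))
            existing = paternal[sid]
            if any(abs(pos - p) < 8 for p, _, _ in existing):
                continue
            ref1 = genome.sequence(sid)[pos]
            if ref1 == "N":
                continue
            existing.append((pos, ref1, ref1 + copy))
            existing.sort()

    for table in (maternal, paternal):
        for sid in table:
            table[sid].sort()
    return ParentPair(
        genome=genome,
        maternal_variants=maternal,
        paternal_variants=paternal,
        het_rate_maternal=het_rate_maternal,
        het_rate_paternal=het_rate_paternal,
    )


# ---------------------------------------------------------------------------
# F1 progeny


@dataclass
class Gamete:
    """One meiotic product: starting haplotype and crossover breakpoints
    (reference coordinates, strictly increasing)."""

    start_hap: int
    breakpoints: list[int]

    def hap_at(self, pos: int) -> int:
        return (self.start_hap + bisect_right(self.breakpoints, pos)) % 2


@dataclass
class ProgenySet:
    parents: ParentPair
    n_progeny: int
    gametes: list[dict[str, dict[str, Gamete]]]  # [progeny][parent][scaffold]
    truth_cm_per_mb: float

    def gamete_variants(self, i: int, parent: str, scaffold: str) -> list[Variant]:
        g = self.gametes[i][parent][scaffold]
        return [v for v in self.parents.variants(parent, scaffold) if g.hap_at(v[0]) == 1]

    def gamete_sequence(self, i: int, parent: str, scaffold: str) -> str:
        ref = self.parents.genome.sequence(scaffold)
        return apply_variants(ref, self.gamete_variants(i, parent, scaffold))

    def truth_genotypes(self) -> pd.DataFrame:
        """Truth allele (0=ref,1=alt) per parental het site per progeny."""
        rows = []
        for parent in ("maternal", "paternal"):
            table = (
                self.parents.maternal_variants
                if parent == "maternal"
                else self.parents.paternal_variants
            )
            for sid, variants in table.items():
                for pos, ref, alt in variants:
                    alleles = [
                        self.gametes[i][parent][sid].hap_at(pos)
                        for i in range(self.n_progeny)
                    ]
                    rows.append([parent, sid, pos, ref, alt] + alleles)
        cols = ["parent", "scaffold", "pos", "ref", "alt"] + [
            f"p{i + 1:02d}" for i in range(self.n_progeny)
        ]
        return pd.DataFrame(rows, columns=cols)


def _draw_gamete(rng, length_bp, cm_per_mb) -> Gamete:
    expected = length_bp / 1e6 * cm_per_mb / 100.0  # crossovers per gamete
    n_xo = rng.poisson(expected)
    breaks = sorted(int(b) for b in rng.integers(1, length_bp, size=n_xo))
    return Gamete(start_hap=int(rng.integers(0, 2)), breakpoints=breaks)


def simulate_f1(
    parents: ParentPair,
    truth_cm_per_mb: float = 0.9,
    n_progeny: int = 51,
    seed: int = 0,
) -> ProgenySet:
    """Draw independent gametes per progeny: Poisson crossovers, no
    interference, one maternal and one paternal gamete each."""
    if n_progeny < 2:
        raise ValueError("need at least 2 progeny")
    rng = np.random.default_rng(seed)
    lengths = parents.genome.scaffold_lengths()
    gametes = []
    for _ in range(n_progeny):
        per_parent = {}
        for parent in ("maternal", "paternal"):
            per_parent[parent] = {
                sid: _draw_gamete(rng, length, truth_cm_per_mb)
                for sid, length in lengths.items()
            }
        gametes.append(per_parent)
    return ProgenySet(
        parents=parents,
        n_progeny=n_progeny,
        gametes=gametes,
        truth_cm_per_mb=truth_cm_per_mb,
    )


# ---------------------------------------------------------------------------
# Digest


@dataclass
class RadFragment:
    scaffold_id: str
    start: int
    end: int
    side5_enzyme: int  # 1 = enzyme1 (NsiI), 2 = enzyme2 (MseI)
    side3_enzyme: int
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def digest_ddrad(
    sequence: str,
    enzyme1: tuple[str, int] = NSI_I,
    enzyme2: tuple[str, int] = MSE_I,
    min_len: int = DEFAULT_SIZE_RANGE[0],
    max_len: int = DEFAULT_SIZE_RANGE[1],
    scaffold_id: str = "seq",
) -> list[RadFragment]:
    """Simultaneous double digest with size selection.

    Returns fragments flanked by one cut of each enzyme with
    min_len <= length <= max_len, coordinates 0-based half-open on the
    input sequence.  Both recognition sites here are palindromic, so a
    forward-strand scan finds every cut.
    """
    cuts = []
    for enz_id, (site, cut_after) in ((1, enzyme1), (2, enzyme2)):
        pat = re.compile("(?=" + re.escape(site) + ")")
        cuts.extend((m.start() + cut_after, enz_id) for m in pat.finditer(sequence))
    cuts.sort()
    frags = []
    for (c1, e1), (c2, e2) in zip(cuts, cuts[1:]):
        length = c2 - c1
        if e1 != e2 and min_len <= length <= max_len:
            frags.append(
                RadFragment(
                    scaffold_id=scaffold_id,
                    start=c1,
                    end=c2,
                    side5_enzyme=e1,
                    side3_enzyme=e2,
                    sequence=sequence[c1:c2],
                )
            )
    return frags


# ---------------------------------------------------------------------------
# Reads


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    quality: str


def _quality_strings(rng, depth, n, q_mean, q_sd):
    q = np.clip(np.rint(rng.normal(q_mean, q_sd, (depth, n))), 2, 41)
    q = (q + 33).astype(np.uint8)
    return [bytes(row).decode("ascii") for row in q]


def _add_errors(rng, seq, error_rate):
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
    return "".join(arr)


def _locus_depths(rng, n, mean_depth, dispersion):
    if mean_depth <= 0:
        return np.zeros(n, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean_depth, n)
    lam = rng.gamma(1.0 / dispersion, mean_depth * dispersion, n)
    return rng.poisson(lam)


def generate_reads(
    fragments: list[RadFragment],
    barcode: str,
    mean_depth: float,
    depth_dispersion: float = 0.3,
    error_rate: float = 0.001,
    read_len: int = DEFAULT_READ_LEN,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    q_mean: float = 38.0,
    q_sd: float = 2.0,
    sample_id: str = "sample",
) -> list[FastqRead]:
    """Reads for one sample: barcode + genomic bases from the NsiI end of
    each fragment, truncated to ``read_len``; per-locus depth drawn with
    gamma-Poisson (negative-binomial-style) dispersion."""
    if not 4 <= len(barcode) <= 8:
        raise ValueError("barcode length must be 4-8 bp")
    if rng is None:
        rng = np.random.default_rng(seed)
    reads = []
    depths = _locus_depths(rng, len(fragments), mean_depth, depth_dispersion)
    for frag, depth in zip(fragments, depths):
        if depth == 0:
            continue
        if frag.side5_enzyme == 1:
            template = frag.sequence
            strand = "+"
        else:
            template = revcomp(frag.sequence)
            strand = "-"
        genomic = template[: read_len - len(barcode)]
        quals = _quality_strings(rng, depth, len(barcode) + len(genomic), q_mean, q_sd)
        # errors are rare; draw the per-read error flags in one batch
        if error_rate > 0:
            any_err = rng.random(depth) < (1 - (1 - error_rate) ** len(genomic))
        else:
            any_err = np.zeros(depth, dtype=bool)
        base = barcode + genomic
        prefix = f"{sample_id}:{frag.scaffold_id}:{frag.start}-{frag.end}:{strand}:"
        for k in range(depth):
            if any_err[k]:
                n_err = max(1, rng.binomial(len(genomic), error_rate))
                g = list(genomic)
                for i in rng.choice(len(g), size=min(n_err, len(g)), replace=False):
                    g[i] = str(rng.choice([b for b in "ACGT" if b != g[i]]))
                seq = barcode + "".join(g)
            else:
                seq = base
            reads.append(FastqRead(prefix + str(k), seq, quals[k]))
    return reads


def make_barcodes(sample_ids: list[str], seed: int = 0) -> dict[str, str]:
    """Distinct 4-8 bp barcodes, no barcode a prefix of another (so exact
    prefix demultiplexing is unambiguous)."""
    rng = np.random.default_rng(seed)
    barcodes: dict[str, str] = {}
    used: list[str] = []
    for sid in sample_ids:
        while True:
            n = int(rng.integers(4, 9))
            bc = _random_seq(rng, n)
            if all(not bc.startswith(u) and not u.startswith(bc) for u in used):
                used.append(bc)
                barcodes[sid] = bc
                break
    return barcodes


def simulate_cross_reads(
    progeny: ProgenySet,
    barcodes: dict[str, str],
    mean_depth: float = 8.0,
    depth_dispersion: float = 0.3,
    error_rate: float = 0.001,
    read_len: int = DEFAULT_READ_LEN,
    parent_depth_multiplier: float = 2.0,
    min_len: int = DEFAULT_SIZE_RANGE[0],
    max_len: int = DEFAULT_SIZE_RANGE[1],
    seed: int = 0,
) -> list[FastqRead]:
    """Pooled multiplexed FASTQ for the whole cross.

    ``barcodes`` must contain entries for ``mother``, ``father`` and each
    progeny id ``p01`` ... (see :func:`make_barcodes`).  Each individual's
    two haplotypes are digested separately so presence/absence and indel
    variation changes the fragment complement, and each haplotype is
    sampled at half the individual depth.  Parents get
    ``parent_depth_multiplier`` times the progeny depth.
    """
    rng = np.random.default_rng(seed)
    parents = progeny.parents
    genome = parents.genome
    reads: list[FastqRead] = []

    def sample_reads(sample_id, hap_seqs, depth):
        for sid, seq in hap_seqs:
            frags = digest_ddrad(
                seq, min_len=min_len, max_len=max_len, scaffold_id=sid
            )
            reads.extend(
                generate_reads(
                    frags,
                    barcodes[sample_id],
                    depth / 2.0,
                    depth_dispersion,
                    error_rate,
                    read_len,
                    rng=rng,
                    sample_id=sample_id,
                )
            )

    for parent, sample_id in (("maternal", "mother"), ("paternal", "father")):
        for hap in (0, 1):
            sample_reads(
                sample_id,
                [(sid, parents.haplotype(parent, hap, sid)) for sid in genome.scaffold_ids],
                mean_depth * parent_depth_multiplier,
            )

    for i in range(progeny.n_progeny):
        sample_id = f"p{i + 1:02d}"
        for parent in ("maternal", "paternal"):
            sample_reads(
                sample_id,
                [
                    (sid, progeny.gamete_sequence(i, parent, sid))
                    for sid in genome.scaffold_ids
                ],
                mean_depth,
            )
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# ---------------------------------------------------------------------------
# Marker-level simulator (map construction / anchoring suites)


def simulate_testcross_dataset(
    n_lgs: int = 5,
    markers_per_lg: int = 40,
    spacing_cm: float = 2.5,
    n_progeny: int = 51,
    seed: int = 0,
    missing_rate: float = 0.02,
    scaffolds_per_lg: int = 4,
    mb_per_cm: float = 1.1,
    flip_prob: float = 0.5,
) -> dict:
    """CP genotype matrix drawn directly from the crossover model.

    One paternal testcross marker per truth position, ``spacing_cm``
    apart along each linkage group; recombination between neighbours
    follows Haldane's formula (Poisson crossovers).  Markers are assigned
    to contiguous physical scaffolds (``scaffolds_per_lg`` per LG) at
    ``mb_per_cm``; each scaffold is reverse-oriented with probability
    ``flip_prob`` so orientation recovery can be scored.

    Returns dict with ``calls`` (marker x progeny CP codes nn/np/--),
    ``info`` (marker, lg_true, cm_true, scaffold, pos, seg_type) and
    ``scaffold_truth`` (scaffold, lg_true, orientation_true).
    """
    rng = np.random.default_rng(seed)
    r_step = haldane_r(spacing_cm)
    calls_rows = []
    info_rows = []
    scaffold_rows = []
    progeny_ids = [f"p{i + 1:02d}" for i in range(n_progeny)]
    for lg in range(1, n_lgs + 1):
        m = markers_per_lg
        # gamete alleles: start Bernoulli(0.5), switch with prob r between neighbours
        alleles = np.empty((n_progeny, m), dtype=int)
        alleles[:, 0] = rng.integers(0, 2, n_progeny)
        switches = rng.random((n_progeny, m - 1)) < r_step
        for j in range(1, m):
            alleles[:, j] = alleles[:, j - 1] ^ switches[:, j - 1]
        cm = np.arange(m) * spacing_cm
        # contiguous physical scaffolds, optionally flipped
        bounds = np.array_split(np.arange(m), scaffolds_per_lg)
        for k, idx in enumerate(bounds):
            sc_id = f"lg{lg}_sc{k + 1}"
            flipped = bool(rng.random() < flip_prob)
            span_cm = cm[idx] - cm[idx[0]]
            pos = (span_cm * mb_per_cm * 1e6).astype(int)
            if flipped:
                pos = pos.max() - pos
            scaffold_rows.append((sc_id, lg, "-" if flipped else "+"))
            for j, p in zip(idx, pos):
                marker = f"m_lg{lg}_{j + 1:03d}"
                info_rows.append((marker, lg, float(cm[j]), sc_id, int(p), "nnxnp"))
                row = np.where(alleles[:, j] == 1, "np", "nn").astype(object)
                if missing_rate > 0:
                    row[rng.random(n_progeny) < missing_rate] = "--"
                calls_rows.append(row)
    info = pd.DataFrame(
        info_rows, columns=["marker", "lg_true", "cm_true", "scaffold", "pos", "seg_type"]
    ).set_index("marker")
    calls = pd.DataFrame(calls_rows, index=info.index, columns=progeny_ids)
    scaffold_truth = pd.DataFrame(
        scaffold_rows, columns=["scaffold", "lg_true", "orientation_true"]
    ).set_index("scaffold")
    return {"calls": calls, "info": info, "scaffold_truth": scaffold_truth}


def simulate_site_summaries(
    parents: ParentPair,
    parent: str = "paternal",
    depth_range: tuple[int, int] = (20, 60),
    error_site_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site pileup summaries at a parent's heterozygous sites.

    Depth uniform over ``depth_range``; allele counts binomial(depth,
    0.5).  ``error_site_rate`` adds homozygous sites with a low-fraction
    error allele per base of genome, to exercise the minor-fraction
    filter.
    """
    rng = np.random.default_rng(seed)
    het = parents.het_sites()
    het = het[(het.parent == parent) & (het.kind != "repeat_insertion")]
    rows = []
    for _, site in het.iterrows():
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        a = rng.binomial(depth, 0.5)
        rows.append((site.scaffold, site.pos, depth, site.ref, int(a), site.alt, int(depth - a)))
    if error_site_rate > 0:
        for sid, seq in parents.genome.scaffolds:
            n_err = rng.poisson(error_site_rate * len(seq))
            for pos in rng.integers(0, len(seq), n_err):
                depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
                minor = max(1, int(round(depth * 0.05)))
                ref = seq[int(pos)]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                rows.append((sid, int(pos), depth, ref, depth - minor, alt, minor))
    df = pd.DataFrame(
        rows, columns=["scaffold", "pos", "depth", "alleleA", "countA", "alleleB", "countB"]
    )
    return df.sort_values(["scaffold", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# File export


def write_fasta(genome_or_records, path: str | Path, masked: bool = False,
                repeat_intervals: dict | None = None) -> None:
    """Write scaffolds as FASTA; with ``masked`` the repeat intervals are
    hard-masked to N."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if isinstance(genome_or_records, AnnotatedGenome):
        items = genome_or_records.scaffolds
        repeat_intervals = genome_or_records.repeat_intervals
    else:
        items = genome_or_records
    records = []
    for sid, seq in items:
        if masked and repeat_intervals:
            arr = list(seq)
            for s, e in repeat_intervals.get(sid, []):
                arr[s:e] = "N" * (e - s)
            seq = "".join(arr)
        records.append(SeqRecord(Seq(seq), id=sid, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(intervals):
            for s, e in intervals[sid]:
                fh.write(f"{sid}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid, s, e = line.split()[:3]
            out.setdefault(sid, []).append((int(s), int(e)))
    return {sid: merge_intervals(iv) for sid, iv in out.items()}


def write_fastq(reads: list[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_barcode_table(barcodes: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbarcode\n")
        for sid, bc in barcodes.items():
            fh.write(f"{sid}\t{bc}\n")


def write_truth_table(progeny: ProgenySet, path: str | Path) -> None:
    """Truth table: site, scaffold, position, truth cM, per-progeny truth
    genotype (0=ref allele, 1=alt allele)."""
    df = progeny.truth_genotypes()
    df = df.copy()
    df.insert(3, "truth_cm", df["pos"] / 1e6 * progeny.truth_cm_per_mb)
    df.to_csv(path, sep="\t", index=False)
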