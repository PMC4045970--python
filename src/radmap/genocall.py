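"""Marker discovery and CP genotype calling from tag clusters.

A cluster's distinct tag sequences are its candidate alleles; a sample
is heterozygous when each of two alleles carries at least 25% of that
sample's reads.  Parental genotypes define the segregation type in
cross-pollinator (CP) convention:

* father het, mother hom  -> nn x np   (paternal testcross, 1:1)
* mother het, father hom  -> lm x ll   (maternal testcross, 1:1)
* both het, shared alleles-> hk x hk   (intercross, 1:2:1)

Marker-quality filters follow the discovery protocol: progeny calls need
>= 3 reads and a locus must reach that depth in > 90% of progeny; a
retained marker may miss at most 10% of progeny; testcross markers with
class ratio > 3:1 and dominant-coded intercross markers with ratio
> 10:1 are excluded as distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tagmap import Cluster

MIN_PROGENY_DEPTH = 3
MIN_CALLED_FRACTION = 0.90     # strict: fraction with >= 3x must exceed this
MAX_MISSING = 0.10
HET_MINOR_FRACTION = 0.25
RATIO_1TO1 = 3.0
RATIO_3TO1 = 10.0
MIN_INFORMATIVE = 10
MISSING = "--"

SEG_PATERNAL = "nnxnp"
SEG_MATERNAL = "lmxll"
SEG_INTERCROSS = "hkxhk"
SEG_UNINFORMATIVE = "uninformative"


@dataclass
class MarkerLocus:
    locus_id: str
    scaffold_id: str
    position: int
    alleles: tuple[str, ...]
    maternal_genotype: tuple[int, ...] | None   # indices into alleles
    paternal_genotype: tuple[int, ...] | None
    segregation_type: str
    calls: dict[str, str] = field(default_factory=dict)   # progeny -> CP code
    depths: dict[str, int] = field(default_factory=dict)

    @property
    def missing_fraction(self) -> float:
        if not self.calls:
            return 1.0
        n_miss = sum(1 for c in self.calls.values() if c == MISSING)
        return n_miss / len(self.calls)


def call_sample_genotype(allele_counts: dict[str, int],
                         min_depth: int = MIN_PROGENY_DEPTH,
                         het_minor_fraction: float = HET_MINOR_FRACTION):
    """Genotype one sample from its per-allele read counts.

    Returns a tuple of 1 or 2 allele keys, or None when depth is below
    ``min_depth``.  Heterozygous only when two alleles each reach the
    minor-fraction threshold; low-count alleles are treated as errors.
    """
    depth = sum(allele_counts.values())
    if depth < min_depth:
        return None
    ranked = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top, second = ranked[0], ranked[1] if len(ranked) > 1 else (None, 0)
    if second[1] >= het_minor_fraction * depth:
        return tuple(sorted((top[0], second[0])))
    return (top[0],)


def call_locus_alleles(cluster: Cluster,
                       parent_ids: tuple[str, str] = ("mother", "father"),
                       het_minor_fraction: float = HET_MINOR_FRACTION,
                       min_parent_depth: int = MIN_PROGENY_DEPTH):
    """Identify the allele set of a cluster from the parental panel.

    Each parent is genotyped from its own reads (the 25% minor-fraction
    rule applied per sample, low-count sequences treated as errors);
    the locus allele set is the union of parental alleles.  More than
    two alleles violates diploidy and discards the locus (None).
    Returns (alleles, maternal_genotype, paternal_genotype) with
    genotypes as tuples of allele sequences or None when a parent is
    not callable.
    """
    genotypes = []
    for pid in parent_ids:
        counts = cluster.reads.get(pid, {})
        if not counts:
            genotypes.append(None)
            continue
        genotypes.append(
            call_sample_genotype(counts, min_parent_depth, het_minor_fraction)
        )
    alleles = sorted({a for gt in genotypes if gt for a in gt})
    if not alleles or len(alleles) > 2:
        return None
    return tuple(alleles), genotypes[0], genotypes[1]


def type_parental_segregation(maternal_genotype, paternal_genotype) -> str:
    """CP segregation type from the two parental genotypes."""
    if maternal_genotype is None or paternal_genotype is None:
        return SEG_UNINFORMATIVE
    m_het = len(set(maternal_genotype)) == 2
    p_het = len(set(paternal_genotype)) == 2
    if p_het and not m_het:
        return SEG_PATERNAL
    if m_het and not p_het:
        return SEG_MATERNAL
    if m_het and p_het and set(maternal_genotype) == set(paternal_genotype):
        return SEG_INTERCROSS
    return SEG_UNINFORMATIVE


def _cp_code(seg_type, genotype, maternal_genotype, paternal_genotype):
    if genotype is None:
        return MISSING
    gset = set(genotype)
    if seg_type == SEG_PATERNAL:
        hom = next(iter(set(maternal_genotype)))
        alt = next(a for a in set(paternal_genotype) if a != hom)
        # carrying the paternal alternate allele is diagnostic for np
        return "np" if alt in gset else "nn"
    if seg_type == SEG_MATERNAL:
        hom = next(iter(set(paternal_genotype)))
        alt = next(a for a in set(maternal_genotype) if a != hom)
        return "lm" if alt in gset else "ll"
    if seg_type == SEG_INTERCROSS:
        h, k = sorted(set(maternal_genotype))
        if gset == {h}:
            return "hh"
        if gset == {h, k}:
            return "hk"
        if gset == {k}:
            return "kk"
        return MISSING
    return MISSING


def genotype_progeny(
    cluster: Cluster,
    progeny_ids: list[str],
    parent_ids: tuple[str, str] = ("mother", "father"),
    min_depth: int = MIN_PROGENY_DEPTH,
    min_called_fraction: float = MIN_CALLED_FRACTION,
    het_minor_fraction: float = HET_MINOR_FRACTION,
) -> tuple[MarkerLocus | None, str]:
    """Call per-progeny CP genotypes for one cluster.

    Returns (locus, "ok"), or (None, reason) when the locus is
    monomorphic, not parent-typeable, or reaches ``min_depth`` in too
    few progeny (the called fraction must strictly exceed
    ``min_called_fraction``).
    """
    res = call_locus_alleles(cluster, parent_ids, het_minor_fraction, min_depth)
    if res is None:
        return None, "multiallelic_or_no_parent_reads"
    alleles, m_gt, p_gt = res
    if len(alleles) < 2:
        return None, "monomorphic"
    seg = type_parental_segregation(m_gt, p_gt)
    if seg == SEG_UNINFORMATIVE:
        return None, "uninformative_parents"
    n_deep = 0
    calls = {}
    depths = {}
    for pid in progeny_ids:
        counts = {
            seq: n for seq, n in cluster.reads.get(pid, {}).items() if seq in alleles
        }
        depth = sum(counts.values())
        depths[pid] = depth
        if depth >= min_depth:
            n_deep += 1
            gt = call_sample_genotype(counts, min_depth, het_minor_fraction)
        else:
            gt = None
        calls[pid] = _cp_code(seg, gt, m_gt, p_gt)
    if n_deep / len(progeny_ids) <= min_called_fraction:
        return None, "low_called_fraction"
    return MarkerLocus(
        locus_id=cluster.locus_id,
        scaffold_id=cluster.scaffold_id,
        position=cluster.position,
        alleles=alleles,
        maternal_genotype=m_gt,
        paternal_genotype=p_gt,
        segregation_type=seg,
        calls=calls,
        depths=depths,
    ), "ok"


def filter_integrity(locus: MarkerLocus, max_missing: float = MAX_MISSING) -> bool:
    """Keep when the missing fraction over all progeny is <= max_missing."""
    return locus.missing_fraction <= max_missing


def filter_distortion(
    locus_or_calls,
    seg_type: str | None = None,
    ratio_1to1: float = RATIO_1TO1,
    ratio_3to1: float = RATIO_3TO1,
    min_informative: int = MIN_INFORMATIVE,
) -> tuple[bool, str]:
    """Segregation-distortion filter.

    1:1 (testcross) markers are dropped when major:minor exceeds 3;
    intercross markers in dominant 3:1 coding are dropped when
    dominant:recessive exceeds 10 (checked for both dominant codings).
    Returns (keep, reason).
    """
    if isinstance(locus_or_calls, MarkerLocus):
        calls = list(locus_or_calls.calls.values())
        seg_type = locus_or_calls.segregation_type
    else:
        calls = list(locus_or_calls)
    calls = [c for c in calls if c != MISSING]
    if len(calls) < min_informative:
        return False, "too_few_informative"
    counts = pd.Series(calls).value_counts()
    if seg_type in (SEG_PATERNAL, SEG_MATERNAL):
        a, b = (("nn", "np") if seg_type == SEG_PATERNAL else ("ll", "lm"))
        n_a, n_b = int(counts.get(a, 0)), int(counts.get(b, 0))
        major, minor = max(n_a, n_b), min(n_a, n_b)
        if minor == 0 or major / minor > ratio_1to1:
            return False, "distorted_1to1"
        return True, "ok"
    if seg_type == SEG_INTERCROSS:
        hh = int(counts.get("hh", 0))
        hk = int(counts.get("hk", 0))
        kk = int(counts.get("kk", 0))
        for dom, rec in ((hh + hk, kk), (kk + hk, hh)):
            if rec == 0 or dom / rec > ratio_3to1:
                return False, "distorted_3to1"
        return True, "ok"
    return False, "uninformative"


@dataclass
class GenotypeMatrix:
    """Markers x progeny CP call table with provenance.

    ``calls``: DataFrame indexed by marker id, columns = progeny, values
    CP codes ('--' missing).  ``info``: per-marker metadata (scaffold,
    pos, seg_type, source).
    """

    calls: pd.DataFrame
    info: pd.DataFrame
    reference_mode: str = ""
    filter_log: pd.DataFrame | None = None

    @property
    def n_markers(self) -> int:
        return len(self.calls)

    @property
    def n_progeny(self) -> int:
        return len(self.calls.columns)


def score_markers(
    clusters,
    progeny_ids: list[str],
    reference_mode: str = "",
    parent_ids: tuple[str, str] = ("mother", "father"),
    min_depth: int = MIN_PROGENY_DEPTH,
    min_called_fraction: float = MIN_CALLED_FRACTION,
    max_missing: float = MAX_MISSING,
) -> GenotypeMatrix:
    """Full marker-discovery pipeline over clusters: allele calling,
    progeny genotyping, integrity and distortion filters.

    The returned filter log records every polymorphic locus and why it
    was dropped, so scored-marker accounting is reproducible.
    """
    rows = {}
    info_rows = []
    log = []
    for cl in clusters:
        locus, reason = genotype_progeny(
            cl, progeny_ids, parent_ids, min_depth, min_called_fraction
        )
        if locus is None:
            log.append((cl.locus_id, "dropped", reason))
            continue
        if not filter_integrity(locus, max_missing):
            log.append((locus.locus_id, "dropped", "integrity"))
            continue
        keep, reason = filter_distortion(locus)
        if not keep:
            log.append((locus.locus_id, "dropped", reason))
            continue
        log.append((locus.locus_id, "kept", "ok"))
        rows[locus.locus_id] = locus.calls
        info_rows.append(
            (locus.locus_id, locus.scaffold_id, locus.position,
             locus.segregation_type, "radseq")
        )
    info = pd.DataFrame(
        info_rows, columns=["marker", "scaffold", "pos", "seg_type", "source"]
    ).set_index("marker")
    calls = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=progeny_ids, index=info.index
    ).fillna(MISSING)
    filter_log = pd.DataFrame(log, columns=["locus", "status", "reason"])
    return GenotypeMatrix(calls=calls, info=info,
                          reference_mode=reference_mode, filter_log=filter_log)


def write_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Genotype matrix TSV: marker, scaffold, pos (1-based), seg_type,
    source, then one CP call per progeny."""
    df = matrix.info.copy()
    df["pos"] = df["pos"] + 1
    out = pd.concat([df, matrix.calls], axis=1)
    out.to_csv(path, sep="\t", index_label="marker")


def write_loc_file(matrix: GenotypeMatrix, path: str | Path, name: str = "radmap") -> None:
    """CP-population loc-style export (name / popt=CP / nloc / nind header)."""
    with open(path, "w") as fh:
        fh.write(f"name = {name}\npopt = CP\n")
        fh.write(f"nloc = {matrix.n_markers}\nnind = {matrix.n_progeny}\n\n")
        for marker, row in matrix.calls.iterrows():
            seg = matrix.info.loc[marker, "seg_type"]
            seg_tag = {SEG_PATERNAL: "<nnxnp>", SEG_MATERNAL: "<lmxll>",
                       SEG_INTERCROSS: "<hkxhk>"}.get(seg, "<nnxnp>")
            fh.write(f"{marker} {seg_tag} " + " ".join(row.values) + "\n")
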