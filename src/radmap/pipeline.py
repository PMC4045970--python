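"""Stage orchestration: file-driven pipeline with manifests.

Each stage reads its inputs from the working directory, writes text
artifacts, and records a manifest (input hashes, config hash, package
version) so that deterministic stages are reproducible byte-for-byte
from config + seed.  Stages: simulate, demux, align, genotype, bin,
map, compare-refs, anchor, hetscan, all.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, anchor, cpmap, genocall, hetscan, markerbin, readio, refeval, simcross, tagmap

log = logging.getLogger("radmap")

#: Threshold names mirror the stage modules; simulate block defines the
#: synthetic study conditions (51 progeny; maternal 0.03% / paternal
#: 0.37% heterozygosity; NsiI+MseI 200-500 bp; 100 bp reads; parents at
#: twice progeny depth).  The desk-scale genome keeps an end-to-end run
#: in minutes.
DEFAULT_CONFIG: dict = {
    "workdir": "radmap_run",
    "seed": 1,
    "mode": "masked",
    # optional TSV of external (e.g. SSR-style) CP genotypes to merge
    # before mapping: marker id column then one CP call per progeny
    "external_markers": None,
    "simulate": {
        "n_scaffolds": 5,
        "scaffold_length": 300_000,
        "repeat_families": [[400, 450, 0.02], [250, 900, 0.05], [600, 250, 0.01]],
        "gene_density": 0.05,
        "het_rate_maternal": 0.0003,
        "het_rate_paternal": 0.0037,
        "repeat_insertions_per_mb": 8.0,
        "truth_cm_per_mb": 30.0,
        "n_progeny": 51,
        "mean_depth": 8.0,
        "depth_dispersion": 0.3,
        "error_rate": 0.001,
        "read_len": 100,
        "parent_depth_multiplier": 2.0,
        "min_len": 200,
        "max_len": 500,
    },
    "readio": {"tag_length": 92, "min_q": 20, "max_low_q": 4},
    "tagmap": {"max_mismatch": 2, "max_indel": 2,
               "cluster_min_depth": 4, "cluster_max_depth": 200},
    "genocall": {"min_progeny_depth": 3, "min_called_fraction": 0.90,
                 "max_missing": 0.10},
    "cpmap": {"lod_min": 5.0, "rf_max": 0.25, "ripple_window": 3},
    "anchor": {"gap_len": 100, "top_n_scaffolds": 10},
    "hetscan": {"min_depth": 10, "max_depth": 120, "min_minor_frac": 0.2,
                "window": 500_000, "step": 250_000},
}

STAGES = ["simulate", "demux", "align", "genotype", "bin", "map",
          "compare-refs", "anchor", "hetscan", "all"]

# stage that produces each upstream artifact, for actionable errors
_PRODUCERS = {
    "genome.fasta": "simulate",
    "repeats.bed": "simulate",
    "genes.bed": "simulate",
    "reads.fastq": "simulate",
    "barcodes.tsv": "simulate",
    "site_summaries.tsv": "simulate",
    "demux": "demux",
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(workdir: Path, name: str) -> Path:
    p = workdir / name
    if not p.exists():
        producer = _PRODUCERS.get(name, "an earlier stage")
        raise FileNotFoundError(
            f"missing input {p}; run the '{producer}' stage first"
        )
    return p


def _manifest(workdir: Path, stage: str, cfg: dict, inputs: list[Path],
              outputs: list[Path], t0: float) -> None:
    data = {
        "stage": stage,
        "version": __version__,
        "config_hash": config_hash(cfg),
        "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
        "outputs": {p.name: _hash_file(p) for p in outputs if p.exists()},
        "seconds": round(time.time() - t0, 2),
    }
    with open(workdir / f"manifest.{stage.replace('-', '_')}.json", "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)


def _load_genome(workdir: Path) -> simcross.AnnotatedGenome:
    from Bio import SeqIO

    scaffolds = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(_require(workdir, "genome.fasta")), "fasta")
    ]
    repeats = simcross.read_bed(_require(workdir, "repeats.bed"))
    genes = simcross.read_bed(_require(workdir, "genes.bed"))
    return simcross.AnnotatedGenome(
        scaffolds=scaffolds, repeat_intervals=repeats, gene_intervals=genes
    )


def _sample_ids(cfg) -> tuple[list[str], list[str]]:
    n = cfg["simulate"]["n_progeny"]
    progeny = [f"p{i + 1:02d}" for i in range(n)]
    return ["mother", "father"] + progeny, progeny


# -- stages -----------------------------------------------------------------


def stage_simulate(cfg: dict) -> dict:
    workdir = Path(cfg["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    genome = simcross.simulate_genome(
        n_scaffolds=sim["n_scaffolds"],
        scaffold_lengths=sim["scaffold_length"],
        repeat_family_specs=[tuple(f) for f in sim["repeat_families"]],
        gene_density=sim["gene_density"],
        seed=seed,
    )
    parents = simcross.simulate_parents(
        genome,
        het_rate_maternal=sim["het_rate_maternal"],
        het_rate_paternal=sim["het_rate_paternal"],
        repeat_insertions_per_mb=sim["repeat_insertions_per_mb"],
        seed=seed + 1,
    )
    progeny = simcross.simulate_f1(
        parents, truth_cm_per_mb=sim["truth_cm_per_mb"],
        n_progeny=sim["n_progeny"], seed=seed + 2,
    )
    samples, _ = _sample_ids(cfg)
    barcodes = simcross.make_barcodes(samples, seed=seed + 3)
    reads = simcross.simulate_cross_reads(
        progeny, barcodes,
        mean_depth=sim["mean_depth"], depth_dispersion=sim["depth_dispersion"],
        error_rate=sim["error_rate"], read_len=sim["read_len"],
        parent_depth_multiplier=sim["parent_depth_multiplier"],
        min_len=sim["min_len"], max_len=sim["max_len"], seed=seed + 4,
    )
    # the heterozygosity scan targets the assembly individual's own
    # genome, i.e. the near-homozygous maternal parent
    site_summaries = simcross.simulate_site_summaries(
        parents, parent="maternal", seed=seed + 5
    )
    simcross.write_fasta(genome, workdir / "genome.fasta")
    simcross.write_bed(genome.repeat_intervals, workdir / "repeats.bed")
    simcross.write_bed(genome.gene_intervals, workdir / "genes.bed")
    simcross.write_fastq(reads, workdir / "reads.fastq")
    simcross.write_barcode_table(barcodes, workdir / "barcodes.tsv")
    simcross.write_truth_table(progeny, workdir / "truth_markers.tsv")
    site_summaries.to_csv(workdir / "site_summaries.tsv", sep="\t", index=False)
    outputs = [workdir / n for n in (
        "genome.fasta", "repeats.bed", "genes.bed", "reads.fastq",
        "barcodes.tsv", "truth_markers.tsv", "site_summaries.tsv")]
    _manifest(workdir, "simulate", cfg, [], outputs, t0)
    log.info("simulate: %d reads, %d paternal het sites",
             len(reads), parents.n_het_sites("paternal"))
    return {"n_reads": len(reads)}


def stage_demux(cfg: dict) -> dict:
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    barcodes = readio.read_barcode_table(_require(workdir, "barcodes.tsv"))
    reads = readio.read_fastq(_require(workdir, "reads.fastq"))
    rc = cfg["readio"]
    result = readio.demultiplex(
        reads, barcodes, tag_length=rc["tag_length"],
        min_q=rc["min_q"], max_low_q=rc["max_low_q"],
    )
    outdir = workdir / "demux"
    readio.write_sample_fastq(result, outdir)
    counts = result.counts_frame()
    counts.to_csv(workdir / "demux_counts.tsv", sep="\t", index=False)
    _manifest(workdir, "demux", cfg,
              [workdir / "reads.fastq", workdir / "barcodes.tsv"],
              [workdir / "demux_counts.tsv"], t0)
    log.info("demux: %d reads, %d ambiguous", result.n_total, result.n_ambiguous)
    return {"n_ambiguous": result.n_ambiguous}


def _demux_from_files(cfg: dict) -> readio.DemuxResult:
    workdir = Path(cfg["workdir"])
    outdir = workdir / "demux"
    if not outdir.exists():
        raise FileNotFoundError(
            f"missing input {outdir}; run the 'demux' stage first"
        )
    barcodes = readio.read_barcode_table(_require(workdir, "barcodes.tsv"))
    result = readio.DemuxResult(samples={})
    for sid in barcodes:
        srs = readio.SampleReadSet(sample_id=sid)
        fq = outdir / f"{sid}.tags.fastq"
        if fq.exists():
            srs.tags = list(readio.read_fastq(fq))
        result.samples[sid] = srs
    return result


def _align_mode(cfg: dict, mode: str, demux=None, genome=None):
    workdir = Path(cfg["workdir"])
    if genome is None:
        genome = _load_genome(workdir)
    if demux is None:
        demux = _demux_from_files(cfg)
    tc = cfg["tagmap"]
    index = tagmap.build_reference_index(genome, mode)
    alignments = tagmap.align_sample_tags(
        demux, index, max_mismatch=tc["max_mismatch"], max_indel=tc["max_indel"]
    )
    return genome, alignments


def stage_align(cfg: dict, mode: str | None = None) -> dict:
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    mode = mode or cfg["mode"]
    _, alignments = _align_mode(cfg, mode)
    out = workdir / f"alignments.{mode}.tsv"
    tagmap.write_alignment_dump(alignments, out)
    _manifest(workdir, f"align-{mode}", cfg, [workdir / "genome.fasta"], [out], t0)
    n_unique = sum(a.count for a in alignments if a.status == "unique")
    log.info("align[%s]: %d unique read placements", mode, n_unique)
    return {"mode": mode, "n_unique": n_unique}


def stage_genotype(cfg: dict, mode: str | None = None,
                   alignments: list | None = None) -> genocall.GenotypeMatrix:
    """Genotype stage; recomputes alignments in memory when not given
    (the TSV dump is a report, not a serialization)."""
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    mode = mode or cfg["mode"]
    if alignments is None:
        if not (workdir / f"alignments.{mode}.tsv").exists():
            raise FileNotFoundError(
                f"missing input {workdir / f'alignments.{mode}.tsv'}; "
                "run the 'align' stage (tagmap) first"
            )
        _, alignments = _align_mode(cfg, mode)
    tc = cfg["tagmap"]
    gc = cfg["genocall"]
    clusters, cstats = tagmap.build_clusters(
        alignments, min_depth=tc["cluster_min_depth"],
        max_depth=tc["cluster_max_depth"],
    )
    _, progeny_ids = _sample_ids(cfg)
    matrix = genocall.score_markers(
        clusters, progeny_ids, reference_mode=mode,
        min_depth=gc["min_progeny_depth"],
        min_called_fraction=gc["min_called_fraction"],
        max_missing=gc["max_missing"],
    )
    genocall.write_matrix(matrix, workdir / f"matrix.{mode}.tsv")
    if matrix.filter_log is not None:
        matrix.filter_log.to_csv(
            workdir / f"filter_log.{mode}.tsv", sep="\t", index=False
        )
    _manifest(workdir, f"genotype-{mode}", cfg, [],
              [workdir / f"matrix.{mode}.tsv"], t0)
    log.info("genotype[%s]: %d clusters -> %d markers",
             mode, cstats["n_kept"], matrix.n_markers)
    return matrix


def stage_bin(cfg: dict, mode: str | None = None,
              matrix: genocall.GenotypeMatrix | None = None):
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    mode = mode or cfg["mode"]
    if matrix is None:
        matrix = _read_matrix(workdir, mode)
    bins, binned = markerbin.collapse_bins(matrix)
    markerbin.write_bin_table(bins, workdir / f"bins.{mode}.tsv")
    genocall.write_matrix(binned, workdir / f"matrix.binned.{mode}.tsv")
    _manifest(workdir, f"bin-{mode}", cfg, [],
              [workdir / f"bins.{mode}.tsv"], t0)
    log.info("bin[%s]: %d markers -> %d bins", mode, matrix.n_markers, len(bins))
    return bins, binned


def _read_matrix(workdir: Path, mode: str, binned: bool = False) -> genocall.GenotypeMatrix:
    name = f"matrix.binned.{mode}.tsv" if binned else f"matrix.{mode}.tsv"
    path = workdir / name
    if not path.exists():
        stage = "bin (markerbin)" if binned else "genotype (genocall)"
        raise FileNotFoundError(f"missing input {path}; run the '{stage}' stage first")
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in ("scaffold", "pos", "seg_type", "source",
                             "n_members", "representative") if c in df.columns]
    info = df[meta_cols].copy()
    if "pos" in info.columns:
        info["pos"] = info["pos"].astype(int) - 1
    calls = df.drop(columns=meta_cols)
    return genocall.GenotypeMatrix(calls=calls, info=info)


def stage_map(cfg: dict, mode: str | None = None, binned=None):
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    mode = mode or cfg["mode"]
    if binned is None:
        binned = _read_matrix(workdir, mode, binned=True)
    if cfg.get("external_markers"):
        ext = pd.read_csv(cfg["external_markers"], sep="\t", index_col=0)
        binned = cpmap.merge_external_markers(binned, ext)
    cp = cfg["cpmap"]
    maps = {}
    for parent in ("paternal", "maternal"):
        gm, table = cpmap.build_map(
            binned, parent=parent, lod_min=cp["lod_min"], rf_max=cp["rf_max"],
            ripple_window=cp["ripple_window"],
        )
        cpmap.write_map(gm, binned.info, workdir / f"map.{parent}.{mode}.tsv")
        maps[parent] = (gm, table)
        log.info("map[%s,%s]: %d groups, %.1f cM, %d bins placed",
                 mode, parent, len(gm.groups), gm.total_length_cm, gm.n_markers)
    _manifest(workdir, f"map-{mode}", cfg, [],
              [workdir / f"map.paternal.{mode}.tsv"], t0)
    return maps


def run_mode_pipeline(cfg: dict, mode: str, demux=None, genome=None):
    """align -> genotype -> bin -> map for one reference dialect,
    passing artifacts in memory; files are still written per stage."""
    _, alignments = _align_mode(cfg, mode, demux=demux, genome=genome)
    tagmap.write_alignment_dump(
        alignments, Path(cfg["workdir"]) / f"alignments.{mode}.tsv"
    )
    matrix = stage_genotype(cfg, mode, alignments=alignments)
    bins, binned = stage_bin(cfg, mode, matrix=matrix)
    maps = stage_map(cfg, mode, binned=binned)
    return {"alignments": alignments, "matrix": matrix, "bins": bins,
            "binned": binned, "maps": maps}


def stage_compare_refs(cfg: dict) -> pd.DataFrame:
    """Run the marker-scoring comparison across the three dialects and
    write concordance and summary reports."""
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    genome = _load_genome(workdir)
    lengths = genome.scaffold_lengths()
    demux = _demux_from_files(cfg)
    summaries = []
    for mode in ("unmasked", "masked", "genemodels"):
        res = run_mode_pipeline(cfg, mode, demux=demux, genome=genome)
        gm, _ = res["maps"]["paternal"]
        frame = gm.to_frame()
        conc = refeval.build_concordance(
            frame, res["binned"].info, lengths,
            top_n_scaffolds=cfg["anchor"]["top_n_scaffolds"],
        )
        conc.counts.to_csv(workdir / f"concordance.{mode}.tsv", sep="\t")
        refeval.heatmap_fractions(conc).to_csv(
            workdir / f"concordance_fractions.{mode}.tsv", sep="\t",
            float_format="%.4f",
        )
        n_scored = res["matrix"].n_markers
        n_mapped = int(
            res["binned"].info.loc[frame.marker, "n_members"].sum()
        ) if len(frame) else 0
        summaries.append(refeval.strategy_summary(mode, n_scored, n_mapped, conc))
    df = pd.DataFrame(summaries)
    df.to_csv(workdir / "reference_comparison.tsv", sep="\t", index=False)
    with open(workdir / "reference_comparison.json", "w") as fh:
        json.dump(summaries, fh, indent=1)
    _manifest(workdir, "compare-refs", cfg, [workdir / "genome.fasta"],
              [workdir / "reference_comparison.tsv"], t0)
    return df


def stage_anchor(cfg: dict, mode: str | None = None, maps=None, binned=None) -> pd.DataFrame:
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    mode = mode or cfg["mode"]
    genome = _load_genome(workdir)
    lengths = genome.scaffold_lengths()
    if binned is None:
        binned = _read_matrix(workdir, mode, binned=True)
    if maps is None:
        maps = stage_map(cfg, mode, binned=binned)
    gm, _ = maps["paternal"]
    frame = gm.to_frame()
    anchors, unanchored = anchor.assign_scaffolds(
        frame, binned.info, all_scaffolds=list(lengths)
    )
    megas = anchor.order_orient(
        anchors, frame, binned.info, lengths, gap_len=cfg["anchor"]["gap_len"]
    )
    stats = anchor.map_stats(megas, frame, lengths)
    anchor.write_agp(megas, workdir / f"megascaffolds.{mode}.agp")
    anchor.write_anchor_table(megas, workdir / f"anchors.{mode}.tsv")
    stats.to_csv(workdir / f"map_stats.{mode}.tsv", sep="\t", index=False)
    _manifest(workdir, f"anchor-{mode}", cfg, [],
              [workdir / f"megascaffolds.{mode}.agp"], t0)
    log.info("anchor[%s]: %d scaffolds into %d megascaffolds",
             mode, len(anchors), len(megas.megascaffolds))
    return stats


def stage_hetscan(cfg: dict) -> pd.DataFrame:
    workdir = Path(cfg["workdir"])
    t0 = time.time()
    sites = hetscan.read_site_summaries(_require(workdir, "site_summaries.tsv"))
    genome = _load_genome(workdir)
    lengths = genome.scaffold_lengths()
    hs = cfg["hetscan"]
    het = hetscan.call_het_sites(
        sites, min_depth=hs["min_depth"], max_depth=hs["max_depth"],
        min_minor_frac=hs["min_minor_frac"],
    )
    windows = hetscan.window_scan(het, lengths, window=hs["window"], step=hs["step"])
    summary = hetscan.genome_summary(het, lengths)
    hetscan.write_window_bed(windows, workdir / "het_windows.tsv")
    summary.to_csv(workdir / "het_summary.tsv", sep="\t", index=False,
                   float_format="%.4f")
    _manifest(workdir, "hetscan", cfg, [workdir / "site_summaries.tsv"],
              [workdir / "het_summary.tsv"], t0)
    return summary


def run_stage(stage: str, cfg: dict):
    """Dispatch a pipeline stage by name."""
    if stage == "simulate":
        return stage_simulate(cfg)
    if stage == "demux":
        return stage_demux(cfg)
    if stage == "align":
        return stage_align(cfg)
    if stage == "genotype":
        return stage_genotype(cfg)
    if stage == "bin":
        return stage_bin(cfg)
    if stage == "map":
        return stage_map(cfg)
    if stage == "compare-refs":
        return stage_compare_refs(cfg)
    if stage == "anchor":
        return stage_anchor(cfg)
    if stage == "hetscan":
        return stage_hetscan(cfg)
    if stage == "all":
        stage_simulate(cfg)
        stage_demux(cfg)
        res = run_mode_pipeline(cfg, cfg["mode"])
        stage_anchor(cfg, cfg["mode"], maps=res["maps"], binned=res["binned"])
        stage_hetscan(cfg)
        return None
    raise ValueError(f"unknown stage: {stage}; choose from {STAGES}")
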