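"""Reusable simulation experiments.

These functions drive the recovery and comparison studies that the
analysis scripts, the test suite, and the acceptance script all share:

* :func:`map_recovery` — marker-level truth recovery of linkage-group
  partition, within-group order, and map length;
* :func:`anchoring_recovery` — scaffold-to-LG assignment and
  orientation recovery;
* :func:`reference_comparison` — the read-level three-reference
  marker-scoring comparison (scored counts and concordance purity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import anchor, cpmap, markerbin, pipeline, refeval
from .genocall import GenotypeMatrix
from .simcross import simulate_testcross_dataset


def _matrix_from_dataset(ds) -> GenotypeMatrix:
    info = ds["info"].rename(columns={"pos": "pos"}).copy()
    info["source"] = "radseq"
    return GenotypeMatrix(calls=ds["calls"], info=info[["scaffold", "pos", "seg_type", "source"]])


def _bin_truth_positions(bins, info) -> pd.Series:
    return pd.Series(
        {b.bin_id: float(info.loc[b.members, "cm_true"].mean()) for b in bins}
    )


def evaluate_map(ds, genetic_map: cpmap.GeneticMap, bins) -> dict:
    """Score one estimated map against dataset truth.

    partition_ok: the estimated grouping reproduces the truth linkage
    groups exactly (every truth LG recovered as one pure estimated
    group, no marker misplaced or left unlinked).
    mean_tau: mean |Kendall tau| between estimated bin order and truth
    positions per LG.  length_rel_err: |estimated - truth| / truth over
    the summed map length.
    """
    info = ds["info"]
    member_of = {}
    for b in bins:
        for m in b.members:
            member_of[b.bin_id] = b.members
    truth_lgs = info.lg_true.nunique()
    est_groups = []
    for g in genetic_map.groups:
        members = [m for b in g.markers for m in member_of.get(b, [])]
        est_groups.append(set(members))
    all_markers = set(info.index)
    covered = set().union(*est_groups) if est_groups else set()
    pure = all(len(info.loc[sorted(g), "lg_true"].unique()) == 1 for g in est_groups)
    partition_ok = (
        len(est_groups) == truth_lgs and pure and covered == all_markers
    )
    taus = []
    for g in genetic_map.groups:
        truth_pos = _bin_truth_positions(bins, info).reindex(g.markers)
        if truth_pos.nunique() < 2:
            continue
        tau = kendalltau(np.arange(len(g.markers)), truth_pos.to_numpy()).statistic
        taus.append(abs(tau))
    truth_length = 0.0
    for lg, sub in info.groupby("lg_true"):
        truth_length += sub.cm_true.max() - sub.cm_true.min()
    est_length = genetic_map.total_length_cm
    return {
        "partition_ok": bool(partition_ok),
        "n_groups": len(genetic_map.groups),
        "mean_tau": float(np.mean(taus)) if taus else np.nan,
        "length_rel_err": abs(est_length - truth_length) / truth_length,
        "est_length_cm": est_length,
        "truth_length_cm": truth_length,
    }


def run_map_dataset(seed: int, n_lgs=5, markers_per_lg=40, spacing_cm=2.5,
                    n_progeny=51, missing_rate=0.02, scaffolds_per_lg=4):
    """Simulate one marker-level dataset, bin, group, order and map it."""
    ds = simulate_testcross_dataset(
        n_lgs=n_lgs, markers_per_lg=markers_per_lg, spacing_cm=spacing_cm,
        n_progeny=n_progeny, seed=seed, missing_rate=missing_rate,
        scaffolds_per_lg=scaffolds_per_lg,
    )
    matrix = _matrix_from_dataset(ds)
    bins, binned = markerbin.collapse_bins(matrix)
    gm, table = cpmap.build_map(binned, parent="paternal")
    return ds, matrix, bins, binned, gm, table


def map_recovery(n_datasets: int = 20, seed0: int = 1000, **kwargs) -> pd.DataFrame:
    """Truth-recovery study over independent simulated datasets."""
    rows = []
    for i in range(n_datasets):
        ds, _, bins, _, gm, _ = run_map_dataset(seed0 + i, **kwargs)
        res = evaluate_map(ds, gm, bins)
        res["seed"] = seed0 + i
        rows.append(res)
    return pd.DataFrame(rows)


def anchoring_recovery(n_datasets: int = 10, seed0: int = 2000, **kwargs) -> pd.DataFrame:
    """Scaffold assignment and orientation recovery on marker-level
    simulations with known scaffold truth."""
    rows = []
    for i in range(n_datasets):
        ds, _, bins, binned, gm, _ = run_map_dataset(seed0 + i, **kwargs)
        frame = gm.to_frame()
        info = binned.info
        scaffold_truth = ds["scaffold_truth"]
        lengths = (
            ds["info"].groupby("scaffold").pos.max().astype(int) + 10_000
        ).to_dict()
        anchors, unanchored = anchor.assign_scaffolds(frame, info, list(lengths))
        megas = anchor.order_orient(anchors, frame, info, lengths)
        # map estimated LG labels onto truth LGs by member majority
        member_truth = ds["info"].lg_true
        bin_members = {b.bin_id: b.members for b in bins}
        bin_truth_cm = _bin_truth_positions(bins, ds["info"])
        lg_to_truth = {}
        lg_reversed = {}
        for g in gm.groups:
            members = [m for b in g.markers for m in bin_members.get(b, [])]
            lg_to_truth[g.lg_id] = int(member_truth.loc[members].mode().iloc[0])
            # a linkage group's direction is arbitrary; orientation truth
            # is defined relative to the estimated direction
            tau = kendalltau(
                np.arange(len(g.markers)),
                bin_truth_cm.reindex(g.markers).to_numpy(),
            ).statistic
            lg_reversed[g.lg_id] = bool(tau is not None and tau < 0)
        n_ok = 0
        n_assigned = 0
        n_orient_ok = 0
        n_orient_eligible = 0
        for a in megas.anchors:
            truth_lg = int(scaffold_truth.loc[a.scaffold_id, "lg_true"])
            n_assigned += 1
            if lg_to_truth.get(a.lg) == truth_lg:
                n_ok += 1
            sub = frame[frame.marker.isin(
                info.index[info.scaffold == a.scaffold_id]
            )]
            distinct_cm = sub[sub.lg == a.lg].cm.nunique()
            if distinct_cm >= 3 and a.orientation in "+-":
                n_orient_eligible += 1
                expected = scaffold_truth.loc[a.scaffold_id, "orientation_true"]
                if lg_reversed.get(a.lg, False):
                    expected = "-" if expected == "+" else "+"
                if a.orientation == expected:
                    n_orient_ok += 1
        rows.append({
            "seed": seed0 + i,
            "n_scaffolds": len(scaffold_truth),
            "n_assigned": n_assigned,
            "assign_accuracy": n_ok / n_assigned if n_assigned else np.nan,
            "n_orient_eligible": n_orient_eligible,
            "orient_accuracy": (
                n_orient_ok / n_orient_eligible if n_orient_eligible else np.nan
            ),
        })
    return pd.DataFrame(rows)


def simulate_cross_in_memory(cfg: dict):
    """Simulate and demultiplex one cross without touching disk.

    Mirrors the simulate + demux pipeline stages (same seeds, same
    artifacts) but keeps everything in memory for the comparison and
    recovery studies.
    """
    from . import readio, simcross, tagmap  # local import keeps cycles away

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
    samples = ["mother", "father"] + [
        f"p{i + 1:02d}" for i in range(sim["n_progeny"])
    ]
    barcodes = simcross.make_barcodes(samples, seed=seed + 3)
    reads = simcross.simulate_cross_reads(
        progeny, barcodes,
        mean_depth=sim["mean_depth"], depth_dispersion=sim["depth_dispersion"],
        error_rate=sim["error_rate"], read_len=sim["read_len"],
        parent_depth_multiplier=sim["parent_depth_multiplier"],
        min_len=sim["min_len"], max_len=sim["max_len"], seed=seed + 4,
    )
    rc = cfg["readio"]
    demux = readio.demultiplex(
        reads, barcodes, tag_length=rc["tag_length"],
        min_q=rc["min_q"], max_low_q=rc["max_low_q"],
    )
    return genome, parents, progeny, demux


def _score_mode(cfg, genome, demux, mode):
    from . import genocall, tagmap  # local import keeps cycles away

    tc = cfg["tagmap"]
    gc = cfg["genocall"]
    index = tagmap.build_reference_index(genome, mode)
    alignments = tagmap.align_sample_tags(
        demux, index, max_mismatch=tc["max_mismatch"], max_indel=tc["max_indel"]
    )
    clusters, _ = tagmap.build_clusters(
        alignments, min_depth=tc["cluster_min_depth"],
        max_depth=tc["cluster_max_depth"],
    )
    progeny_ids = [f"p{i + 1:02d}" for i in range(cfg["simulate"]["n_progeny"])]
    matrix = genocall.score_markers(
        clusters, progeny_ids, reference_mode=mode,
        min_depth=gc["min_progeny_depth"],
        min_called_fraction=gc["min_called_fraction"],
        max_missing=gc["max_missing"],
    )
    bins, binned = markerbin.collapse_bins(matrix)
    cp = cfg["cpmap"]
    gm, table = cpmap.build_map(
        binned, parent="paternal", lod_min=cp["lod_min"], rf_max=cp["rf_max"],
        ripple_window=cp["ripple_window"],
    )
    return matrix, bins, binned, gm


def reference_comparison(seeds, overrides: dict | None = None) -> pd.DataFrame:
    """Read-level three-reference comparison over simulation seeds.

    Runs the full simulate -> demux -> align -> genotype -> bin -> map
    chain in memory for each seed and reference dialect; returns one
    row per (seed, mode) with scored/mapped marker counts and mean
    concordance purity.
    """
    rows = []
    for seed in seeds:
        cfg = pipeline.load_config(overrides={**(overrides or {}), "seed": int(seed)})
        genome, _, _, demux = simulate_cross_in_memory(cfg)
        for mode in ("unmasked", "masked", "genemodels"):
            matrix, bins, binned, gm = _score_mode(cfg, genome, demux, mode)
            frame = gm.to_frame()
            conc = refeval.build_concordance(
                frame, binned.info, genome.scaffold_lengths(),
                cfg["anchor"]["top_n_scaffolds"],
            )
            purity = conc.row_purity().dropna()
            n_mapped = (
                int(binned.info.loc[frame.marker, "n_members"].sum())
                if len(frame) else 0
            )
            rows.append({
                "seed": seed,
                "mode": mode,
                "scored": matrix.n_markers,
                "mapped": n_mapped,
                "mean_purity": float(purity.mean()) if len(purity) else np.nan,
                "min_purity": float(purity.min()) if len(purity) else np.nan,
                "map_length_cm": gm.total_length_cm,
                "n_groups": len(gm.groups),
            })
    return pd.DataFrame(rows)
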