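"""Genetic-map-guided scaffold anchoring into megascaffolds.

Each scaffold is assigned to the modal linkage group of its mapped
bins, ordered along the group by the mean cM of those bins, and
oriented by the sign of the rank correlation between marker physical
positions and cM positions.  The result is emitted as AGP v2.1 with a
fixed inter-scaffold gap, plus per-group statistics (cM length, marker
counts, markers/cM, physical Mb, Mb/cM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

DEFAULT_GAP_LEN = 100


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    lg: str
    n_markers: int
    mean_cm: float
    orientation: str = "+"          # + | - | ? (unoriented, placed as +)
    n_conflicting: int = 0


@dataclass
class Megascaffold:
    lg: str
    components: list[tuple[str, int, int, str]]  # (scaffold, start, end, orientation)
    gap_len: int

    @property
    def length(self) -> int:
        return self.components[-1][2] if self.components else 0


@dataclass
class MegascaffoldSet:
    megascaffolds: list[Megascaffold]
    anchors: list[ScaffoldAnchor]
    unanchored: list[str] = field(default_factory=list)
    gap_len: int = DEFAULT_GAP_LEN


def assign_scaffolds(
    map_frame: pd.DataFrame,
    marker_info: pd.DataFrame,
    all_scaffolds: list[str] | None = None,
) -> tuple[list[ScaffoldAnchor], list[str]]:
    """Assign each scaffold to the modal LG of its mapped bins.

    ``marker_info`` must give scaffold and physical pos per mapped
    marker id.  Minority (conflicting) markers are counted but never
    split a scaffold.  Mean cM is computed over modal-LG markers only.
    Returns (anchors, unanchored scaffold ids).
    """
    merged = map_frame.merge(
        marker_info[["scaffold", "pos"]], left_on="marker", right_index=True,
        how="left",
    )
    merged = merged[merged.scaffold.notna() & (merged.scaffold != "")]
    anchors = []
    seen = set()
    for sc, sub in merged.groupby("scaffold"):
        lg_counts = sub.lg.value_counts()
        modal = lg_counts.sort_index().sort_values(
            ascending=False, kind="stable"
        ).index[0]
        in_modal = sub[sub.lg == modal]
        anchors.append(
            ScaffoldAnchor(
                scaffold_id=sc,
                lg=modal,
                n_markers=int(len(sub)),
                mean_cm=float(in_modal.cm.mean()),
                n_conflicting=int(len(sub) - len(in_modal)),
            )
        )
        seen.add(sc)
    unanchored = [s for s in (all_scaffolds or []) if s not in seen]
    anchors.sort(key=lambda a: a.scaffold_id)
    return anchors, unanchored


def _orient(sub: pd.DataFrame) -> str:
    """Orientation from rank correlation of physical pos vs cM; requires
    >= 2 distinct cM values and a nonzero correlation."""
    if sub.cm.nunique() < 2 or sub.pos.nunique() < 2:
        return "?"
    rho = spearmanr(sub.pos, sub.cm).statistic
    if np.isnan(rho) or rho == 0:
        return "?"
    return "+" if rho > 0 else "-"


def order_orient(
    anchors: list[ScaffoldAnchor],
    map_frame: pd.DataFrame,
    marker_info: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    gap_len: int = DEFAULT_GAP_LEN,
) -> MegascaffoldSet:
    """Order scaffolds within each LG by mean cM (ties by descending
    length) and orient them; build AGP coordinates with ``gap_len`` N
    between components."""
    merged = map_frame.merge(
        marker_info[["scaffold", "pos"]], left_on="marker", right_index=True,
        how="left",
    )
    megas = []
    for lg in sorted({a.lg for a in anchors}):
        in_lg = sorted(
            (a for a in anchors if a.lg == lg),
            key=lambda a: (a.mean_cm, -scaffold_lengths.get(a.scaffold_id, 0),
                           a.scaffold_id),
        )
        comps = []
        cur = 0
        for a in in_lg:
            sub = merged[(merged.scaffold == a.scaffold_id) & (merged.lg == lg)]
            a.orientation = _orient(sub)
            length = scaffold_lengths.get(a.scaffold_id, 0)
            if comps:
                cur += gap_len
            comps.append((a.scaffold_id, cur, cur + length,
                          a.orientation if a.orientation != "?" else "+"))
            cur += length
        megas.append(Megascaffold(lg=lg, components=comps, gap_len=gap_len))
    anchored_ids = {a.scaffold_id for a in anchors}
    unanchored = [s for s in scaffold_lengths if s not in anchored_ids]
    return MegascaffoldSet(megascaffolds=megas, anchors=anchors,
                           unanchored=unanchored, gap_len=gap_len)


def map_stats(
    megas: MegascaffoldSet,
    map_frame: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    external_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-LG and total mapping statistics.

    Columns: lg, distance_cm, markers, markers_per_cm (1 decimal),
    mean_interval_cm (distance / (markers - 1), 2 decimals),
    physical_mb, mb_per_cm (2 decimals), n_scaffolds.  The totals row
    sums components and recomputes the ratios from the sums.
    """
    rows = []
    for mega in megas.megascaffolds:
        lg = mega.lg
        sub = map_frame[map_frame.lg == lg]
        dist = float(sub.cm.max() - sub.cm.min()) if len(sub) else 0.0
        n_markers = int(len(sub))
        phys = sum(
            scaffold_lengths.get(c[0], 0) for c in mega.components
        ) / 1e6
        rows.append((lg, dist, n_markers, phys, len(mega.components)))
    df = pd.DataFrame(
        rows, columns=["lg", "distance_cm", "markers", "physical_mb", "n_scaffolds"]
    )
    total = pd.DataFrame(
        [(
            "Total",
            df.distance_cm.sum(),
            df.markers.sum(),
            df.physical_mb.sum(),
            df.n_scaffolds.sum(),
        )],
        columns=df.columns,
    )
    out = pd.concat([df, total], ignore_index=True)
    for c in ("distance_cm", "markers", "physical_mb"):
        out[c] = pd.to_numeric(out[c], errors="coerce").fillna(0.0)
    # zero-length groups get undefined (NaN) ratio statistics
    denom = out["distance_cm"].replace(0.0, np.nan)
    out["markers_per_cm"] = (out.markers / denom).round(1)
    out["mean_interval_cm"] = (denom / (out.markers - 1).clip(lower=1)).round(2)
    out["mb_per_cm"] = (out.physical_mb / denom).round(2)
    return out


def write_agp(megas: MegascaffoldSet, path: str | Path) -> None:
    """AGP v2.1: one object per megascaffold, map-supported scaffold
    components separated by fixed N gaps."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for mega in megas.megascaffolds:
            obj = f"megascaffold_{mega.lg}"
            part = 0
            prev_end = None
            for sc, start, end, orient in mega.components:
                if prev_end is not None:
                    part += 1
                    fh.write(
                        f"{obj}\t{prev_end + 1}\t{start}\t{part}\tN\t"
                        f"{mega.gap_len}\tscaffold\tyes\tmap\n"
                    )
                part += 1
                fh.write(
                    f"{obj}\t{start + 1}\t{end}\t{part}\tW\t{sc}\t1\t"
                    f"{end - start}\t{orient}\n"
                )
                prev_end = end


def read_agp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append(f)
    cols = ["object", "obj_start", "obj_end", "part", "type",
            "c6", "c7", "c8", "c9"]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("obj_start", "obj_end", "part"):
        df[c] = df[c].astype(int)
    return df


def write_anchor_table(megas: MegascaffoldSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tlg\tn_markers\tmean_cm\torientation\tn_conflicting\n")
        for a in megas.anchors:
            fh.write(
                f"{a.scaffold_id}\t{a.lg}\t{a.n_markers}\t{a.mean_cm:.3f}\t"
                f"{a.orientation}\t{a.n_conflicting}\n"
            )
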