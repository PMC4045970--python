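"""Within-genome heterozygosity from per-site pileup summaries.

Sites are called heterozygous when read depth lies in [10, 120] and the
minor allele reaches a configurable fraction (default 0.2); densities
are reported per 500 kb sliding window with 250 kb step and per
scaffold, with the genome value as the unweighted mean over scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MIN_DEPTH = 10
MAX_DEPTH = 120
MIN_MINOR_FRAC = 0.2
WINDOW = 500_000
STEP = 250_000


@dataclass
class WindowDensity:
    scaffold: str
    start: int
    end: int
    n_variants: int

    @property
    def per_kb(self) -> float:
        return self.n_variants / ((self.end - self.start) / 1000.0)


def call_het_sites(
    site_summaries: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    max_depth: int = MAX_DEPTH,
    min_minor_frac: float = MIN_MINOR_FRAC,
) -> pd.DataFrame:
    """Filter a site-summary table down to heterozygous calls.

    Expects columns scaffold, pos, depth, countA, countB (biallelic
    summaries).  A site is heterozygous iff min_depth <= depth <=
    max_depth and minor count / depth >= min_minor_frac.
    """
    df = site_summaries
    depth = df["depth"].to_numpy()
    minor = np.minimum(df["countA"].to_numpy(), df["countB"].to_numpy())
    keep = (depth >= min_depth) & (depth <= max_depth) & (
        minor >= min_minor_frac * depth
    )
    return df.loc[keep].reset_index(drop=True)


def window_scan(
    het_sites: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    window: int = WINDOW,
    step: int = STEP,
) -> list[WindowDensity]:
    """Sliding-window variant densities.

    Windows start at 0 with the given step; the final window is
    truncated at the scaffold end (its true length is the denominator).
    A scaffold shorter than the step yields a single full-scaffold
    window.
    """
    out = []
    for sc in sorted(scaffold_lengths):
        length = scaffold_lengths[sc]
        pos = np.sort(
            het_sites.loc[het_sites.scaffold == sc, "pos"].to_numpy()
        )
        if length <= step:
            starts = [0]
        else:
            starts = list(range(0, length - step + 1, step))
            # ensure terminal coverage when length is not a step multiple
            if starts[-1] + window < length:
                starts.append(starts[-1] + step)
        for s in starts:
            e = min(s + window, length)
            n = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
            out.append(WindowDensity(sc, s, e, n))
    return out


def genome_summary(
    het_sites: pd.DataFrame | pd.Series,
    scaffold_lengths: dict[str, int],
    weighted: bool = False,
) -> pd.DataFrame:
    """Per-scaffold variants/kb plus the genome average.

    The average row is the unweighted mean over scaffolds (matching the
    convention of averaging a printed per-scaffold column); a
    length-weighted alternative is available via ``weighted``.
    Zero-length scaffolds are excluded and flagged by omission.
    """
    if isinstance(het_sites, pd.Series):
        counts = het_sites
    else:
        counts = het_sites.groupby("scaffold").size()
    rows = []
    for sc in sorted(scaffold_lengths):
        length = scaffold_lengths[sc]
        if length <= 0:
            continue
        n = int(counts.get(sc, 0))
        rows.append((sc, length, n, n / (length / 1000.0)))
    df = pd.DataFrame(rows, columns=["scaffold", "length", "n_variants", "per_kb"])
    if weighted:
        avg = df.n_variants.sum() / (df.length.sum() / 1000.0)
    else:
        avg = df.per_kb.mean()
    total = pd.DataFrame(
        [("Average", df.length.sum(), df.n_variants.sum(), avg)], columns=df.columns
    )
    return pd.concat([df, total], ignore_index=True)


def read_site_summaries(path: str | Path) -> pd.DataFrame:
    """Site-summary TSV: scaffold, pos, depth, alleleA, countA, alleleB,
    countB (pos 0-based)."""
    return pd.read_csv(path, sep="\t")


def write_window_bed(windows: list[WindowDensity], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\tstart\tend\tn_variants\tper_kb\n")
        for w in windows:
            fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\t{w.n_variants}\t{w.per_kb:.4f}\n")
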