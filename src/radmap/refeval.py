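"""Reference-strategy evaluation: scaffold x linkage-group concordance.

For each reference dialect used to score markers, mapped markers are
cross-tabulated by the scaffold they align to and the linkage group
they map into.  A clean reference puts (nearly) all markers of a
scaffold into one LG; collisions from repetitive sequence smear rows
across groups.  Row purity (modal-LG fraction) and the percentage of
scored markers that end up mapped summarize each strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConcordanceMatrix:
    """rows = scaffolds (top-N by length), columns = linkage groups,
    cells = mapped-marker counts."""

    counts: pd.DataFrame
    n_other_scaffolds: int = 0   # mapped markers on non-top scaffolds
    n_unplaced: int = 0          # mapped markers with no alignment scaffold

    def row_purity(self) -> pd.Series:
        """Modal-LG fraction per scaffold row (ties -> lower LG index)."""
        sums = self.counts.sum(axis=1)
        modal = self.counts.max(axis=1)
        return (modal / sums.replace(0, np.nan)).rename("purity")

    def modal_lg(self) -> pd.Series:
        return self.counts.idxmax(axis=1).rename("modal_lg")

    @property
    def total_in_matrix(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_concordance(
    map_frame: pd.DataFrame,
    marker_info: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    top_n_scaffolds: int = 10,
) -> ConcordanceMatrix:
    """Cross-tabulate mapped markers: alignment scaffold x linkage group.

    ``map_frame`` is a GeneticMap frame (lg, marker, cm) whose marker
    ids may be bins; ``marker_info`` maps each marker/bin id to its
    alignment scaffold (column "scaffold"); rows with empty scaffold are
    counted as unplaced.  Top scaffolds are chosen by length.
    """
    top = [
        s for s, _ in sorted(
            scaffold_lengths.items(), key=lambda kv: (-kv[1], kv[0])
        )[:top_n_scaffolds]
    ]
    lgs = sorted(map_frame.lg.unique())
    counts = pd.DataFrame(0, index=top, columns=lgs, dtype=int)
    n_other = 0
    n_unplaced = 0
    for _, row in map_frame.iterrows():
        sc = marker_info.loc[row.marker, "scaffold"] if row.marker in marker_info.index else ""
        weight = int(marker_info.loc[row.marker].get("n_members", 1)) if row.marker in marker_info.index else 1
        if not sc:
            n_unplaced += weight
        elif sc in counts.index:
            counts.loc[sc, row.lg] += weight
        else:
            n_other += weight
    return ConcordanceMatrix(counts=counts, n_other_scaffolds=n_other,
                             n_unplaced=n_unplaced)


def percent_anchored(n_mapped: int, n_scored: int) -> int:
    """Percentage of scored markers that were mapped, reported to the
    integer as in the summary-table convention."""
    if n_scored <= 0:
        raise ValueError("n_scored must be positive")
    if not 0 <= n_mapped <= n_scored:
        raise ValueError("need 0 <= n_mapped <= n_scored")
    return int(round(100.0 * n_mapped / n_scored))


def heatmap_fractions(concordance: ConcordanceMatrix) -> pd.DataFrame:
    """Row-normalized concordance (each row sums to 1 over LG columns);
    all-zero rows are emitted as zeros."""
    sums = concordance.counts.sum(axis=1)
    frac = concordance.counts.div(sums.replace(0, np.nan), axis=0)
    return frac.fillna(0.0)


def strategy_summary(mode: str, n_scored: int, n_mapped: int,
                     concordance: ConcordanceMatrix) -> dict:
    purity = concordance.row_purity().dropna()
    return {
        "mode": mode,
        "scored": int(n_scored),
        "mapped": int(n_mapped),
        "percent_anchored": percent_anchored(n_mapped, n_scored) if n_scored else 0,
        "mean_purity": float(purity.mean()) if len(purity) else float("nan"),
    }
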