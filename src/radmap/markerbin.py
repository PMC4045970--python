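"""Recombination-bin collapsing of co-segregating markers.

Two markers of the same segregation type share a bin when their
similarity score equals the progeny count: every progeny is either
identical or missing in one of them, i.e. zero observed recombinants.
Scores are computed under both phase alignments and the better one is
taken, so repulsion-phase co-segregation also collapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genocall import MISSING, GenotypeMatrix

# phase flip per CP code within a segregation type
_FLIP = {"nn": "np", "np": "nn", "ll": "lm", "lm": "ll",
         "hh": "kk", "kk": "hh", "hk": "hk", MISSING: MISSING}


@dataclass
class BinAssignment:
    bin_id: str
    representative: str
    members: list[str]
    genotypes: pd.Series  # representative's call vector

    @property
    def size(self) -> int:
        return len(self.members)


def similarity_score(calls_a, calls_b, try_phase_flip: bool = True) -> int:
    """Sum of identical and missing genotype agreements across progeny.

    Range [0, n_progeny]; computed under both phase alignments with the
    maximum taken.  The two markers must cover the same progeny set.
    """
    a = pd.Series(calls_a)
    b = pd.Series(calls_b)
    if len(a) != len(b) or not (a.index == b.index).all():
        raise ValueError("markers cover different progeny sets")

    def score(bv):
        miss = (a == MISSING) | (bv == MISSING)
        return int((miss | (a == bv)).sum())

    s = score(b)
    if try_phase_flip:
        s = max(s, score(b.map(_FLIP)))
    return s


def collapse_bins(matrix: GenotypeMatrix,
                  max_conflicts: int = 0) -> tuple[list[BinAssignment], GenotypeMatrix]:
    """Partition markers into recombination bins.

    A marker joins a bin only when its score reaches n_progeny minus
    ``max_conflicts`` against *every* current member (conflict veto);
    with the default of zero, one conflicting call keeps markers apart.
    The error-tolerant setting (max_conflicts > 0) is provided as a
    knob but is not the semantics of a recombination bin and stays off
    by default.  Markers are processed in a canonical order (fewest
    missing calls, then genomic coordinate, then id) which makes the
    partition independent of input order; the representative is the
    first member under that same order.

    Returns (bins, binned matrix with one row per bin).
    """
    calls = matrix.calls
    info = matrix.info
    n = len(calls.columns)

    def sort_key(marker):
        row = calls.loc[marker]
        n_missing = int((row == MISSING).sum())
        pos = info.loc[marker, "pos"] if "pos" in info.columns else 0
        sc = info.loc[marker, "scaffold"] if "scaffold" in info.columns else ""
        return (n_missing, str(sc), int(pos), marker)

    ordered = sorted(calls.index, key=sort_key)
    # precompute plain and phase-flipped call arrays for fast scoring
    arr = {m: calls.loc[m].to_numpy(dtype=object) for m in ordered}
    flipped = {
        m: calls.loc[m].map(_FLIP).to_numpy(dtype=object) for m in ordered
    }

    need = n - max_conflicts

    def compatible(ma, mb) -> bool:
        a, b, bf = arr[ma], arr[mb], flipped[mb]
        miss = (a == MISSING) | (b == MISSING)
        if (miss | (a == b)).sum() >= need:
            return True
        return bool((miss | (a == bf)).sum() >= need)

    bins: list[BinAssignment] = []
    by_type: dict[str, list[BinAssignment]] = {}
    for marker in ordered:
        seg = info.loc[marker, "seg_type"]
        row = calls.loc[marker]
        placed = False
        for b in by_type.get(seg, []):
            if all(compatible(m, marker) for m in b.members):
                b.members.append(marker)
                placed = True
                break
        if not placed:
            b = BinAssignment(
                bin_id=f"bin{len(bins) + 1:04d}",
                representative=marker,
                members=[marker],
                genotypes=row.copy(),
            )
            bins.append(b)
            by_type.setdefault(seg, []).append(b)

    bin_calls = pd.DataFrame(
        {b.bin_id: b.genotypes for b in bins}
    ).T.reindex(columns=calls.columns)
    bin_info = pd.DataFrame(
        {
            "marker": [b.bin_id for b in bins],
            "scaffold": [info.loc[b.representative, "scaffold"] for b in bins],
            "pos": [info.loc[b.representative, "pos"] for b in bins],
            "seg_type": [info.loc[b.representative, "seg_type"] for b in bins],
            "source": [info.loc[b.representative].get("source", "radseq") for b in bins],
            "n_members": [b.size for b in bins],
            "representative": [b.representative for b in bins],
        }
    ).set_index("marker")
    binned = GenotypeMatrix(
        calls=bin_calls, info=bin_info, reference_mode=matrix.reference_mode
    )
    return bins, binned


def write_bin_table(bins: list[BinAssignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\trepresentative\tmember_count\tmembers\n")
        for b in bins:
            fh.write(f"{b.bin_id}\t{b.representative}\t{b.size}\t{','.join(b.members)}\n")
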