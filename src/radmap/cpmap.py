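"""Linkage-map construction from CP genotypes.

Two-point recombination fractions and LOD scores, linkage grouping by
connected components over (LOD, r) thresholds, Stam-style weighted
least-squares ordering with a ripple refinement, and Kosambi map
positions.  Maternal and paternal maps are built independently from
their testcross markers; intercross (hk x hk) markers are informative
for both and enter either map through a generic two-point maximum
likelihood over the joint progeny classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genocall import (
    MISSING,
    SEG_INTERCROSS,
    SEG_MATERNAL,
    SEG_PATERNAL,
    GenotypeMatrix,
    filter_distortion,
)
from .mapfunc import kosambi_cm, inverse_kosambi  # noqa: F401  (re-exported)

LOD_MIN = 5.0
RF_MAX = 0.25
RIPPLE_WINDOW = 3
_PAIR_LOD_FLOOR = 0.1  # pairs below this LOD carry no ordering weight


@dataclass
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    r_hat: float
    lod: float
    n_informative: int
    phase: str = "coupling"


@dataclass
class TwoPointTable:
    """Dense pairwise r / LOD / N over one marker set."""

    markers: list[str]
    r: np.ndarray
    lod: np.ndarray
    n: np.ndarray
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {m: i for i, m in enumerate(self.markers)}

    def get(self, a: str, b: str) -> TwoPointEstimate:
        i, j = self.index[a], self.index[b]
        return TwoPointEstimate(a, b, float(self.r[i, j]), float(self.lod[i, j]),
                                int(self.n[i, j]))


def lod_testcross(n: int, recombinants: int) -> float:
    """LOD = (N-R) log10 2(1-r) + R log10 2r at r = R/N; 0 at r = 0.5."""
    if n == 0:
        return 0.0
    r = recombinants / n
    if r >= 0.5:
        return 0.0
    lod = (n - recombinants) * np.log10(2 * (1 - r))
    if recombinants:
        lod += recombinants * np.log10(2 * r)
    return float(lod)


def _testcross_code(calls: pd.Series, seg_type: str) -> np.ndarray:
    """0/1/nan encoding of a testcross (or dominant-coded) marker."""
    one = {"np", "lm", "hk"}  # hk unused here; testcross only
    out = np.full(len(calls), np.nan)
    vals = calls.to_numpy(dtype=object)
    out[np.isin(vals, ["nn", "ll", "hh"])] = 0.0
    out[np.isin(vals, list(one))] = 1.0
    return out


def estimate_rf_testcross(code_a: np.ndarray, code_b: np.ndarray) -> TwoPointEstimate:
    both = ~np.isnan(code_a) & ~np.isnan(code_b)
    n = int(both.sum())
    if n == 0:
        return TwoPointEstimate("a", "b", 0.5, 0.0, 0)
    diff = int((code_a[both] != code_b[both]).sum())
    rec = min(diff, n - diff)
    phase = "coupling" if diff <= n - diff else "repulsion"
    r = rec / n
    return TwoPointEstimate("a", "b", r, lod_testcross(n, rec), n, phase)


# -- generic two-point likelihood (handles hk x hk and mixed pairs) ---------


def _parent_gametes(het_a: bool, het_b: bool, phase: int, r: float):
    """Joint (allele_a, allele_b) gamete probabilities for one parent.

    Homozygous loci contribute allele 0 deterministically.  Phase 0 is
    coupling (1-1 / 0-0 haplotypes), phase 1 repulsion.
    """
    if het_a and het_b:
        if phase == 0:
            return {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2,
                    (0, 1): r / 2, (1, 0): r / 2}
        return {(0, 1): (1 - r) / 2, (1, 0): (1 - r) / 2,
                (0, 0): r / 2, (1, 1): r / 2}
    if het_a:
        return {(0, 0): 0.5, (1, 0): 0.5}
    if het_b:
        return {(0, 0): 0.5, (0, 1): 0.5}
    return {(0, 0): 1.0}


def _observable(seg: str, maternal_allele: int, paternal_allele: int) -> str:
    if seg == SEG_PATERNAL:
        return "np" if paternal_allele else "nn"
    if seg == SEG_MATERNAL:
        return "lm" if maternal_allele else "ll"
    dose = maternal_allele + paternal_allele
    return ("hh", "hk", "kk")[dose]


def _pair_class_probs(seg_a: str, seg_b: str, phase_m: int, phase_p: int, r: float):
    m_het_a = seg_a in (SEG_MATERNAL, SEG_INTERCROSS)
    m_het_b = seg_b in (SEG_MATERNAL, SEG_INTERCROSS)
    p_het_a = seg_a in (SEG_PATERNAL, SEG_INTERCROSS)
    p_het_b = seg_b in (SEG_PATERNAL, SEG_INTERCROSS)
    probs: dict[tuple[str, str], float] = {}
    for (ma, mb), pm in _parent_gametes(m_het_a, m_het_b, phase_m, r).items():
        for (pa, pb), pp in _parent_gametes(p_het_a, p_het_b, phase_p, r).items():
            key = (_observable(seg_a, ma, pa), _observable(seg_b, mb, pb))
            probs[key] = probs.get(key, 0.0) + pm * pp
    return probs


def estimate_rf_general(calls_a: pd.Series, calls_b: pd.Series,
                        seg_a: str, seg_b: str) -> TwoPointEstimate:
    """Two-point ML over the joint progeny class table; phases enumerated,
    r maximized numerically per phase, best phase kept."""
    ok = (calls_a != MISSING) & (calls_b != MISSING)
    counts: dict[tuple[str, str], int] = {}
    for a, b in zip(calls_a[ok], calls_b[ok]):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    n = int(ok.sum())
    if n == 0:
        return TwoPointEstimate("a", "b", 0.5, 0.0, 0)

    def neg_loglik(r, phase_m, phase_p):
        probs = _pair_class_probs(seg_a, seg_b, phase_m, phase_p, r)
        ll = 0.0
        for key, c in counts.items():
            p = probs.get(key, 0.0)
            if p <= 0:
                return 1e9  # impossible class under this model
            ll += c * np.log(p)
        return -ll

    best = None
    for phase_m in (0, 1):
        for phase_p in (0, 1):
            res = minimize_scalar(
                neg_loglik, bounds=(1e-6, 0.5), args=(phase_m, phase_p),
                method="bounded", options={"xatol": 1e-5},
            )
            if best is None or res.fun < best[0]:
                best = (float(res.fun), float(res.x), phase_m, phase_p)
    ll_null = -neg_loglik(0.5, 0, 0)
    lod = (-(best[0]) - ll_null) / np.log(10)
    lod = max(0.0, float(lod))
    r_hat = min(best[1], 0.5)
    phase = "coupling" if (best[2], best[3]) == (0, 0) else "repulsion"
    return TwoPointEstimate("a", "b", r_hat, lod, n, phase)


def estimate_rf(calls_a, calls_b, seg_a: str = SEG_PATERNAL,
                seg_b: str = SEG_PATERNAL) -> TwoPointEstimate:
    """Two-point estimate for a marker pair.

    Same-parent testcross pairs use the closed form r = R/N with phase
    chosen to minimize r; any pair involving an intercross marker falls
    back to the generic likelihood.  Testcross pairs from different
    parents segregate through different meioses and are unlinked by
    construction (r = 0.5, LOD 0).
    """
    calls_a = pd.Series(calls_a)
    calls_b = pd.Series(calls_b)
    if seg_a == seg_b and seg_a in (SEG_PATERNAL, SEG_MATERNAL):
        est = estimate_rf_testcross(
            _testcross_code(calls_a, seg_a), _testcross_code(calls_b, seg_b)
        )
        return est
    if {seg_a, seg_b} == {SEG_PATERNAL, SEG_MATERNAL}:
        ok = (calls_a != MISSING) & (calls_b != MISSING)
        return TwoPointEstimate("a", "b", 0.5, 0.0, int(ok.sum()))
    return estimate_rf_general(calls_a, calls_b, seg_a, seg_b)


def pairwise_table(matrix: GenotypeMatrix, parent: str) -> TwoPointTable:
    """All-pairs two-point table for one parental map.

    ``parent`` is "maternal" or "paternal"; markers of the matching
    testcross type plus intercross markers are included.  Same-type
    testcross pairs are computed vectorized; pairs involving intercross
    markers use the generic likelihood.
    """
    seg_tc = SEG_PATERNAL if parent == "paternal" else SEG_MATERNAL
    info = matrix.info
    use = info.index[(info.seg_type == seg_tc) | (info.seg_type == SEG_INTERCROSS)]
    markers = list(use)
    m = len(markers)
    r = np.full((m, m), 0.5)
    lod = np.zeros((m, m))
    nmat = np.zeros((m, m), dtype=int)
    tc_idx = [i for i, mk in enumerate(markers) if info.loc[mk, "seg_type"] == seg_tc]
    hk_idx = [i for i, mk in enumerate(markers) if info.loc[mk, "seg_type"] == SEG_INTERCROSS]

    if tc_idx:
        X = np.vstack(
            [_testcross_code(matrix.calls.loc[markers[i]], seg_tc) for i in tc_idx]
        )
        V = (~np.isnan(X)).astype(float)
        M1 = np.nan_to_num(X)          # 1 where allele 1
        M0 = V - M1                    # 1 where allele 0
        N = V @ V.T
        same = M1 @ M1.T + M0 @ M0.T
        diff = N - same
        rec = np.minimum(diff, N - diff)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(N > 0, rec / np.maximum(N, 1), 0.5)
            l1 = (N - rec) * np.log10(np.maximum(2 * (1 - rr), 1e-300))
            l2 = np.where(rec > 0, rec * np.log10(np.maximum(2 * rr, 1e-300)), 0.0)
            ld = np.where((N > 0) & (rr < 0.5), l1 + l2, 0.0)
        for a, ia in enumerate(tc_idx):
            for b, ib in enumerate(tc_idx):
                r[ia, ib] = rr[a, b] if N[a, b] > 0 else 0.5
                lod[ia, ib] = max(ld[a, b], 0.0)
                nmat[ia, ib] = N[a, b]

    for i in hk_idx:
        for j in range(m):
            if j == i:
                continue
            est = estimate_rf_general(
                matrix.calls.loc[markers[i]], matrix.calls.loc[markers[j]],
                info.loc[markers[i], "seg_type"], info.loc[markers[j], "seg_type"],
            )
            r[i, j] = r[j, i] = est.r_hat
            lod[i, j] = lod[j, i] = est.lod
            nmat[i, j] = nmat[j, i] = est.n_informative
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, 0.0)
    return TwoPointTable(markers=markers, r=r, lod=lod, n=nmat)


def group_markers(table: TwoPointTable, lod_min: float = LOD_MIN,
                  rf_max: float = RF_MAX) -> list[list[str]]:
    """Linkage groups = connected components of the (LOD, r) threshold
    graph, largest first; singletons are reported as unlinked groups."""
    g = nx.Graph()
    g.add_nodes_from(table.markers)
    m = len(table.markers)
    for i in range(m):
        for j in range(i + 1, m):
            if table.lod[i, j] >= lod_min and table.r[i, j] <= rf_max:
                g.add_edge(table.markers[i], table.markers[j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


# -- ordering ---------------------------------------------------------------


def _pair_arrays(table: TwoPointTable, ids: list[str]):
    """Distances and inverse-variance weights for the ordering objective.

    Distances inside the layout objective are Haldane transforms of the
    pair estimates: under a no-interference crossover model the Haldane
    distance is additive in expectation over intervening intervals, so
    long-range pairs agree with sums of short ones and anchor the
    layout instead of pulling chromosome ends inward (a mapping-function
    mismatch that rewards folded orders).  Weights are pair LODs.  The
    reported map positions are still Kosambi; this choice only affects
    which order the layout prefers.
    """
    from .mapfunc import CM_CAP

    idx = [table.index[m] for m in ids]
    r = np.minimum(table.r[np.ix_(idx, idx)], 0.49999)
    lod = table.lod[np.ix_(idx, idx)]
    d = np.minimum(-50.0 * np.log(1.0 - 2.0 * r), CM_CAP)
    w = np.where(lod >= _PAIR_LOD_FLOOR, lod, 0.0)
    np.fill_diagonal(w, 0.0)
    return d, w


def _wls_positions(d: np.ndarray, w: np.ndarray, order: list[int]):
    """Weighted LS positions given an order; x[order[0]] anchored at 0.
    Returns (positions aligned with ``order``, weighted SSE)."""
    m = len(order)
    rows = []
    rhs = []
    wts = []
    for a in range(m):
        for b in range(a + 1, m):
            i, j = order[a], order[b]
            if w[i, j] > 0:
                rows.append((a, b))
                rhs.append(d[i, j])
                wts.append(w[i, j])
    if not rows:
        return np.arange(m, dtype=float), 0.0
    A = np.zeros((len(rows), m - 1))
    for k, (a, b) in enumerate(rows):
        if b > 0:
            A[k, b - 1] += 1.0
        if a > 0:
            A[k, a - 1] -= 1.0
    sw = np.sqrt(np.asarray(wts))
    sol, *_ = np.linalg.lstsq(A * sw[:, None], np.asarray(rhs) * sw, rcond=None)
    x = np.concatenate(([0.0], sol))
    resid = (A @ sol - np.asarray(rhs)) * sw
    return x, float(resid @ resid)


def _insertion_cost(d, w, order, x, new):
    """Best slot for ``new`` with existing positions fixed."""
    best = None
    m = len(order)
    dn = np.array([d[new, i] for i in order])
    wn = np.array([w[new, i] for i in order])
    usable = wn > 0
    for slot in range(m + 1):
        sign = np.where(np.arange(m) < slot, 1.0, -1.0)  # left: x_new = x_i + d
        target = x + sign * dn
        wsum = wn[usable].sum()
        if wsum == 0:
            cost, xn = 0.0, (x[slot - 1] if slot else x[0])
        else:
            xn = float((wn[usable] * target[usable]).sum() / wsum)
            cost = float((wn[usable] * (target[usable] - xn) ** 2).sum())
        if best is None or cost < best[0]:
            best = (cost, slot, xn)
    return best


def order_group(group: list[str], table: TwoPointTable,
                ripple_window: int = RIPPLE_WINDOW) -> list[str]:
    """Order markers by incremental weighted-least-squares placement.

    Markers are inserted in decreasing information order (sum of pair
    LODs, ties by id); each insertion slot minimizes the weighted
    squared deviation between fitted and observed pair distances; a
    sliding-window ripple accepts improving permutations.  Deterministic
    for a given table.
    """
    if len(group) < 2:
        return list(group)
    d, w = _pair_arrays(table, group)
    m = len(group)
    info_order = sorted(range(m), key=lambda i: (-w[i].sum(), group[i]))
    order = [info_order[0], info_order[1]]
    x, _ = _wls_positions(d, w, order)
    # small groups afford a full WLS refit per candidate slot; large
    # ones use the fixed-positions approximation during the scan
    exact_scan = m <= 80
    for new in info_order[2:]:
        if exact_scan:
            best = None
            for slot in range(len(order) + 1):
                cand = order[:slot] + [new] + order[slot:]
                _, sse = _wls_positions(d, w, cand)
                if best is None or sse < best[0]:
                    best = (sse, slot)
            slot = best[1]
        else:
            _, slot, _ = _insertion_cost(d, w, order, x, new)
        order.insert(slot, new)
        x, _ = _wls_positions(d, w, order)

    # ripple to convergence
    improved = True
    passes = 0
    _, best_sse = _wls_positions(d, w, order)
    while improved and passes < 10:
        improved = False
        passes += 1
        for start in range(0, m - ripple_window + 1):
            window = order[start:start + ripple_window]
            for perm in permutations(window):
                if list(perm) == window:
                    continue
                cand = order[:start] + list(perm) + order[start + ripple_window:]
                _, sse = _wls_positions(d, w, cand)
                if sse < best_sse - 1e-9:
                    order = cand
                    best_sse = sse
                    improved = True

    # window permutations cannot undo a misplaced block; for small
    # groups, polish with single-marker relocation and segment
    # reversal (2-opt) until no move improves the WLS objective
    if exact_scan:
        improved = True
        passes = 0
        while improved and passes < 5:
            improved = False
            passes += 1
            for i in range(m):
                marker = order[i]
                rest = order[:i] + order[i + 1:]
                for slot in range(m):
                    if slot == i:
                        continue
                    cand = rest[:slot] + [marker] + rest[slot:]
                    _, sse = _wls_positions(d, w, cand)
                    if sse < best_sse - 1e-9:
                        order = cand
                        best_sse = sse
                        improved = True
                        break
            for i in range(m - 1):
                for j in range(i + 2, m + 1):
                    cand = order[:i] + order[i:j][::-1] + order[j:]
                    _, sse = _wls_positions(d, w, cand)
                    if sse < best_sse - 1e-9:
                        order = cand
                        best_sse = sse
                        improved = True
    # canonical direction: first marker id smaller than last
    if group[order[0]] > group[order[-1]]:
        order = order[::-1]
    return [group[i] for i in order]


# -- map assembly -----------------------------------------------------------


@dataclass
class LinkageGroupMap:
    lg_id: str
    markers: list[str]
    positions: list[float]

    @property
    def length_cm(self) -> float:
        return self.positions[-1] if self.positions else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class GeneticMap:
    parent: str
    groups: list[LinkageGroupMap]
    unlinked: list[str] = field(default_factory=list)

    @property
    def total_length_cm(self) -> float:
        return float(sum(g.length_cm for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for mk, cm in zip(g.markers, g.positions):
                rows.append((g.lg_id, mk, cm))
        return pd.DataFrame(rows, columns=["lg", "marker", "cm"])


def map_positions(ordered: list[str], table: TwoPointTable) -> list[float]:
    """Cumulative Kosambi positions over adjacent pairs (first marker at
    0); a missing adjacent estimate is bridged by the shortest-path
    distance through intermediate markers."""
    if len(ordered) == 1:
        return [0.0]
    g = None
    pos = [0.0]
    for a, b in zip(ordered, ordered[1:]):
        i, j = table.index[a], table.index[b]
        if table.n[i, j] > 0 and table.r[i, j] < 0.5:
            step = kosambi_cm(float(table.r[i, j]))
        else:
            if g is None:
                g = nx.Graph()
                m = len(table.markers)
                for p in range(m):
                    for q in range(p + 1, m):
                        if table.n[p, q] > 0 and table.lod[p, q] >= _PAIR_LOD_FLOOR:
                            g.add_edge(
                                table.markers[p], table.markers[q],
                                weight=float(kosambi_cm(min(table.r[p, q], 0.49999))),
                            )
            try:
                step = nx.shortest_path_length(g, a, b, weight="weight")
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                step = kosambi_cm(0.49999)
        pos.append(pos[-1] + float(step))
    return pos


def build_map(matrix: GenotypeMatrix, parent: str = "paternal",
              lod_min: float = LOD_MIN, rf_max: float = RF_MAX,
              ripple_window: int = RIPPLE_WINDOW) -> tuple[GeneticMap, TwoPointTable]:
    """Group, order and position one parental map."""
    table = pairwise_table(matrix, parent)
    comps = group_markers(table, lod_min, rf_max)
    groups = []
    unlinked = []
    k = 0
    for comp in comps:
        if len(comp) < 2:
            unlinked.extend(comp)
            continue
        k += 1
        ordered = order_group(comp, table, ripple_window)
        pos = map_positions(ordered, table)
        groups.append(LinkageGroupMap(f"LG{k}", ordered, pos))
    return GeneticMap(parent=parent, groups=groups, unlinked=unlinked), table


def merge_external_markers(matrix: GenotypeMatrix,
                           external_calls: pd.DataFrame,
                           external_info: pd.DataFrame | None = None,
                           max_missing: float = 0.10) -> GenotypeMatrix:
    """Append an external (e.g. SSR-style) CP genotype table.

    External markers bypass read-depth filters but still face the
    integrity and distortion filters.  Progeny columns must match.
    """
    if external_calls.empty:
        return matrix
    if list(external_calls.columns) != list(matrix.calls.columns):
        raise ValueError("external table progeny do not match the matrix")
    keep = []
    for marker, row in external_calls.iterrows():
        missing_frac = (row == MISSING).mean()
        if missing_frac > max_missing:
            continue
        seg = (
            external_info.loc[marker, "seg_type"]
            if external_info is not None
            else _guess_seg_type(row)
        )
        ok, _ = filter_distortion(list(row.values), seg_type=seg)
        if ok:
            keep.append((marker, seg, row))
    if not keep:
        return matrix
    add_calls = pd.DataFrame(
        {m: r for m, _, r in keep}
    ).T.reindex(columns=matrix.calls.columns)
    add_info = pd.DataFrame(
        {
            "marker": [m for m, _, _ in keep],
            "scaffold": [
                external_info.loc[m, "scaffold"]
                if external_info is not None and "scaffold" in external_info.columns
                else "" for m, _, _ in keep
            ],
            "pos": [
                int(external_info.loc[m, "pos"])
                if external_info is not None and "pos" in external_info.columns
                else -1 for m, _, _ in keep
            ],
            "seg_type": [s for _, s, _ in keep],
            "source": "external",
        }
    ).set_index("marker")
    return GenotypeMatrix(
        calls=pd.concat([matrix.calls, add_calls]),
        info=pd.concat([matrix.info, add_info]),
        reference_mode=matrix.reference_mode,
    )


def _guess_seg_type(row: pd.Series) -> str:
    vals = set(row.values) - {MISSING}
    if vals <= {"nn", "np"}:
        return SEG_PATERNAL
    if vals <= {"ll", "lm"}:
        return SEG_MATERNAL
    return SEG_INTERCROSS


def write_map(genetic_map: GeneticMap, info: pd.DataFrame, path) -> None:
    """Map TSV: LG, marker, cM, source."""
    df = genetic_map.to_frame()
    df["source"] = [
        info.loc[m, "source"] if m in info.index else "radseq" for m in df.marker
    ]
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
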