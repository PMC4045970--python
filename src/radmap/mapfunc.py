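"""Map functions: conversions between recombination fraction and cM.

Kosambi is the estimation-side map function; Haldane is the truth-side
conversion implied by a Poisson (no-interference) crossover model, which
is what the simulator draws.
"""

from __future__ import annotations

import numpy as np

#: Sentinel distance reported when r has reached independence (r >= 0.5).
CM_CAP = 1e6


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 * ln((1+2r)/(1-2r)) in cM.

    r >= 0.5 maps to a capped sentinel rather than +inf so cumulative
    positions stay finite and the condition remains visible.
    """
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, CM_CAP)
    ok = r < 0.5
    out[ok] = 25.0 * np.log((1.0 + 2.0 * r[ok]) / (1.0 - 2.0 * r[ok]))
    if out.ndim == 0:
        return float(out)
    return out


def inverse_kosambi(cm: float | np.ndarray) -> float | np.ndarray:
    """r = 0.5 * tanh(2d) with d in Morgans (cm/100)."""
    d = np.asarray(cm, dtype=float) / 100.0
    r = 0.5 * np.tanh(2.0 * d)
    if r.ndim == 0:
        return float(r)
    return r


def haldane_r(cm: float | np.ndarray) -> float | np.ndarray:
    """Recombinant fraction for a Poisson crossover process: (1 - e^{-2d})/2."""
    d = np.asarray(cm, dtype=float) / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    if r.ndim == 0:
        return float(r)
    return r


def inverse_haldane(r: float | np.ndarray) -> float | np.ndarray:
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, CM_CAP)
    ok = r < 0.5
    out[ok] = -50.0 * np.log(1.0 - 2.0 * r[ok])
    if out.ndim == 0:
        return float(out)
    return out
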