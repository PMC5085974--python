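"""Independent brute-force oracles used to cross-check the pipeline.

Each oracle deliberately uses a different mechanism from the library code
it checks: erosion by explicit neighbourhood shifts (and a pure-Python
triple loop for tiny grids), ROI sums by per-voxel Python accumulation,
DVH metrics by looping over member voxels, the Wilcoxon null by exhaustive
enumeration of rank assignments, and the resolution rule by a direct
re-statement of its text.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def erode_once_shifts(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Binary erosion as an AND over explicit offsets of the element."""
    out = np.ones_like(mask, dtype=bool)
    center = np.array(element.shape) // 2
    for offset in np.argwhere(element):
        d = offset - center
        shifted = np.zeros_like(mask, dtype=bool)
        src = [slice(max(0, -dd), mask.shape[i] - max(0, dd)) for i, dd in enumerate(d)]
        dst = [slice(max(0, dd), mask.shape[i] - max(0, -dd)) for i, dd in enumerate(d)]
        shifted[tuple(dst)] = mask[tuple(src)]
        out &= shifted  # outside-image treated as background
    return out


def erode_shifts(mask: np.ndarray, element: np.ndarray, iterations: int) -> np.ndarray:
    out = mask.astype(bool)
    for _ in range(iterations):
        out = erode_once_shifts(out, element)
    return out


def erode_once_loop(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Pure-Python neighbourhood scan (tiny grids only)."""
    nx, ny, nz = mask.shape
    center = tuple(s // 2 for s in element.shape)
    offsets = [tuple(o - c for o, c in zip(off, center)) for off in zip(*np.nonzero(element))]
    out = np.zeros_like(mask, dtype=bool)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                keep = True
                for dx, dy, dz in offsets:
                    x, y, z = i + dx, j + dy, k + dz
                    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz) or not mask[x, y, z]:
                        keep = False
                        break
                out[i, j, k] = keep
    return out


def roi_measures_loop(values: np.ndarray, mask: np.ndarray, spacing_mm) -> tuple[float, float, float]:
    """(mass_mg, density_mg_cc, volume_ml) by per-voxel accumulation."""
    vv_cc = (spacing_mm[0] * spacing_mm[1] * spacing_mm[2]) / 1000.0
    members = [float(values[tuple(idx)]) for idx in np.argwhere(mask)]
    if not members:
        raise ValueError("empty ROI")
    total = math.fsum(members)
    return total * vv_cc, total / len(members), len(members) * vv_cc


def dvh_loop(dose: np.ndarray, mask: np.ndarray, x_gy: float) -> dict:
    """D_max/D_mean/D_min/V_x by looping over member voxels."""
    vals = [float(dose[tuple(idx)]) for idx in np.argwhere(mask)]
    if not vals:
        raise ValueError("empty structure")
    at_least = sum(1 for v in vals if v >= x_gy)
    return {
        "D_max": max(vals),
        "D_min": min(vals),
        "D_mean": math.fsum(vals) / len(vals),
        "V_x": 100.0 * at_least / len(vals),
    }


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-sided rank-sum p by enumerating all C(n1+n2, n1) assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    n1, n = len(x), len(x) + len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties by assumption
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = [sum(c) - n1 * (n1 + 1) / 2 for c in itertools.combinations(range(1, n + 1), n1)]
    total = len(us)
    lower = sum(1 for u in us if u <= u_obs) / total
    upper = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(lower, upper))


def resolution_rule(v_baseline_ml: float, v_followup_ml: float,
                    full=0.80, partial_lower=0.20, floor_ml=15.0) -> str:
    """Direct restatement of the labelling rule for the sweep cross-check."""
    decrease = v_baseline_ml - v_followup_ml
    fraction = decrease / v_baseline_ml
    if decrease < floor_ml:
        return "none"
    if fraction < partial_lower:
        return "none"
    if fraction > full:
        return "full"
    return "partial"
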