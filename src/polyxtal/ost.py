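"""Orthogonal space tempering: the 2D (λ, F_λ) bias and its bookkeeping.

A second-order generalized-ensemble bias: repulsive 2D Gaussian hills
are deposited over the coupling λ and its conjugate force
F_λ = ∂U/∂λ, flattening free-energy barriers both along the
vacuum-to-crystal path and perpendicular to it.  Hill heights decay
exponentially (transition tempering) once a coverage statistic — the
minimum over λ of the maximum bias over F_λ — exceeds a threshold,
so the entire path must be at least lightly covered before tempering
begins.  A 1D bias along λ is derived from the biased ensemble average
of F_λ by thermodynamic integration; its negative is the running
free-energy profile estimate.

Hills are snapped to the bin grid on deposition; evaluation is the
smooth analytic sum of the deposited Gaussians (truncated at five bins
per axis), so bias energy and its partial derivatives are exact
derivatives of one another.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .energy import KB

__all__ = [
    "OSTParams",
    "BiasGrid",
    "deposit_hill",
    "bias_energy_and_gradient",
    "coverage_statistic",
    "tempering_height",
    "one_d_bias",
    "free_energy_profile",
    "total_bias",
    "save_checkpoint",
    "load_checkpoint",
    "merge_grids",
]

CHECKPOINT_VERSION = "polyxtal-bias 1"


@dataclass(frozen=True)
class OSTParams:
    """Tunables of the OST bias.

    Defaults are the production values of the search: λ bins of width
    0.005 and F_λ bins of 2 kcal/mol; Gaussian widths of two bins in
    either dimension (w1 = 0.01, w2 = 4 kcal/mol); evaluation truncated
    after five bins; initial hill height 0.05 kcal/mol; tempering
    threshold V_th = 1 kcal/mol with rate ΔT = 2 k_BT.
    """

    hill_height: float = 0.05  # h(t0), kcal/mol
    lam_bin_width: float = 0.005
    flam_bin_width: float = 2.0  # kcal/mol
    w1: float = 0.01  # Gaussian width along λ
    w2: float = 4.0  # Gaussian width along F_λ, kcal/mol
    truncation_bins: int = 5
    tempering_threshold: float = 1.0  # V_th, kcal/mol
    tempering_rate: float = 2.0  # ΔT in multiples of k_BT
    deposition_stride: int = 10  # MD steps between hills

    def __post_init__(self) -> None:
        for name in ("hill_height", "lam_bin_width", "flam_bin_width", "w1",
                     "w2", "tempering_threshold", "tempering_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class BiasGrid:
    """Accumulated hill heights over (λ, F_λ) plus derived quantities.

    The λ axis covers [0, 1] exactly with bin centers at multiples of
    the bin width.  The F_λ axis starts at ±100 kcal/mol and doubles
    outward on demand; expansion preserves deposited bias bit-exactly.
    """

    def __init__(self, params: OSTParams | None = None, flam_range: float = 100.0):
        self.params = params or OSTParams()
        p = self.params
        self.n_lam = int(round(1.0 / p.lam_bin_width)) + 1
        nf = int(math.ceil(flam_range / p.flam_bin_width))
        self._f_lo = -nf  # F-bin index of the first stored column
        n_f = 2 * nf + 1
        # deposited hill heights per (λ bin, F bin) cell
        self.heights = np.zeros((self.n_lam, n_f))
        # smooth bias evaluated at bin centers (incrementally stamped)
        self.values = np.zeros((self.n_lam, n_f))
        # per-λ-bin visit statistics for the 1D bias
        self.counts = np.zeros(self.n_lam, dtype=np.int64)
        self.sum_w = np.zeros(self.n_lam)
        self.sum_wf = np.zeros(self.n_lam)
        self.one_d = np.zeros(self.n_lam)  # cached f_m per λ bin
        self._stamp = self._make_stamp()

    # -- axes ------------------------------------------------------------

    @property
    def lam_centers(self) -> np.ndarray:
        return np.arange(self.n_lam) * self.params.lam_bin_width

    @property
    def flam_centers(self) -> np.ndarray:
        return (np.arange(self.heights.shape[1]) + self._f_lo) * self.params.flam_bin_width

    def _lam_bin(self, lam: float) -> int:
        m = int(round(lam / self.params.lam_bin_width))
        return min(max(m, 0), self.n_lam - 1)

    def _f_bin(self, flam: float) -> int:
        return int(round(flam / self.params.flam_bin_width))

    def _ensure_f(self, k: int) -> int:
        """Grow the F axis (doubling outward) until bin index k ± truncation
        fits; returns the column index of k."""
        pad = self.params.truncation_bins
        while k - pad < self._f_lo or k + pad > self._f_lo + self.heights.shape[1] - 1:
            n_f = self.heights.shape[1]
            grow = n_f  # double outward, symmetric
            half = grow // 2
            self.heights = np.pad(self.heights, ((0, 0), (half, grow - half)))
            self.values = np.pad(self.values, ((0, 0), (half, grow - half)))
            self._f_lo -= half
        return k - self._f_lo

    def _make_stamp(self) -> np.ndarray:
        """Truncated unit-height 2D Gaussian sampled at bin centers."""
        p = self.params
        t = p.truncation_bins
        dm = np.arange(-t, t + 1) * p.lam_bin_width
        dk = np.arange(-t, t + 1) * p.flam_bin_width
        return np.exp(-0.5 * (dm[:, None] / p.w1) ** 2 - 0.5 * (dk[None, :] / p.w2) ** 2)

    # -- sampling hooks ---------------------------------------------------

    def record_visit(self, lam: float, flam: float, beta: float) -> None:
        """Accumulate one sample for the thermodynamic-integration bias.

        Samples are reweighted by exp(β g_m) to undo the 2D bias when
        estimating ⟨F_λ⟩ per λ bin.
        """
        m = self._lam_bin(lam)
        g, _, _ = bias_energy_and_gradient(self, lam, flam)
        w = math.exp(min(beta * g, 500.0))
        self.counts[m] += 1
        self.sum_w[m] += w
        self.sum_wf[m] += w * flam


def deposit_hill(grid: BiasGrid, lam: float, flam: float, height: float) -> BiasGrid:
    """Deposit one truncated 2D Gaussian hill of the given height at (λ, F_λ).

    The hill center snaps to the nearest bin centers.  Mutates and
    returns the grid.
    """
    if not (np.isfinite(flam) and np.isfinite(lam)):
        raise ValueError(f"non-finite hill center ({lam}, {flam})")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    p = grid.params
    m = grid._lam_bin(lam)
    kcol = grid._ensure_f(grid._f_bin(flam))
    grid.heights[m, kcol] += height
    t = p.truncation_bins
    lo_m, hi_m = max(m - t, 0), min(m + t, grid.n_lam - 1)
    grid.values[lo_m:hi_m + 1, kcol - t:kcol + t + 1] += (
        height * grid._stamp[lo_m - m + t:hi_m - m + t + 1]
    )
    return grid


def bias_energy_and_gradient(
    grid: BiasGrid, lam: float, flam: float
) -> tuple[float, float, float]:
    """Smooth 2D bias g_m(λ, F_λ) and its partials (∂/∂λ, ∂/∂F_λ).

    Analytic sum of the deposited Gaussians whose centers lie within the
    truncation radius of the query point.  The force on coordinates is
    assembled by the caller via the chain rule with ∂²U/∂λ∂x.
    """
    p = grid.params
    t = p.truncation_bins
    m = grid._lam_bin(lam)
    k = grid._f_bin(flam)
    lo_m, hi_m = max(m - t, 0), min(m + t, grid.n_lam - 1)
    k_lo_col = k - t - grid._f_lo
    k_hi_col = k + t - grid._f_lo
    n_f = grid.heights.shape[1]
    lo_c, hi_c = max(k_lo_col, 0), min(k_hi_col, n_f - 1)
    if hi_c < lo_c or hi_m < lo_m:
        return 0.0, 0.0, 0.0
    H = grid.heights[lo_m:hi_m + 1, lo_c:hi_c + 1]
    if not H.any():
        return 0.0, 0.0, 0.0
    lam_c = np.arange(lo_m, hi_m + 1) * p.lam_bin_width
    f_c = (np.arange(lo_c, hi_c + 1) + grid._f_lo) * p.flam_bin_width
    dl = (lam - lam_c)[:, None]
    df = (flam - f_c)[None, :]
    g = H * np.exp(-0.5 * (dl / p.w1) ** 2 - 0.5 * (df / p.w2) ** 2)
    e = float(g.sum())
    de_dl = float((g * (-dl / p.w1**2)).sum())
    de_df = float((g * (-df / p.w2**2)).sum())
    return e, de_dl, de_df


def coverage_statistic(grid: BiasGrid) -> float:
    """Coverage V(t): min over λ bins of the max bias over F_λ bins."""
    return float(grid.values.max(axis=1).min())


def tempering_height(
    params: OSTParams, coverage: float, kT: float = KB * 298.15
) -> float:
    """Tempered hill height h(t_i), nonincreasing in the coverage.

    Equals h(t0) until the coverage reaches V_th, then decays as
    exp(−(V(t) − V_th) / (ΔT · k_BT)).
    """
    if coverage < 0:
        raise ValueError("coverage must be nonnegative")
    v_ex = coverage - params.tempering_threshold
    if v_ex <= 0:
        return params.hill_height
    return params.hill_height * math.exp(-v_ex / (params.tempering_rate * kT))


def one_d_bias(grid: BiasGrid, beta: float | None = None) -> np.ndarray:
    """Rebuild and cache the 1D bias f_m(λ) per λ bin.

    f_m(λ) = −∫₀^λ ⟨F_λ'⟩ dλ' by trapezoid integration over the λ bins,
    where ⟨F_λ'⟩ is the bias-reweighted bin average recorded during
    sampling (weights ∝ e^{β g_m}); f_m(0) = 0.  λ bins never visited
    take the average of their nearest visited neighbors.
    """
    visited = grid.sum_w > 0
    mean_f = np.zeros(grid.n_lam)
    if visited.any():
        mean_f[visited] = grid.sum_wf[visited] / grid.sum_w[visited]
        if not visited.all():
            idx = np.flatnonzero(visited)
            missing = np.flatnonzero(~visited)
            lo = np.searchsorted(idx, missing) - 1
            hi = np.clip(lo + 1, 0, len(idx) - 1)
            lo = np.clip(lo, 0, len(idx) - 1)
            mean_f[missing] = 0.5 * (mean_f[idx[lo]] + mean_f[idx[hi]])
    dl = grid.params.lam_bin_width
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (mean_f[1:] + mean_f[:-1]) * dl)]
    )
    grid.one_d = -integral
    return grid.one_d


def free_energy_profile(grid: BiasGrid) -> np.ndarray:
    """Free-energy estimate ΔG(λ) = ∫₀^λ ⟨F_λ'⟩ dλ' (= −f_m) per λ bin."""
    return -one_d_bias(grid)


def total_bias(grid: BiasGrid, lam: float, flam: float) -> float:
    """Total OST bias f_m(λ) + g_m(λ, F_λ) in kcal/mol.

    Uses the cached 1D bias (linearly interpolated between bin centers);
    call `one_d_bias` to rebuild it after new samples.
    """
    g, _, _ = bias_energy_and_gradient(grid, lam, flam)
    f = float(np.interp(lam, grid.lam_centers, grid.one_d))
    return f + g


def total_bias_and_gradient(
    grid: BiasGrid, lam: float, flam: float
) -> tuple[float, float, float]:
    """(f_m + g_m, ∂/∂λ, ∂/∂F_λ); the f_m part is piecewise linear in λ."""
    g, gl, gf = bias_energy_and_gradient(grid, lam, flam)
    centers = grid.lam_centers
    f = float(np.interp(lam, centers, grid.one_d))
    m = min(grid._lam_bin(lam), grid.n_lam - 2)
    df = (grid.one_d[m + 1] - grid.one_d[m]) / grid.params.lam_bin_width
    return f + g, gl + float(df), gf


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(grid: BiasGrid, path) -> None:
    """Versioned JSON dump of the grid (bounds, bins, heights, statistics)."""
    p = grid.params
    payload = {
        "version": CHECKPOINT_VERSION,
        "params": {
            "hill_height": p.hill_height,
            "lam_bin_width": p.lam_bin_width,
            "flam_bin_width": p.flam_bin_width,
            "w1": p.w1,
            "w2": p.w2,
            "truncation_bins": p.truncation_bins,
            "tempering_threshold": p.tempering_threshold,
            "tempering_rate": p.tempering_rate,
            "deposition_stride": p.deposition_stride,
        },
        "f_lo": grid._f_lo,
        "n_f": grid.heights.shape[1],
        "heights": [
            [int(m), int(k), h]
            for m, k in zip(*np.nonzero(grid.heights))
            for h in [float(grid.heights[m, k])]
        ],
        "counts": grid.counts.tolist(),
        "sum_w": grid.sum_w.tolist(),
        "sum_wf": grid.sum_wf.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> BiasGrid:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported bias checkpoint version in {path}")
    grid = BiasGrid(OSTParams(**payload["params"]))
    need = payload["f_lo"] + payload["n_f"] - 1
    grid._ensure_f(payload["f_lo"] + grid.params.truncation_bins)
    grid._ensure_f(need - grid.params.truncation_bins)
    # grow to at least the stored extent, then restamp hills
    for m, k, h in payload["heights"]:
        kabs = k + payload["f_lo"]
        col = grid._ensure_f(kabs)
        grid.heights[m, col] += h
        t = grid.params.truncation_bins
        lo_m, hi_m = max(m - t, 0), min(m + t, grid.n_lam - 1)
        grid.values[lo_m:hi_m + 1, col - t:col + t + 1] += (
            h * grid._stamp[lo_m - m + t:hi_m - m + t + 1]
        )
    grid.counts = np.asarray(payload["counts"], dtype=np.int64)
    grid.sum_w = np.asarray(payload["sum_w"], dtype=float)
    grid.sum_wf = np.asarray(payload["sum_wf"], dtype=float)
    one_d_bias(grid)
    return grid


def merge_grids(grids: list[BiasGrid]) -> BiasGrid:
    """Additively merge multi-walker bias grids (histograms and statistics)."""
    if not grids:
        raise ValueError("no grids to merge")
    out = BiasGrid(grids[0].params)
    for g in grids:
        if g.params != out.params:
            raise ValueError("cannot merge grids with different parameters")
        for m, k in zip(*np.nonzero(g.heights)):
            kabs = k + g._f_lo
            col = out._ensure_f(kabs)
            h = float(g.heights[m, k])
            out.heights[m, col] += h
            t = out.params.truncation_bins
            lo_m, hi_m = max(m - t, 0), min(m + t, out.n_lam - 1)
            out.values[lo_m:hi_m + 1, col - t:col + t + 1] += (
                h * out._stamp[lo_m - m + t:hi_m - m + t + 1]
            )
        out.counts += g.counts
        out.sum_w += g.sum_w
        out.sum_wf += g.sum_wf
    one_d_bias(out)
    return out
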