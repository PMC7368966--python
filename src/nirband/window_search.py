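"""Grid-search moving-window stage: exhaustive (N, S) waveband scan with PLS.

A window is a contiguous waveband of ``N`` channels starting at 1-based
channel ``S``; admissibility requires ``S + N - 1 <= P``.  For every window on
the grid a PLS model is fitted on the calibration part for each candidate
latent-variable count and the count minimizing the validation RMSE is kept.
The optimal window is the argmin of validation RMSE over the whole grid; a
ranked list of mutually non-overlapping top-k wavebands feeds the downstream
component-compression and genetic-refinement stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .regression import evaluate, fit_pls, max_components, predict
from .spectra import SpectralDataset, WavelengthAxis

__all__ = ["Window", "WindowGrid", "WindowRecord", "GSMWResult",
           "enumerate_windows", "evaluate_window", "gsmw_search",
           "select_top_windows", "DEFAULT_N_GRID_SPEC"]

#: the full-resolution N grid used for a 700-channel axis:
#: every width up to 100, then steps of 10 up to 300 and 20 up to 700.
DEFAULT_N_GRID_SPEC = "1:1:100,110:10:300,320:20:700"


@dataclass(frozen=True, order=True)
class Window:
    """Contiguous waveband: 1-based start channel S, width N (channels)."""

    S: int
    N: int

    def __post_init__(self) -> None:
        if self.S < 1 or self.N < 1:
            raise ValueError(f"window requires S >= 1 and N >= 1, got {self}")

    @property
    def last(self) -> int:
        """1-based index of the last channel in the window."""
        return self.S + self.N - 1

    def overlaps(self, other: "Window") -> bool:
        return self.S <= other.last and other.S <= self.last

    def start_nm(self, axis: WavelengthAxis) -> float:
        return axis.wavelength_of_index(self.S)

    def end_nm(self, axis: WavelengthAxis) -> float:
        return axis.wavelength_of_index(self.last)


@dataclass(frozen=True)
class WindowGrid:
    """Admissible window widths; start positions are always all admissible S."""

    n_values: tuple[int, ...]

    def __post_init__(self) -> None:
        ns = tuple(int(n) for n in self.n_values)
        if not ns:
            raise ValueError("window grid has no N values")
        if any(n < 1 for n in ns) or any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("N values must be strictly increasing positive integers")
        object.__setattr__(self, "n_values", ns)

    @classmethod
    def from_spec(cls, spec: str, p: int | None = None) -> "WindowGrid":
        """Parse a grid string like ``"1:1:100,110:10:300,320:20:700"``.

        Each comma-separated piece is ``start:step:stop`` (inclusive) or a
        single integer.  If ``p`` is given, widths above ``p`` are dropped.
        """
        ns: list[int] = []
        for piece in spec.split(","):
            piece = piece.strip()
            if ":" in piece:
                a, s, b = (int(x) for x in piece.split(":"))
                ns.extend(range(a, b + 1, s))
            else:
                ns.append(int(piece))
        if p is not None:
            ns = [n for n in ns if n <= p]
        return cls(tuple(sorted(set(ns))))

    @classmethod
    def full(cls, p: int) -> "WindowGrid":
        """Every width 1..p."""
        return cls(tuple(range(1, p + 1)))


@dataclass(frozen=True)
class WindowRecord:
    window: Window
    best_lv: int
    rmsev: float
    r_v: float | None


@dataclass(frozen=True)
class GSMWResult:
    """Full RMSE-surface of the window scan plus a ranking by validation RMSE."""

    axis: WavelengthAxis
    records: tuple[WindowRecord, ...]
    ranking: tuple[int, ...] = field(default=())  # record indices, best first

    def __post_init__(self) -> None:
        if not self.ranking:
            order = sorted(
                range(len(self.records)),
                key=lambda i: (self.records[i].rmsev,
                               self.records[i].window.N,
                               self.records[i].window.S),
            )
            object.__setattr__(self, "ranking", tuple(order))

    @property
    def best(self) -> WindowRecord:
        return self.records[self.ranking[0]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format surface: one row per evaluated window."""
        rows = [{
            "N": r.window.N,
            "S": r.window.S,
            "start_nm": r.window.start_nm(self.axis),
            "end_nm": r.window.end_nm(self.axis),
            "best_LV": r.best_lv,
            "RMSEV": r.rmsev,
            "R_V": r.r_v,
        } for r in self.records]
        return pd.DataFrame(rows)


def enumerate_windows(p: int, grid: WindowGrid) -> list[Window]:
    """All admissible windows, N ascending then S ascending.

    For each admissible width the count of start positions is ``p - N + 1``,
    so the total is ``sum_N (p - N + 1)`` — 78,790 for the 700-channel axis
    with the full-resolution grid.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    return [Window(S=s, N=n)
            for n in grid.n_values if n <= p
            for s in range(1, p - n + 2)]


def evaluate_window(window: Window, cal: SpectralDataset, val: SpectralDataset,
                    lv_cap: int = 15) -> WindowRecord:
    """Fit the window's PLS model, choosing the LV count by validation RMSE.

    A single NIPALS fit at the ceiling provides coefficients at every
    truncation level, so the latent-variable scan costs one fit per window.
    """
    if cal.axis != val.axis:
        raise ValueError("calibration and validation sets must share an axis")
    Xc = cal.window_matrix(window.S, window.N)
    Xv = val.window_matrix(window.S, window.N)
    a_max = max_components(window.N, cal.n_samples, cap=lv_cap)
    if a_max < 1:
        raise ValueError("no latent variable admissible for this window")
    model = fit_pls(Xc, cal.y, a_max)
    best: tuple[float, int] | None = None
    for a in range(1, model.n_components + 1):
        rmsev = float(np.sqrt(np.mean((predict(model, Xv, a) - val.y) ** 2)))
        if best is None or rmsev < best[0]:
            best = (rmsev, a)
    if best is None:  # rank-deficient beyond component 0
        rep = evaluate(val.y, np.full(val.n_samples, model.y_mean))
        return WindowRecord(window=window, best_lv=0, rmsev=rep.rmse, r_v=rep.r)
    rep = evaluate(val.y, predict(model, Xv, best[1]), which_set="validation")
    return WindowRecord(window=window, best_lv=best[1], rmsev=rep.rmse, r_v=rep.r)


def gsmw_search(cal: SpectralDataset, val: SpectralDataset, grid: WindowGrid,
                lv_cap: int = 15) -> GSMWResult:
    """Evaluate every admissible window on the grid (full surface retained).

    Each window's evaluation is independent, so the result does not depend on
    execution order; records are stored in enumeration order (N, then S).
    """
    windows = enumerate_windows(cal.axis.count, grid)
    records = tuple(evaluate_window(w, cal, val, lv_cap=lv_cap) for w in windows)
    return GSMWResult(axis=cal.axis, records=records)


def select_top_windows(result: GSMWResult, k: int) -> list[WindowRecord]:
    """Greedy top-k by ascending RMSEV, skipping overlapping wavebands.

    Ties are broken toward smaller N, then smaller S.  Returns fewer than k
    records (with a warning) when the surface holds no more disjoint windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chosen: list[WindowRecord] = []
    for i in result.ranking:
        rec = result.records[i]
        if all(not rec.window.overlaps(c.window) for c in chosen):
            chosen.append(rec)
            if len(chosen) == k:
                break
    if len(chosen) < k:
        warnings.warn(
            f"only {len(chosen)} disjoint windows available (requested {k})",
            stacklevel=2)
    return chosen
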