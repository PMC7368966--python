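"""Spectral data model: wavelength axis, dataset container, SNV, delimited-text I/O.

A near-infrared dataset is an ``n_samples x P`` absorbance matrix on a uniform
wavelength axis together with one reference value (analyte content, wt.%) per
sample.  Wavelength channels are addressed with 1-based indices ``S`` so that
channel ``S`` sits at ``start_nm + (S - 1) * step_nm``; all public interfaces
and reports use this convention even though arrays are stored 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthAxis",
    "SpectralDataset",
    "span_variable_count",
    "snv_transform",
    "read_dataset",
    "write_dataset",
]

#: relative tolerance for deciding that a wavelength header is uniformly spaced
_AXIS_RTOL = 1e-8


@dataclass(frozen=True)
class WavelengthAxis:
    """Uniform wavelength grid defined by (start, step, count).

    The channel count is authoritative: the last wavelength is derived as
    ``start_nm + (count - 1) * step_nm``, never the other way around, so an
    axis is always self-consistent even when a nominal end wavelength would
    disagree by one channel.
    """

    start_nm: float
    step_nm: float
    count: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def end_nm(self) -> float:
        return self.start_nm + (self.count - 1) * self.step_nm

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.count)

    def wavelength_of_index(self, s: int) -> float:
        """Wavelength (nm) of the 1-based channel index ``s``."""
        if not 1 <= s <= self.count:
            raise IndexError(
                f"channel index {s} out of range 1..{self.count}"
            )
        return self.start_nm + (s - 1) * self.step_nm

    def index_of_wavelength(self, nm: float) -> int:
        """1-based channel index of a wavelength lying exactly on the grid."""
        pos = (nm - self.start_nm) / self.step_nm
        s = int(round(pos)) + 1
        if not 1 <= s <= self.count or abs(pos - round(pos)) > _AXIS_RTOL * max(1.0, abs(pos)):
            raise ValueError(f"{nm} nm is not a channel of {self}")
        return s

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"axis[{self.start_nm}:{self.step_nm}:{self.end_nm} nm, P={self.count}]"


def span_variable_count(start_nm: float, end_nm: float, step_nm: float) -> int:
    """Number of channels in the closed waveband [start_nm, end_nm].

    Both endpoints count, so e.g. 1446-1520 nm at 2 nm spacing holds 38
    variables.  The span must be an exact multiple of the step.
    """
    if end_nm < start_nm:
        raise ValueError(f"end_nm {end_nm} < start_nm {start_nm}")
    span = end_nm - start_nm
    n = span / step_nm
    if abs(n - round(n)) > _AXIS_RTOL * max(1.0, abs(n)):
        raise ValueError(f"span {span} nm is not divisible by step {step_nm} nm")
    return int(round(n)) + 1


@dataclass(frozen=True)
class SpectralDataset:
    """Absorbance matrix + reference values on a shared wavelength axis."""

    axis: WavelengthAxis
    absorbance: np.ndarray  # (n_samples, P)
    y: np.ndarray  # (n_samples,) analyte content, wt.%
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.absorbance, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "absorbance", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if X.shape[1] != self.axis.count:
            raise ValueError(
                f"absorbance has {X.shape[1]} columns but axis has {self.axis.count} channels"
            )
        if y.shape != (X.shape[0],):
            raise ValueError(f"y has shape {y.shape}, expected ({X.shape[0]},)")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("absorbance/y contain non-finite values")
        ids = self.sample_ids or tuple(f"s{i + 1}" for i in range(X.shape[0]))
        if len(ids) != X.shape[0]:
            raise ValueError("sample_ids length mismatch")
        object.__setattr__(self, "sample_ids", tuple(str(i) for i in ids))

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, indices: np.ndarray | list[int]) -> "SpectralDataset":
        """Row subset (0-based indices), preserving order."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            axis=self.axis,
            absorbance=self.absorbance[idx],
            y=self.y[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )

    def window_matrix(self, s: int, n: int) -> np.ndarray:
        """Columns of the window starting at 1-based channel ``s``, width ``n``."""
        if s < 1 or n < 1 or s + n - 1 > self.axis.count:
            raise ValueError(f"window (S={s}, N={n}) not admissible for P={self.axis.count}")
        return self.absorbance[:, s - 1 : s - 1 + n]


def snv_transform(dataset: SpectralDataset) -> SpectralDataset:
    """Standard normal variate: centre and scale each spectrum independently.

    Each row is brought to mean 0 and sample standard deviation 1 (ddof=1),
    removing per-sample multiplicative scatter and additive offset.  The axis
    and reference values are untouched.
    """
    X = dataset.absorbance
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        names = ", ".join(dataset.sample_ids[i] for i in bad[:5])
        raise ValueError(f"SNV undefined for constant spectra: {names}")
    return replace(dataset, absorbance=(X - mean) / sd)


def _check_uniform(wl: np.ndarray) -> WavelengthAxis:
    if wl.size < 1:
        raise ValueError("no wavelength columns")
    if wl.size == 1:
        return WavelengthAxis(float(wl[0]), 1.0, 1)
    steps = np.diff(wl)
    step = steps[0]
    if step <= 0 or not np.allclose(steps, step, rtol=_AXIS_RTOL, atol=0):
        raise ValueError(f"wavelength header is not uniformly spaced: steps {np.unique(steps)[:5]}")
    return WavelengthAxis(float(wl[0]), float(step), int(wl.size))


def read_dataset(path) -> SpectralDataset:
    """Read a dataset from comma-separated text.

    Expected layout: first column ``sample_id``, second column ``reference``,
    remaining columns headed by wavelength in nm (uniform spacing).
    """
    df = pd.read_csv(path)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "reference"]:
        raise ValueError("expected columns: sample_id, reference, <wavelengths...>")
    try:
        wl = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from None
    axis = _check_uniform(wl)
    X = df.iloc[:, 2:].to_numpy(dtype=float)
    y = df["reference"].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("dataset contains missing/non-numeric cells")
    return SpectralDataset(axis=axis, absorbance=X, y=y,
                           sample_ids=tuple(df["sample_id"].astype(str)))


def write_dataset(dataset: SpectralDataset, path) -> None:
    """Write a dataset in the format :func:`read_dataset` reads."""
    cols = {"sample_id": list(dataset.sample_ids),
            "reference": dataset.y}
    df = pd.DataFrame(cols)
    wl = dataset.axis.wavelengths()
    spec = pd.DataFrame(dataset.absorbance, columns=[repr(float(w)) for w in wl])
    pd.concat([df, spec], axis=1).to_csv(path, index=False)
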