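"""Spectral containers and per-spectrum preprocessing.

Vis-NIR reflectance/absorbance scans are stored in a :class:`SpectralSet`:
a common wavelength grid plus one row per scan, with sample and replicate
identifiers. All transforms here are *per-spectrum* (no statistics are
learned from a calibration set), so they can be applied before any
train/test split without leakage.

The canonical pipeline order is fixed: trim edge wavelengths, average
replicate scans, then apply a scatter-correcting transform. Standard
Normal Variate (SNV) is the shipped default transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "SpectralSet",
    "PreprocessPlan",
    "DEFAULT_PLAN",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "trim_wavelengths",
    "snv",
    "snv_detrend",
    "savitzky_golay",
    "first_derivative",
    "second_derivative",
    "gap_derivative",
    "apply_plan",
    "standard_pipeline",
]


@dataclass
class SpectralSet:
    """A set of spectra on a shared, strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of shape (p,)
        Wavelength of each band, in nm, strictly increasing.
    values : array of shape (n_scans, p)
        One row per scan (absorbance-like units).
    sample_ids : array of shape (n_scans,)
        Identifier of the physical sample each scan belongs to.
    rep_ids : array of shape (n_scans,)
        Replicate index of each scan within its sample.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: np.ndarray
    rep_ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids)
        self.rep_ids = np.asarray(self.rep_ids, dtype=int)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be 1-D")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing (unsorted grid)")
        n, p = self.values.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"values has {p} columns but grid has {self.wavelengths.size} wavelengths"
            )
        if self.sample_ids.shape != (n,) or self.rep_ids.shape != (n,):
            raise ValueError("sample_ids and rep_ids must have one entry per scan row")
        pairs = list(zip(self.sample_ids.tolist(), self.rep_ids.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicated (sample_id, rep_id) pair")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: sample_id, rep, then one column per wavelength."""
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "rep", self.rep_ids)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def write_spectra(spectra: SpectralSet, path) -> None:
    """Write a wide CSV with header ``sample_id,rep,<wavelength_nm>...``."""
    spectra.to_frame().to_csv(path, index=False)


def read_spectra(path) -> SpectralSet:
    """Read a wide spectra CSV (``sample_id,rep,<wavelength>...``).

    Raises
    ------
    ValueError
        If a wavelength header is non-numeric or the grid is unsorted;
        pandas itself rejects ragged rows.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "sample_id" or df.columns[1] != "rep":
        raise ValueError("expected leading columns 'sample_id,rep'")
    wl = []
    for c in df.columns[2:]:
        try:
            wl.append(float(c))
        except ValueError as exc:
            raise ValueError(f"non-numeric wavelength header {c!r}") from exc
    wl = np.asarray(wl)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("unsorted wavelength headers")
    return SpectralSet(
        wavelengths=wl,
        values=df.iloc[:, 2:].to_numpy(dtype=float),
        sample_ids=df["sample_id"].to_numpy(),
        rep_ids=df["rep"].to_numpy(dtype=int),
    )


def average_replicates(spectra: SpectralSet) -> SpectralSet:
    """Average replicate scans of each sample into one spectrum.

    The mean is the plain arithmetic mean over a sample's replicates.
    Output rows keep the first-appearance order of the sample ids, and
    every output ``rep_id`` is 0.
    """
    ids = pd.Index(spectra.sample_ids)
    order = ids.drop_duplicates()
    frame = pd.DataFrame(spectra.values)
    frame["__sid"] = spectra.sample_ids
    mean = frame.groupby("__sid", sort=False).mean()
    mean = mean.loc[order]
    return SpectralSet(
        wavelengths=spectra.wavelengths,
        values=mean.to_numpy(),
        sample_ids=np.asarray(order),
        rep_ids=np.zeros(len(order), dtype=int),
    )


def trim_wavelengths(
    spectra: SpectralSet, low_nm: float = 399.0, high_nm: float = 2451.0
) -> SpectralSet:
    """Drop bands outside ``[low_nm, high_nm]`` to suppress edge effects."""
    keep = (spectra.wavelengths >= low_nm) & (spectra.wavelengths <= high_nm)
    if not keep.any():
        raise ValueError(f"no bands left in [{low_nm}, {high_nm}]")
    return SpectralSet(
        wavelengths=spectra.wavelengths[keep],
        values=spectra.values[:, keep],
        sample_ids=spectra.sample_ids,
        rep_ids=spectra.rep_ids,
    )


def snv(spectra: SpectralSet) -> SpectralSet:
    """Standard Normal Variate: centre and scale each spectrum.

    Each row is transformed to mean 0 and unit sample standard deviation
    (n−1 divisor), removing additive offsets and multiplicative scatter.
    """
    if spectra.n_bands < 2:
        raise ValueError("SNV needs at least 2 bands per spectrum")
    mu = spectra.values.mean(axis=1, keepdims=True)
    sd = spectra.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd.ravel() == 0)[0]
    if zero.size:
        sid = spectra.sample_ids[zero[0]]
        raise ValueError(f"zero variance spectrum (sample {sid!r}): SNV undefined")
    return replace(spectra, values=(spectra.values - mu) / sd)


def snv_detrend(spectra: SpectralSet, poly_degree: int = 2) -> SpectralSet:
    """SNV followed by per-spectrum polynomial baseline removal.

    After SNV a least-squares polynomial of ``poly_degree`` in wavelength
    is fitted to each spectrum and subtracted, reducing curvature and
    wavelength-dependent scatter.
    """
    if poly_degree >= spectra.n_bands:
        raise ValueError("poly_degree must be smaller than the band count")
    out = snv(spectra)
    # Scale wavelengths to [-1, 1] for a well-conditioned Vandermonde fit.
    w = out.wavelengths
    x = 2 * (w - w[0]) / (w[-1] - w[0]) - 1 if w[-1] > w[0] else w * 0
    V = np.vander(x, poly_degree + 1)
    coef, *_ = np.linalg.lstsq(V, out.values.T, rcond=None)
    return replace(out, values=out.values - (V @ coef).T)


def _delta(spectra: SpectralSet) -> float:
    d = np.diff(spectra.wavelengths)
    if not np.allclose(d, d[0]):
        raise ValueError("derivative transforms require a uniform wavelength grid")
    return float(d[0])


def savitzky_golay(
    spectra: SpectralSet, window: int, polyorder: int, deriv: int = 0
) -> SpectralSet:
    """Savitzky–Golay smoothing or derivative, edges truncated.

    ``window`` must be odd and larger than ``polyorder``. The half-window
    at each end of the grid is dropped rather than padded.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if window > spectra.n_bands:
        raise ValueError(
            f"window {window} larger than band count {spectra.n_bands}"
        )
    dx = _delta(spectra)
    vals = savgol_filter(
        spectra.values, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=dx, axis=1,
    )
    h = window // 2
    sl = slice(h, spectra.n_bands - h) if h else slice(None)
    return replace(
        spectra, values=vals[:, sl], wavelengths=spectra.wavelengths[sl]
    )


def gap_derivative(spectra: SpectralSet, gap: int) -> SpectralSet:
    """Finite-difference first derivative over a band gap.

    ``d[i] = (x[i+gap] − x[i−gap]) / (2 · gap · Δλ)``; the ``gap`` bands
    at each edge are truncated.
    """
    if gap < 1 or 2 * gap >= spectra.n_bands:
        raise ValueError("gap must satisfy 1 <= gap and 2*gap < band count")
    dx = _delta(spectra)
    v = spectra.values
    deriv = (v[:, 2 * gap:] - v[:, : -2 * gap]) / (2 * gap * dx)
    return replace(
        spectra, values=deriv, wavelengths=spectra.wavelengths[gap:-gap]
    )


def first_derivative(spectra: SpectralSet) -> SpectralSet:
    """Central-difference first derivative (gap derivative with gap 1)."""
    return gap_derivative(spectra, gap=1)


def second_derivative(spectra: SpectralSet) -> SpectralSet:
    """Central second difference ``(x[i+1] − 2x[i] + x[i−1]) / Δλ²``, edges truncated."""
    if spectra.n_bands < 3:
        raise ValueError("second derivative needs at least 3 bands")
    dx = _delta(spectra)
    v = spectra.values
    deriv = (v[:, 2:] - 2 * v[:, 1:-1] + v[:, :-2]) / dx**2
    return replace(spectra, values=deriv, wavelengths=spectra.wavelengths[1:-1])


@dataclass
class PreprocessPlan:
    """Trim bounds plus an ordered list of per-spectrum transform steps.

    Steps use a compact string grammar:
    ``"snv"``, ``"snv-detrend:<degree>"``, ``"sg:<window>,<poly>"``,
    ``"d1"``, ``"d2"``, ``"gap:<g>"``.
    """

    trim_low_nm: float = 399.0
    trim_high_nm: float = 2451.0
    steps: list = field(default_factory=lambda: ["snv"])

    def __post_init__(self) -> None:
        if self.trim_low_nm >= self.trim_high_nm:
            raise ValueError("trim_low_nm must be below trim_high_nm")
        for s in self.steps:
            _parse_step(s)  # validates the grammar eagerly


def _parse_step(step: str):
    name, _, arg = step.partition(":")
    if name == "snv":
        return lambda s: snv(s)
    if name == "snv-detrend":
        deg = int(arg) if arg else 2
        return lambda s: snv_detrend(s, poly_degree=deg)
    if name == "sg":
        window, poly = (int(a) for a in arg.split(","))
        return lambda s: savitzky_golay(s, window=window, polyorder=poly)
    if name == "d1":
        return first_derivative
    if name == "d2":
        return second_derivative
    if name == "gap":
        return lambda s: gap_derivative(s, gap=int(arg))
    raise ValueError(f"unknown preprocessing step {step!r}")


DEFAULT_PLAN = PreprocessPlan()


def apply_plan(spectra: SpectralSet, plan: PreprocessPlan) -> SpectralSet:
    """Trim to the plan's bounds then apply its transform steps in order."""
    out = trim_wavelengths(spectra, plan.trim_low_nm, plan.trim_high_nm)
    for step in plan.steps:
        out = _parse_step(step)(out)
    return out


def standard_pipeline(
    spectra: SpectralSet, plan: PreprocessPlan = DEFAULT_PLAN
) -> SpectralSet:
    """Fixed production order: trim → average replicates → transform steps."""
    out = trim_wavelengths(spectra, plan.trim_low_nm, plan.trim_high_nm)
    out = average_replicates(out)
    for step in plan.steps:
        out = _parse_step(step)(out)
    return out
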