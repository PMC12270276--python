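"""Spontaneous-brain-function metrics on masked 4D time series.

Implements the five voxel-wise measures — ALFF, fALFF, ReHo, FCD, VMHC —
plus whole-mask standardization (rescale to mean 1) and cluster-mean
extraction.  Conventions not fixed by their classic definitions are
explicit and configurable:

* Amplitude spectrum is single-sided, ``2 |FFT_k| / T`` for 0 < f < Nyquist
  (``|FFT| / T`` at the Nyquist bin when T is even).  The DC bin is excluded
  from ALFF and from fALFF's denominator — a constant offset is not a
  fluctuation.  Any fixed convention cancels after standardization.
* FCD counts strictly-greater, positive-threshold correlations, self
  excluded.
* ReHo uses Kendall's W over the 26-neighborhood (plus the voxel itself)
  without tie correction, on rank-transformed (midrank) series; it expects
  band-pass-filtered input (see :func:`bandpass_filter`).
* VMHC mirrors across the midline of the first array axis; anatomical
  symmetric registration is out of scope.

ALFF and fALFF are computed on unfiltered series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Volume4D",
    "MetricMap",
    "alff",
    "falff",
    "reho",
    "fcd",
    "vmhc",
    "standardize_map",
    "extract_cluster_means",
    "bandpass_filter",
    "compute_all_metrics",
]

DEFAULT_BAND = (0.01, 0.1)


@dataclass
class Volume4D:
    """Masked 4D BOLD-like series: ``data[x, y, z, t]`` with repetition
    time ``tr`` (seconds) and a boolean spatial ``mask``."""

    data: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial shape of data")
        if self.data.shape[3] < 16:
            raise ValueError("need >= 16 timepoints")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside mask")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class MetricMap:
    """3-D metric values; zero outside the mask used to compute them."""

    values: np.ndarray
    metric: str
    standardized: bool = False
    band: tuple | None = None


def _masked_series(vol: Volume4D) -> np.ndarray:
    """(n_mask_voxels, T) view of the in-mask time series."""
    return vol.data[vol.mask]


def _amplitude_spectrum(series: np.ndarray, tr: float):
    """Single-sided amplitude spectrum of (V, T) series.

    Returns (freqs, amps) with the DC amplitude zeroed; the Nyquist bin
    (even T) is not doubled.
    """
    T = series.shape[-1]
    spec = np.abs(np.fft.rfft(series, axis=-1))
    amps = 2.0 * spec / T
    amps[..., 0] = 0.0
    if T % 2 == 0:
        amps[..., -1] = spec[..., -1] / T
    freqs = np.fft.rfftfreq(T, d=tr)
    return freqs, amps


def _band_bins(freqs: np.ndarray, band, nyquist: float) -> np.ndarray:
    low, high = band
    if not (0 < low < high <= nyquist + 1e-12):
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyquist}]")
    sel = (freqs >= low) & (freqs <= high)
    if not sel.any():
        raise ValueError(
            f"band {band} contains no frequency bins; bin grid spacing is "
            f"{freqs[1]:.6g} Hz over [0, {freqs[-1]:.6g}] Hz"
        )
    return sel


def alff(vol: Volume4D, band=DEFAULT_BAND) -> MetricMap:
    """Mean single-sided amplitude over the low-frequency band (DC excluded).

    Computed on unfiltered series."""
    freqs, amps = _amplitude_spectrum(_masked_series(vol), vol.tr)
    sel = _band_bins(freqs, band, vol.nyquist)
    vals = np.zeros(vol.mask.shape)
    vals[vol.mask] = amps[:, sel].mean(axis=1)
    return MetricMap(values=vals, metric="ALFF", band=tuple(band))


def falff(vol: Volume4D, band=DEFAULT_BAND) -> MetricMap:
    """Band amplitude sum over total amplitude sum (DC excluded from both);
    an all-zero series gets value 0."""
    freqs, amps = _amplitude_spectrum(_masked_series(vol), vol.tr)
    sel = _band_bins(freqs, band, vol.nyquist)
    num = amps[:, sel].sum(axis=1)
    den = amps[:, 1:].sum(axis=1)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    if (~nz).any():
        warnings.warn(f"{(~nz).sum()} all-zero series assigned fALFF = 0")
    vals = np.zeros(vol.mask.shape)
    vals[vol.mask] = out
    return MetricMap(values=vals, metric="fALFF", band=tuple(band))


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
]


def reho(vol: Volume4D) -> MetricMap:
    """Kendall's W of each voxel's series with its 26 in-mask neighbors.

    W = 12 S / (m^2 (T^3 - T)) with S the sum over timepoints of the squared
    deviation of the rank sums from their mean and m the number of series
    (voxel + in-mask neighbors); no tie correction.  Voxels with m < 2 get 0.
    """
    T = vol.n_timepoints
    mask = vol.mask
    ranks = np.zeros_like(vol.data)
    ranks[mask] = rankdata(vol.data[mask], axis=-1)

    pad_r = np.pad(ranks, ((1, 1), (1, 1), (1, 1), (0, 0)))
    pad_m = np.pad(mask, 1).astype(float)
    rank_sum = np.zeros_like(ranks)
    m_count = np.zeros(mask.shape)
    nx, ny, nz = mask.shape
    for dx, dy, dz in _NEIGHBOR_OFFSETS:
        sl = (slice(1 + dx, 1 + dx + nx), slice(1 + dy, 1 + dy + ny),
              slice(1 + dz, 1 + dz + nz))
        rank_sum += pad_r[sl]
        m_count += pad_m[sl[:3]]

    # S = sum_t (R_t - mean_t R)^2 per voxel
    mean_r = rank_sum.mean(axis=-1, keepdims=True)
    S = ((rank_sum - mean_r) ** 2).sum(axis=-1)
    vals = np.zeros(mask.shape)
    m = np.where(mask, m_count, 0.0)
    ok = mask & (m >= 2)
    vals[ok] = 12.0 * S[ok] / (m[ok] ** 2 * (T**3 - T))
    n_isolated = int((mask & (m < 2)).sum())
    if n_isolated:
        warnings.warn(f"{n_isolated} isolated voxels assigned ReHo = 0")
    return MetricMap(values=vals, metric="ReHo")


def fcd(vol: Volume4D, r_threshold: float = 0.25, block: int = 512) -> MetricMap:
    """Per voxel, the count of other in-mask voxels whose Pearson r with it
    is strictly greater than ``r_threshold`` (self excluded).

    Constant series correlate with nothing and get count 0."""
    mask = vol.mask
    if mask.sum() < 2:
        raise ValueError("FCD needs >= 2 mask voxels")
    X = _masked_series(vol)
    X = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(X, axis=1)
    const = norm == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant series assigned FCD = 0")
    safe = np.where(const, 1.0, norm)
    Z = X / safe[:, None]
    V = Z.shape[0]
    counts = np.zeros(V, dtype=int)
    for start in range(0, V, block):
        stop = min(start + block, V)
        r = Z[start:stop] @ Z.T
        hits = r > r_threshold
        idx = np.arange(start, stop)
        hits[np.arange(stop - start), idx] = False  # self
        hits[:, const] = False
        counts[start:stop] = hits.sum(axis=1)
    counts[const] = 0
    vals = np.zeros(mask.shape)
    vals[mask] = counts
    return MetricMap(values=vals, metric="FCD")


def _mirror(a: np.ndarray) -> np.ndarray:
    return a[::-1]


def vmhc(vol: Volume4D) -> MetricMap:
    """Pearson r between each voxel's series and its mirror counterpart
    across the midline of the first array axis.

    The effective mask is ``mask & mirror(mask)``."""
    eff = vol.mask & _mirror(vol.mask)
    if not eff.any():
        raise ValueError("effective (symmetrized) mask is empty")
    x = vol.data[eff]
    y = _mirror(vol.data)[eff]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.linalg.norm(xc, axis=1) * np.linalg.norm(yc, axis=1)
    r = np.zeros_like(num)
    nz = den > 0
    r[nz] = num[nz] / den[nz]
    vals = np.zeros(vol.mask.shape)
    vals[eff] = np.clip(r, -1.0, 1.0)
    return MetricMap(values=vals, metric="VMHC")


def standardize_map(metric_map: MetricMap, mask: np.ndarray) -> MetricMap:
    """Rescale so the within-mask mean is 1."""
    mask = np.asarray(mask, dtype=bool)
    mean = metric_map.values[mask].mean()
    if mean == 0 or not np.isfinite(mean):
        raise ValueError("degenerate map: within-mask mean is zero")
    if mean < 0 and metric_map.metric in ("ALFF", "fALFF", "ReHo", "FCD"):
        raise ValueError(
            f"degenerate map: negative within-mask mean for {metric_map.metric}")
    vals = np.where(mask, metric_map.values / mean, 0.0)
    return replace(metric_map, values=vals, standardized=True)


def extract_cluster_means(metric_map: MetricMap, labels: np.ndarray,
                          mask: np.ndarray | None = None):
    """Mean metric value per nonzero cluster label.

    Returns a pandas DataFrame with columns ``label``, ``mean``, ``n_voxels``.
    Labels with no in-mask voxels are omitted with a warning.
    """
    import pandas as pd

    labels = np.asarray(labels)
    if labels.shape != metric_map.values.shape:
        raise ValueError("labels shape must match map shape")
    if mask is None:
        mask = np.ones(labels.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = (labels == lab) & mask
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"cluster label {lab} has no voxels inside the mask")
            continue
        rows.append({"label": int(lab), "mean": float(metric_map.values[sel].mean()),
                     "n_voxels": n})
    return pd.DataFrame(rows, columns=["label", "mean", "n_voxels"])


def bandpass_filter(vol: Volume4D, band=DEFAULT_BAND) -> Volume4D:
    """FFT-domain band-pass: keep rfft bins with low <= f <= high, zero the
    rest (DC removed).  Used before ReHo/FCD/VMHC."""
    T = vol.n_timepoints
    freqs = np.fft.rfftfreq(T, d=vol.tr)
    sel = _band_bins(freqs, band, vol.nyquist)
    spec = np.fft.rfft(vol.data, axis=-1)
    spec[..., ~sel] = 0.0
    data = np.fft.irfft(spec, n=T, axis=-1)
    data[~vol.mask] = 0.0
    return Volume4D(data=data, tr=vol.tr, mask=vol.mask)


def compute_all_metrics(vol: Volume4D, band=DEFAULT_BAND,
                        fcd_threshold: float = 0.25,
                        standardize: bool = True) -> dict[str, MetricMap]:
    """All five metrics with the standard pre-processing split: ALFF/fALFF on
    the raw series, ReHo/FCD/VMHC on the band-passed series; optionally
    standardized to whole-mask mean 1."""
    filtered = bandpass_filter(vol, band)
    maps = {
        "alff": alff(vol, band),
        "falff": falff(vol, band),
        "reho": reho(filtered),
        "fcd": fcd(filtered, fcd_threshold),
        "vmhc": vmhc(filtered),
    }
    if standardize:
        maps = {k: standardize_map(v, vol.mask) for k, v in maps.items()}
    return maps
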