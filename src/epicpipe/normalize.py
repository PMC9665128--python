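"""Beta/M conversion and peak-based correction (PBC) of the Infinium II bias.

Infinium arrays mix two bead chemistries.  Type II probes show compressed,
noisier beta distributions: their unmethylated/methylated density modes sit
closer to 0.5 than the type I modes.  PBC is a within-array correction
that, per sample, estimates the density peaks of type I and type II probes
on the M scale (M = log2(beta / (1 - beta))) and linearly rescales the
type II M values on each side of zero so their peaks align with the type I
peaks.  Type I values are untouched.

Externally normalized matrices (NOOB, BMIQ, SWAN, ...) are not recomputed
here; they are ingested as opaque inputs and tagged for benchmarking via
:class:`NormalizationRegistry`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_formats import BetaMatrix

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "PeakPair",
    "find_peaks",
    "pbc_normalize",
    "NormalizationRegistry",
]

DEFAULT_EPS = 1e-6


def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """M = log2(beta / (1 - beta)), with beta clamped to [eps, 1 - eps].

    Accepts scalars, arrays, Series or DataFrames; missing values propagate.
    Raises on values outside [0, 1].
    """
    arr = np.asarray(beta, dtype=float) if not isinstance(beta, (pd.Series, pd.DataFrame)) else beta
    vals = arr.to_numpy(dtype=float) if isinstance(arr, (pd.Series, pd.DataFrame)) else arr
    finite = np.isfinite(vals)
    if ((vals < 0) | (vals > 1))[finite].any() if vals.ndim else (finite and (vals < 0 or vals > 1)):
        raise ValueError("beta values outside [0, 1]")
    clamped = np.clip(vals, eps, 1.0 - eps)
    m = np.log2(clamped / (1.0 - clamped))
    m = np.where(finite, m, np.nan)
    if isinstance(arr, pd.DataFrame):
        return pd.DataFrame(m, index=arr.index, columns=arr.columns)
    if isinstance(arr, pd.Series):
        return pd.Series(m, index=arr.index, name=arr.name)
    return m if m.ndim else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (2**M + 1).

    Missing values propagate; non-finite (inf) inputs are rejected.
    """
    arr = m
    vals = arr.to_numpy(dtype=float) if isinstance(arr, (pd.Series, pd.DataFrame)) else np.asarray(arr, dtype=float)
    if np.isinf(vals).any():
        raise ValueError("non-finite M value")
    with np.errstate(over="ignore"):
        beta = 1.0 / (1.0 + np.exp2(-vals))
    if isinstance(arr, pd.DataFrame):
        return pd.DataFrame(beta, index=arr.index, columns=arr.columns)
    if isinstance(arr, pd.Series):
        return pd.Series(beta, index=arr.index, name=arr.name)
    return beta if beta.ndim else float(beta)


@dataclass(frozen=True)
class PeakPair:
    """Unmethylated (< 0) and methylated (> 0) M-scale density modes."""

    unmeth_peak: float | None
    meth_peak: float | None
    design_type: str | None = None

    def __post_init__(self):
        if self.unmeth_peak is not None and self.unmeth_peak >= 0:
            raise ValueError("unmeth_peak must be negative")
        if self.meth_peak is not None and self.meth_peak <= 0:
            raise ValueError("meth_peak must be positive")


def _side_peak(values: np.ndarray, grid_points: int = 512) -> float | None:
    if len(values) == 0:
        return None
    if len(np.unique(values)) < 2:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


def find_peaks(m_values, design_type: str | None = None) -> PeakPair:
    """Locate the unmethylated/methylated modes of an M-value distribution.

    A Gaussian kernel density (Silverman bandwidth, 512-point grid) is
    estimated separately on the negative and positive values; each side's
    peak is the density argmax.  A side with no values yields a missing
    (None) peak.
    """
    vals = np.asarray(m_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no finite M values supplied")
    return PeakPair(
        unmeth_peak=_side_peak(vals[vals < 0]),
        meth_peak=_side_peak(vals[vals > 0]),
        design_type=design_type,
    )


def pbc_normalize(matrix: BetaMatrix, probes: pd.DataFrame, eps: float = DEFAULT_EPS) -> BetaMatrix:
    """Peak-based correction of type II probes toward the type I distribution.

    Per sample: convert to M, estimate type I and type II peak pairs, and
    rescale type II values side-wise (M' = M * peakI/peakII for the matching
    sign; M = 0 is left unchanged), then convert back to beta.  If a needed
    peak is missing on one side, that side passes through with a warning.
    Probe count and missingness pattern are preserved exactly.
    """
    design = probes.set_index("probe_id")["design_type"].reindex(matrix.probe_ids)
    if design.isna().any():
        missing = matrix.probe_ids[design.isna()][:5]
        raise ValueError(f"probes missing from the manifest: {list(missing)}")
    is_ii = (design == "II").to_numpy()
    out = matrix.values.copy()
    for sample in matrix.sample_ids:
        beta = matrix.values[sample].to_numpy(dtype=float)
        m = beta_to_m(beta, eps=eps)
        m_i, m_ii = m[~is_ii], m[is_ii]
        if np.isfinite(m_i).sum() < 2 or np.isfinite(m_ii).sum() < 2:
            raise ValueError(f"sample {sample}: need >= 2 probes of each design type")
        peaks_i = find_peaks(m_i, "I")
        peaks_ii = find_peaks(m_ii, "II")
        corrected = m_ii.copy()
        for side, p_i, p_ii in (
            ("unmethylated", peaks_i.unmeth_peak, peaks_ii.unmeth_peak),
            ("methylated", peaks_i.meth_peak, peaks_ii.meth_peak),
        ):
            mask = corrected < 0 if side == "unmethylated" else corrected > 0
            if p_i is None or p_ii is None or p_ii == 0:
                if mask.any():
                    warnings.warn(f"sample {sample}: missing {side} peak; side passed through")
                continue
            corrected[mask] = m_ii[mask] * (p_i / p_ii)
        new_beta = beta.copy()
        new_beta[is_ii] = m_to_beta(corrected)
        new_beta[~np.isfinite(beta)] = np.nan
        out[sample] = new_beta
    return matrix.with_values(out, method="PBC")


class NormalizationRegistry:
    """Registry of externally normalized beta matrices for benchmarking.

    The tag "RAW" is reserved for the unnormalized matrix supplied at
    construction; other methods (NOOB, BMIQ, ...) are ingested with
    :meth:`register` and must match the raw matrix dimensions.
    """

    def __init__(self, raw: BetaMatrix):
        self._matrices: dict[str, BetaMatrix] = {"RAW": raw.with_values(raw.values, method="RAW")}

    def register(self, matrix: BetaMatrix, method_name: str) -> BetaMatrix:
        if method_name in self._matrices:
            raise ValueError(f"duplicate normalization tag {method_name!r}")
        raw = self._matrices["RAW"]
        if matrix.values.shape != raw.values.shape:
            raise ValueError("normalized matrix dimensions do not match the raw matrix")
        tagged = matrix.with_values(matrix.values, method=method_name)
        self._matrices[method_name] = tagged
        return tagged

    def __getitem__(self, tag: str) -> BetaMatrix:
        return self._matrices[tag]

    def __contains__(self, tag: str) -> bool:
        return tag in self._matrices

    def tags(self) -> list[str]:
        return list(self._matrices)
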