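"""Reproducibility, coverage, and variance-heterogeneity benchmarking.

Reproducibility is quantified by absolute pairwise beta differences per
probe between replicates (within one technology) or across technologies,
and by per-probe replicate standard deviations.  Variance heterogeneity is
summarized by the statistic h: per probe, the SD (s) and mean (m) of the
M values across replicates are computed; a local regression of s on m
gives a smoothed s* per probe; h_p = |s*_p - s0| with s0 = mean(s), and
h = mean(h_p).  Under homoscedasticity s is independent of m, the smooth is
flat at s0 and h -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix
from .normalize import beta_to_m

__all__ = [
    "PairwiseDiffDistribution",
    "pairwise_abs_diff",
    "replicate_sd",
    "loess_smooth",
    "HetReport",
    "variance_heterogeneity",
    "CoverageSummary",
    "region_coverage",
    "transcript_coverage",
]


@dataclass
class PairwiseDiffDistribution:
    """Per-probe absolute beta differences for one comparison."""

    label: str
    method: str
    diffs: np.ndarray
    n_probes: int
    n_pairs: int

    def __post_init__(self):
        if len(self.diffs) and (np.nanmin(self.diffs) < 0 or np.nanmax(self.diffs) > 1):
            raise ValueError("absolute beta differences must lie in [0, 1]")

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.diffs))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.nanpercentile(self.diffs, [25, 75])
        return float(q1), float(q3)

    def summary(self) -> dict:
        q1, q3 = self.quartiles
        return {
            "label": self.label,
            "method": self.method,
            "median": self.median,
            "q1": q1,
            "q3": q3,
            "n_probes": self.n_probes,
            "n_pairs": self.n_pairs,
        }


def pairwise_abs_diff(a: BetaMatrix, b: BetaMatrix | None = None, label: str | None = None) -> PairwiseDiffDistribution:
    """Absolute pairwise per-probe beta differences.

    With ``b`` given, every (sample of a, sample of b) cross pair
    contributes; with ``b`` omitted (within mode), each unordered pair of
    distinct samples of ``a`` contributes once.  Only probes shared by both
    inputs are compared; missing values yield missing differences, which
    the summary statistics ignore.
    """
    within = b is None
    bb = a if within else b
    shared = a.probe_ids.intersection(bb.probe_ids)
    if len(shared) == 0:
        raise ValueError("no shared probes between the two matrices")
    va = a.values.loc[shared].to_numpy(dtype=float)
    vb = bb.values.loc[shared].to_numpy(dtype=float)
    cols = []
    if within:
        n = va.shape[1]
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        for i, j in pairs:
            cols.append(np.abs(va[:, i] - va[:, j]))
    else:
        pairs = [(i, j) for i in range(va.shape[1]) for j in range(vb.shape[1])]
        for i, j in pairs:
            cols.append(np.abs(va[:, i] - vb[:, j]))
    diffs = np.concatenate(cols) if cols else np.empty(0)
    if label is None:
        label = f"{a.method}-within" if within else f"{a.method}-vs-{bb.method}"
    return PairwiseDiffDistribution(label, a.method, diffs, len(shared), len(pairs))


def replicate_sd(matrix: BetaMatrix, group: list[str], scale: str = "beta") -> pd.Series:
    """Per-probe sample SD (ddof=1) across a replicate group, on the beta or M scale.

    Probes missing in any group sample get a missing SD.
    """
    if len(group) < 2:
        raise ValueError("replicate group must have >= 2 samples")
    vals = matrix.values[list(group)]
    if scale == "M":
        vals = beta_to_m(vals)
    elif scale != "beta":
        raise ValueError(f"unknown scale {scale!r}")
    sd = vals.std(axis=1, ddof=1)
    sd[vals.isna().any(axis=1)] = np.nan
    return sd.rename("replicate_sd")


# ---------------------------------------------------------------------------
# Local regression (tricube-weighted local quadratic, nearest-neighbour span)

def loess_smooth(x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """Evaluate a loess fit of y on x at every x.

    For each point, the ``ceil(span * n)`` nearest neighbours (by |x - x0|)
    receive tricube weights w = (1 - (d/dmax)^3)^3 and a weighted
    polynomial of the given degree is fit and evaluated at x0.  Degenerate
    windows (dmax = 0 or a singular design) fall back to the weighted mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n == 0:
        return np.empty(0)
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    out_sorted = np.empty(n)
    lo = 0
    for i in range(n):
        x0 = xs[i]
        # k-nearest window is contiguous in sorted order; lo is monotone in i
        lo = max(min(lo, i), 0)
        while lo + k <= i:
            lo += 1
        while lo + k < n and x0 - xs[lo] > xs[lo + k] - x0:
            lo += 1
        xw, yw = xs[lo : lo + k], ys[lo : lo + k]
        d = np.abs(xw - x0)
        dmax = d.max()
        if dmax == 0:
            out_sorted[i] = yw.mean()
            continue
        w = (1.0 - (d / dmax) ** 3) ** 3
        w = np.maximum(w, 0.0)
        X = np.vander(xw - x0, degree + 1, increasing=True)
        WX = X * w[:, None]
        try:
            coef = np.linalg.solve(X.T @ WX, WX.T @ yw)
            out_sorted[i] = coef[0]
        except np.linalg.LinAlgError:
            out_sorted[i] = np.average(yw, weights=w) if w.sum() > 0 else yw.mean()
    out = np.empty(n)
    out[order] = out_sorted
    return out


@dataclass
class HetReport:
    """Variance-heterogeneity decomposition for one replicate group."""

    s: np.ndarray
    m: np.ndarray
    s_star: np.ndarray
    s0: float
    h_p: np.ndarray = field(init=False)
    h: float = field(init=False)

    def __post_init__(self):
        if not (len(self.s) == len(self.m) == len(self.s_star)):
            raise ValueError("s, m, s_star must have equal length")
        self.h_p = np.abs(self.s_star - self.s0)
        self.h = float(self.h_p.mean()) if len(self.h_p) else 0.0


def variance_heterogeneity(
    matrix: BetaMatrix, group: list[str], span: float = 0.75, degree: int = 2
) -> HetReport:
    """Compute the variance-heterogeneity statistic h over a replicate group.

    Steps: M per probe; per-probe SD (s) and mean (m) of M across the
    group; loess smooth of s on m evaluated at each m (s*); s0 = mean(s);
    h_p = |s* - s0|; h = mean(h_p).  Probes missing in any group sample are
    excluded.  An all-constant matrix gives s identically zero and h = 0.
    """
    if len(group) < 2:
        raise ValueError("replicate group must have >= 2 samples")
    mvals = beta_to_m(matrix.values[list(group)])
    complete = mvals.notna().all(axis=1)
    mvals = mvals.loc[complete]
    if len(mvals) < 10:
        raise ValueError("need >= 10 fully observed probes")
    arr = mvals.to_numpy(dtype=float)
    s = arr.std(axis=1, ddof=1)
    m = arr.mean(axis=1)
    if np.allclose(s, s[0]):
        s_star = np.full_like(s, s[0])
    else:
        s_star = loess_smooth(m, s, span=span, degree=degree)
    return HetReport(s=s, m=m, s_star=s_star, s0=float(s.mean()))


# ---------------------------------------------------------------------------
# Coverage

@dataclass(frozen=True)
class CoverageSummary:
    kind: str
    cell_line: str
    total_regions: int
    covered_regions: int
    min_probes: int = 1

    @property
    def fraction(self) -> float:
        return self.covered_regions / self.total_regions


def region_coverage(probes: pd.DataFrame, regions: pd.DataFrame, min_probes: int = 1) -> CoverageSummary:
    """Fraction of super-regions (one cell line, one kind) containing >= min_probes probes."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    kinds = regions["kind"].unique()
    cls = regions["cell_line"].unique()
    if len(kinds) != 1 or len(cls) != 1:
        raise ValueError("regions must come from a single cell line and kind")
    counts = np.zeros(len(regions), dtype=int)
    regions = regions.reset_index(drop=True)
    for chrom, grp in regions.groupby("chrom", sort=False):
        pos = np.sort(probes.loc[probes["chrom"] == chrom, "pos0"].to_numpy())
        if len(pos) == 0:
            continue
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="left")
        counts[grp.index.to_numpy()] = hi - lo
    covered = int((counts >= min_probes).sum())
    return CoverageSummary(kinds[0], cls[0], len(regions), covered, min_probes)


def transcript_coverage(
    annotation: pd.DataFrame, transcripts: pd.DataFrame, source_db: str | None = None
) -> float:
    """Fraction of transcripts associated with at least one probe.

    A transcript counts as covered when its id appears in any of the four
    association lists (TSS-promoter, eRNA, enhancer-target, gene-body) of
    any probe.  ``source_db`` restricts the transcript universe.
    """
    tx = transcripts if source_db is None else transcripts[transcripts["source_db"] == source_db]
    if len(tx) == 0:
        raise ValueError("empty transcript set")
    associated: set[str] = set()
    for col in ("promoter_transcripts", "erna_transcripts", "enhancer_targets", "gene_body_transcripts"):
        if col in annotation.columns:
            for xs in annotation[col]:
                associated.update(xs)
    return float(tx["transcript_id"].isin(associated).mean())
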