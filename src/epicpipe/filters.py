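"""Probe- and site-level filtering with an explicit filtering funnel.

Array probes are removed when any sample fails the detection p-value
threshold (p >= 0.05), when they map to a sex chromosome, when they appear
on a published cross-reactive or SNP-overlap list, or when they are not
observed in every replicate of a group.  RRBS sites are removed below a
minimum read coverage (default 10) or on sex chromosomes; opposite-strand
calls of one CpG are averaged when they agree within 0.10 and discarded
otherwise.  Every step emits a :class:`FilterReport` stage so the funnel
is auditable (input = removed + surviving at every stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SEX_CHROMOSOMES, BetaMatrix

__all__ = [
    "FilterReport",
    "filter_detection",
    "filter_probe_lists",
    "require_complete_replicates",
    "filter_pipeline",
    "rrbs_coverage_filter",
    "rrbs_merge_strands",
    "write_filter_report",
]


@dataclass(frozen=True)
class FilterReport:
    """One stage of the filtering funnel."""

    stage: str
    n_input: int
    n_removed: int

    def __post_init__(self):
        if self.n_removed < 0 or self.n_removed > self.n_input:
            raise ValueError("removed count outside [0, input]")

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed

    @property
    def surviving_fraction(self) -> float:
        return self.n_surviving / self.n_input if self.n_input else 1.0

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_surviving": self.n_surviving,
            "surviving_fraction": self.surviving_fraction,
        }


def write_filter_report(reports: list[FilterReport], path) -> None:
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(path, sep="\t", index=False)


def filter_detection(matrix: BetaMatrix, threshold: float = 0.05) -> tuple[BetaMatrix, FilterReport]:
    """Remove probes whose detection p-value is >= ``threshold`` in any sample."""
    if matrix.detection_p is None:
        raise ValueError("matrix has no detection p-value layer")
    fail = (matrix.detection_p.to_numpy() >= threshold).any(axis=1)
    keep_ids = matrix.probe_ids[~fail]
    report = FilterReport("detection_p", len(matrix.probe_ids), int(fail.sum()))
    return matrix.subset_probes(keep_ids), report


def filter_probe_lists(
    matrix: BetaMatrix,
    probes: pd.DataFrame,
    drop_cross_reactive: bool = True,
    drop_snp: bool = True,
    drop_sex: bool = True,
) -> tuple[BetaMatrix, list[FilterReport]]:
    """Remove sex-chromosome, cross-reactive and SNP-overlap probes, in that order.

    The probe table must cover every probe in the matrix and carry the
    ``cross_reactive`` / ``snp_overlap`` flags (see
    :func:`epicpipe.io_formats.flag_probes`).
    """
    info = probes.set_index("probe_id")
    missing = matrix.probe_ids.difference(info.index)
    if len(missing):
        raise ValueError(f"probes absent from the probe table: {list(missing[:5])}")
    info = info.reindex(matrix.probe_ids)
    reports = []
    out = matrix
    stages = [
        ("sex_chromosomes", drop_sex, info["chrom"].isin(SEX_CHROMOSOMES)),
        ("cross_reactive", drop_cross_reactive, info["cross_reactive"].astype(bool)),
        ("snp_overlap", drop_snp, info["snp_overlap"].astype(bool)),
    ]
    for stage, enabled, mask in stages:
        if not enabled:
            continue
        mask = mask.reindex(out.probe_ids).fillna(False)
        keep_ids = out.probe_ids[~mask.to_numpy()]
        reports.append(FilterReport(stage, len(out.probe_ids), int(mask.sum())))
        out = out.subset_probes(keep_ids)
    return out, reports


def require_complete_replicates(matrix: BetaMatrix, group: list[str]) -> tuple[BetaMatrix, FilterReport]:
    """Keep only probes observed (non-missing) in every sample of ``group``."""
    if not group:
        raise ValueError("group must be non-empty")
    unknown = set(group) - set(matrix.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)}")
    complete = matrix.values[list(group)].notna().all(axis=1)
    report = FilterReport("complete_replicates", len(matrix.probe_ids), int((~complete).sum()))
    return matrix.subset_probes(matrix.probe_ids[complete]), report


def filter_pipeline(
    matrix: BetaMatrix,
    probes: pd.DataFrame,
    group: list[str] | None = None,
    detection_threshold: float = 0.05,
) -> tuple[BetaMatrix, list[FilterReport]]:
    """The fixed array filtering sequence: detection -> sex -> cross-reactive -> SNP -> completeness."""
    out, rep = filter_detection(matrix, detection_threshold)
    reports = [rep]
    out, reps = filter_probe_lists(out, probes)
    reports.extend(reps)
    if group:
        out, rep = require_complete_replicates(out, group)
        reports.append(rep)
    return out, reports


# ---------------------------------------------------------------------------
# RRBS

def rrbs_coverage_filter(
    sites: pd.DataFrame, min_reads: int = 10, drop_sex: bool = True
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep sites with coverage >= ``min_reads``, optionally dropping sex chromosomes."""
    keep = sites["coverage"] >= min_reads
    if drop_sex:
        keep &= ~sites["chrom"].isin(SEX_CHROMOSOMES)
    report = FilterReport("rrbs_coverage", len(sites), int((~keep).sum()))
    return sites.loc[keep].reset_index(drop=True), report


def rrbs_merge_strands(
    sites: pd.DataFrame, max_delta: float = 0.10
) -> tuple[pd.DataFrame, FilterReport]:
    """Collapse opposite-strand calls of one CpG into a single unstranded site.

    The minus-strand cytosine of a CpG sits one base downstream of the plus
    strand one, so a pair is (chrom, p, +) with (chrom, p+1, -).  Paired
    values are averaged (coverage summed) when |delta| < ``max_delta``,
    and both are discarded otherwise; unpaired sites pass through as-is.
    The merged site keeps the plus-strand position with strand ".".
    """
    plus = sites[sites["strand"] == "+"].set_index(["chrom", "position"])
    minus = sites[sites["strand"] == "-"].copy()
    minus["pair_pos"] = minus["position"] - 1
    minus = minus.set_index(["chrom", "pair_pos"])
    common = plus.index.intersection(minus.index)
    p = plus.loc[common]
    m = minus.loc[common]
    delta = (p["meth_fraction"] - m["meth_fraction"]).abs()
    # strict "< max_delta" with a float-safe margin so a delta of exactly
    # max_delta (e.g. 0.50 - 0.40) is discarded despite rounding error
    mergeable = (delta < max_delta - 1e-9).fillna(False).to_numpy()

    merged = pd.DataFrame(
        {
            "chrom": [c for c, _ in common[mergeable]],
            "position": [pos for _, pos in common[mergeable]],
            "strand": ".",
            "coverage": (p["coverage"].to_numpy() + m["coverage"].to_numpy())[mergeable],
            "meth_fraction": ((p["meth_fraction"].to_numpy() + m["meth_fraction"].to_numpy()) / 2.0)[mergeable],
        }
    )
    unpaired_plus = sites[(sites["strand"] == "+")].merge(
        pd.DataFrame(list(common), columns=["chrom", "position"]).assign(_paired=True),
        on=["chrom", "position"],
        how="left",
    )
    unpaired_plus = unpaired_plus[unpaired_plus["_paired"].isna()].drop(columns="_paired")
    minus_all = sites[sites["strand"] == "-"].copy()
    minus_all["pair_pos"] = minus_all["position"] - 1
    unpaired_minus = minus_all.merge(
        pd.DataFrame(list(common), columns=["chrom", "pair_pos"]).assign(_paired=True),
        on=["chrom", "pair_pos"],
        how="left",
    )
    unpaired_minus = unpaired_minus[unpaired_minus["_paired"].isna()].drop(columns=["_paired", "pair_pos"])
    out = pd.concat([merged, unpaired_plus, unpaired_minus], ignore_index=True)
    out = out.sort_values(["chrom", "position", "strand"]).reset_index(drop=True)
    if "pos0" in sites.columns:
        out["pos0"] = out["position"] - 1
        out = out[["chrom", "position", "strand", "coverage", "meth_fraction", "pos0"]]
    report = FilterReport("rrbs_merge_strands", len(sites), len(sites) - len(out))
    return out, report
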