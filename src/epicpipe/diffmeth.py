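"""Differential methylation calling between two sample groups.

Per probe, a t-test (Welch by default, given the variance heterogeneity of
850k data; Student's available) is applied to the M values, p-values are
Benjamini-Hochberg adjusted across all tested probes, and an effect size
delta-beta = |median beta(A) - median beta(B)| is computed on the beta
scale.  A probe is called differentially methylated when adjusted p < 0.05
and delta-beta > 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import CATEGORIES, promoter_nonpromoter
from .io_formats import BetaMatrix
from .normalize import beta_to_m

__all__ = ["call_dm", "DMBreakdown", "breakdown_dm"]


def call_dm(
    matrix: BetaMatrix,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    min_delta: float = 0.2,
    variant: str = "welch",
) -> pd.DataFrame:
    """Call differentially methylated probes between two groups.

    Returns one row per probe: t_statistic, p_value, p_adjusted (BH),
    delta_beta, direction ("hyper" when group A's median beta exceeds
    group B's), zero_variance flag and the final ``called`` flag
    (p_adjusted < alpha and delta_beta > min_delta).  Probes with zero
    variance in both groups are assigned p = 1 and flagged.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    beta_a = matrix.values[list(group_a)].to_numpy(dtype=float)
    beta_b = matrix.values[list(group_b)].to_numpy(dtype=float)
    m_a = beta_to_m(beta_a)
    m_b = beta_to_m(beta_b)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant probes trigger scipy precision warnings; they are
        # handled below via the zero-variance flag
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(m_a, m_b, axis=1, equal_var=(variant == "student"), nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    zero_var = (np.nanvar(m_a, axis=1) == 0) & (np.nanvar(m_b, axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    t = np.where(zero_var | ~np.isfinite(t), 0.0, t)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    med_a = np.nanmedian(beta_a, axis=1)
    med_b = np.nanmedian(beta_b, axis=1)
    delta = np.abs(med_a - med_b)
    direction = np.where(med_a > med_b, "hyper", "hypo")
    called = (p_adj < alpha) & (delta > min_delta)
    return pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "t_statistic": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "delta_beta": delta,
            "direction": direction,
            "zero_variance": zero_var,
            "called": called,
        }
    ).set_index("probe_id", drop=False)


@dataclass
class DMBreakdown:
    """Cross-tabulations of called probes by annotation and platform specificity."""

    by_category: pd.DataFrame       # annotation_source x category x specificity counts (tidy)
    promoter_split: pd.DataFrame    # annotation_source x {Promoter, NonPromoter} x specificity
    transcript_counts: pd.DataFrame  # source_db -> distinct transcripts touching a called probe
    n_called: int


def _specificity(probe_ids: pd.Index, manifest_450k: pd.DataFrame | None) -> pd.Series:
    if manifest_450k is None:
        shared = pd.Series(False, index=probe_ids)
    else:
        shared = pd.Series(probe_ids.isin(set(manifest_450k["probe_id"])), index=probe_ids)
    return shared.map({True: "shared-with-450k", False: "850k-specific"})


def breakdown_dm(
    records: pd.DataFrame,
    encode_annotation: pd.DataFrame,
    illumina_categories: pd.Series,
    manifest_450k: pd.DataFrame | None = None,
    transcripts: pd.DataFrame | None = None,
) -> DMBreakdown:
    """Break called probes down by category, annotation source and 450k overlap.

    ``encode_annotation`` is the table from
    :func:`epicpipe.annotate.build_annotation`; ``illumina_categories`` the
    collapsed default annotation.  Probes absent from the 450k manifest are
    850k-specific.  Transcript counts tally distinct transcripts associated
    with at least one called probe, split by source database.
    """
    called = records.loc[records["called"], "probe_id"]
    enc = encode_annotation.set_index("probe_id")
    missing = [p for p in called if p not in enc.index or p not in illumina_categories.index]
    if missing:
        raise ValueError(f"called probes missing from an annotation: {missing[:5]}")
    specificity = _specificity(pd.Index(called), manifest_450k)
    rows = []
    prom_rows = []
    for source, cats in (
        ("ENCODE-based", enc.loc[called, "category"]),
        ("Illumina-default", illumina_categories.loc[called]),
    ):
        groups = promoter_nonpromoter(cats)
        for cat in CATEGORIES:
            for sp in ("850k-specific", "shared-with-450k"):
                n = int(((cats == cat) & (specificity == sp)).sum())
                rows.append((source, cat, sp, n))
        for grp in ("Promoter", "NonPromoter"):
            for sp in ("850k-specific", "shared-with-450k"):
                n = int(((groups == grp) & (specificity == sp)).sum())
                prom_rows.append((source, grp, sp, n))
    by_cat = pd.DataFrame(rows, columns=["annotation_source", "category", "specificity", "count"])
    prom = pd.DataFrame(prom_rows, columns=["annotation_source", "promoter_group", "specificity", "count"])

    tx_rows = []
    if transcripts is not None and len(called):
        associated: set[str] = set()
        sub = enc.loc[called]
        for col in ("promoter_transcripts", "erna_transcripts", "enhancer_targets", "gene_body_transcripts"):
            if col in sub.columns:
                for xs in sub[col]:
                    associated.update(x for x in xs if x != "unknown")
        for db, grp in transcripts.groupby("source_db"):
            tx_rows.append((db, int(grp["transcript_id"].isin(associated).sum())))
    tx = pd.DataFrame(tx_rows, columns=["source_db", "n_transcripts"])
    return DMBreakdown(by_cat, prom, tx, n_called=int(len(called)))
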