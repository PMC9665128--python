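"""ENCODE-chromatin-state probe re-annotation.

chromHMM states 1-3 (promoter flavours) and 4-7 (enhancer flavours) are
collapsed, per cell line, into maximal fused "super-regions"; every probe
then receives exactly one of five categories:

* ``Promoter``   - inside >= 1 Promoter super-region, never an Enhancer one;
* ``Enhancer``   - the symmetric case;
* ``Dual``       - a Promoter region in some cell line and an Enhancer in another;
* ``GeneBody``   - inside a transcript span [TSS, TTS] but no regulatory region;
* ``Intergenic`` - none of the above.

Transcripts attach to regions (and thence to probes) by TSS overlap:
a TSS inside a Promoter region is a promoter transcript; a *lncRNA* TSS
inside an Enhancer region defines an eRNA; enhancer target genes come from
an EnhancerAtlas-style table overlapped cell-line-wise with Enhancer
super-regions.  The module also collapses Illumina's default manifest
annotation onto the same five categories, for comparison.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CHROMHMM_STATES

__all__ = [
    "CATEGORIES",
    "state_kind",
    "build_super_regions",
    "classify_probes",
    "assign_cgi_context",
    "associate_tss",
    "map_enhancer_targets",
    "build_annotation",
    "collapse_illumina_default",
    "promoter_discrepancy_profile",
    "promoter_nonpromoter",
]

CATEGORIES = ("Enhancer", "Dual", "Promoter", "GeneBody", "Intergenic")

_PROMOTER_NUMS = {1, 2, 3}
_ENHANCER_NUMS = {4, 5, 6, 7}


def state_kind(state: str) -> str | None:
    """Map a chromHMM state label to 'Promoter', 'Enhancer' or None (ignored)."""
    if state not in CHROMHMM_STATES:
        raise ValueError(f"unknown chromHMM state label {state!r}")
    num = int(state.split("_", 1)[0])
    if num in _PROMOTER_NUMS:
        return "Promoter"
    if num in _ENHANCER_NUMS:
        return "Enhancer"
    return None


def build_super_regions(segments: pd.DataFrame, cell_line: str) -> pd.DataFrame:
    """Fuse promoter/enhancer chromHMM states into maximal super-regions.

    Consecutive (gap = 0) same-kind segments merge; an intervening ignored
    state breaks fusion because it occupies the intervening coordinates.
    Returns columns chrom, start, end, kind, cell_line, region_id with
    region_id = "{cell_line}:{kind}:{chrom}:{start}".
    """
    if len(segments) and not (segments["cell_line"] == cell_line).all():
        raise ValueError("segments from a different cell line supplied")
    seg = segments.sort_values(["chrom", "start"], kind="mergesort")
    prev_end = seg.groupby("chrom")["end"].shift()
    if (seg["start"] < prev_end.fillna(-1)).any():
        raise ValueError(f"overlapping chromHMM segments for cell line {cell_line}")
    seg = seg.assign(kind=seg["state"].map(state_kind)).dropna(subset=["kind"])
    rows = []
    cur = None  # [chrom, start, end, kind]
    for r in seg.itertuples():
        if cur is not None and r.chrom == cur[0] and r.kind == cur[3] and r.start == cur[2]:
            cur[2] = r.end
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [r.chrom, r.start, r.end, r.kind]
    if cur is not None:
        rows.append(tuple(cur))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind"])
    out["cell_line"] = cell_line
    out["region_id"] = [
        f"{cell_line}:{k}:{c}:{s}" for c, s, k in zip(out["chrom"], out["start"], out["kind"])
    ]
    return out


class _PointIndex:
    """Point-in-interval lookup over a non-overlapping interval set, per chromosome."""

    def __init__(self, df: pd.DataFrame, payload_col: str | None = None):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray | None]] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            payload = g[payload_col].to_numpy() if payload_col else None
            self._by_chrom[chrom] = (g["start"].to_numpy(), g["end"].to_numpy(), payload)

    def lookup(self, chroms: np.ndarray, pos0: np.ndarray):
        """Return (hit mask, payload array with None where no hit)."""
        hit = np.zeros(len(pos0), dtype=bool)
        payload = np.full(len(pos0), None, dtype=object)
        ser = pd.Series(np.arange(len(pos0)))
        for chrom, idx in ser.groupby(pd.Series(chroms)).groups.items():
            entry = self._by_chrom.get(chrom)
            if entry is None:
                continue
            starts, ends, pl = entry
            p = pos0[idx]
            j = np.searchsorted(starts, p, side="right") - 1
            ok = (j >= 0) & (p < ends[np.clip(j, 0, None)])
            hit[np.asarray(idx)[ok]] = True
            if pl is not None:
                payload[np.asarray(idx)[ok]] = pl[j[ok]]
        return hit, payload


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge possibly-overlapping intervals (chrom/start/end) into a disjoint set."""
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        cs = ce = None
        for r in grp.itertuples():
            if cs is None:
                cs, ce = r.start, r.end
            elif r.start <= ce:
                ce = max(ce, r.end)
            else:
                rows.append((chrom, cs, ce))
                cs, ce = r.start, r.end
        if cs is not None:
            rows.append((chrom, cs, ce))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def classify_probes(
    probes: pd.DataFrame,
    regions: pd.DataFrame,
    transcripts: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign the five-category classification and per-cell-line states.

    ``regions`` is the concatenation of super-regions over all cell lines.
    Returns ``(categories, states)`` where ``states`` is a probe x cell-line
    frame of {"Promoter", "Enhancer", "none"}.
    """
    if probes["pos0"].isna().any():
        bad = probes.loc[probes["pos0"].isna(), "probe_id"].iloc[0]
        raise ValueError(f"probe {bad} has no mapped position")
    chroms = probes["chrom"].to_numpy()
    pos0 = probes["pos0"].to_numpy()
    cell_lines = sorted(regions["cell_line"].unique()) if len(regions) else []
    states = pd.DataFrame("none", index=probes["probe_id"], columns=cell_lines)
    for cl in cell_lines:
        sub = regions[regions["cell_line"] == cl]
        for kind in ("Promoter", "Enhancer"):
            idx = _PointIndex(sub[sub["kind"] == kind])
            hit, _ = idx.lookup(chroms, pos0)
            states.loc[hit, cl] = kind  # promoter/enhancer regions of one cell line are disjoint
    any_prom = (states == "Promoter").any(axis=1).to_numpy()
    any_enh = (states == "Enhancer").any(axis=1).to_numpy()
    if len(transcripts):
        body_idx = _PointIndex(merge_intervals(transcripts[["chrom", "start", "end"]]))
        in_body, _ = body_idx.lookup(chroms, pos0)
    else:
        in_body = np.zeros(len(probes), dtype=bool)
    cat = np.where(
        any_prom & any_enh,
        "Dual",
        np.where(any_prom, "Promoter", np.where(any_enh, "Enhancer", np.where(in_body, "GeneBody", "Intergenic"))),
    )
    return pd.Series(cat, index=probes["probe_id"], name="category"), states


def assign_cgi_context(probes: pd.DataFrame, islands: pd.DataFrame, flank: int = 2000) -> pd.Series:
    """Classify each probe as Island / Shore / OpenSea.

    Shores are the +/- ``flank`` bp island flanks (clipped at 0); island
    membership takes precedence when flanks of adjacent islands overlap.
    """
    chroms = probes["chrom"].to_numpy()
    pos0 = probes["pos0"].to_numpy()
    if len(islands) == 0:
        return pd.Series("OpenSea", index=probes["probe_id"], name="cgi_context")
    merged = merge_intervals(islands)
    in_island, _ = _PointIndex(merged).lookup(chroms, pos0)
    flanks = merged.assign(
        start=np.maximum(merged["start"] - flank, 0), end=merged["end"] + flank
    )
    in_flank, _ = _PointIndex(merge_intervals(flanks)).lookup(chroms, pos0)
    ctx = np.where(in_island, "Island", np.where(in_flank, "Shore", "OpenSea"))
    return pd.Series(ctx, index=probes["probe_id"], name="cgi_context")


def associate_tss(transcripts: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Associate transcripts with regulatory regions by TSS overlap.

    A TSS inside a Promoter super-region yields a TSS-promoter association;
    a lncRNA TSS inside an Enhancer super-region yields an eRNA association
    (coding/other TSSs in enhancers yield nothing).  Returns columns
    transcript_id, region_id, association_type, cell_line.
    """
    rows = []
    if len(transcripts) == 0 or len(regions) == 0:
        return pd.DataFrame(columns=["transcript_id", "region_id", "association_type", "cell_line"])
    tchrom = transcripts["chrom"].to_numpy()
    tss0 = transcripts["tss0"].to_numpy()
    for (cl, kind), sub in regions.groupby(["cell_line", "kind"], sort=False):
        idx = _PointIndex(sub, payload_col="region_id")
        hit, rid = idx.lookup(tchrom, tss0)
        for i in np.flatnonzero(hit):
            t = transcripts.iloc[i]
            if kind == "Promoter":
                rows.append((t["transcript_id"], rid[i], "TSS-promoter", cl))
            elif t["biotype"] == "lncRNA":
                rows.append((t["transcript_id"], rid[i], "eRNA", cl))
    return pd.DataFrame(rows, columns=["transcript_id", "region_id", "association_type", "cell_line"])


def map_enhancer_targets(regions: pd.DataFrame, atlas: pd.DataFrame) -> tuple[pd.DataFrame, set[str]]:
    """Attach EnhancerAtlas target transcripts to Enhancer super-regions.

    Overlap must be strictly positive (half-open intervals) and within the
    same cell line.  Returns the association table plus the ids of Enhancer
    super-regions left with an unknown target.
    """
    enh = regions[regions["kind"] == "Enhancer"]
    known_cls = set(enh["cell_line"].unique())
    bad = set(atlas["cell_line"].unique()) - known_cls
    if bad:
        warnings.warn(f"enhancer atlas cell lines absent from ENCODE set ignored: {sorted(bad)}")
        atlas = atlas[atlas["cell_line"].isin(known_cls)]
    rows = []
    hit_regions: set[str] = set()
    for (cl, chrom), sub in enh.groupby(["cell_line", "chrom"], sort=False):
        a = atlas[(atlas["cell_line"] == cl) & (atlas["chrom"] == chrom)]
        if len(a) == 0:
            continue
        tree = IntervalTree()
        for r in a.itertuples():
            tree.addi(r.start, r.end, r.target_transcript)
        for r in sub.itertuples():
            for iv in tree.overlap(r.start, r.end):
                rows.append((iv.data, r.region_id, "enhancer-target", cl))
                hit_regions.add(r.region_id)
    assoc = pd.DataFrame(rows, columns=["transcript_id", "region_id", "association_type", "cell_line"])
    unknown = set(enh["region_id"]) - hit_regions
    return assoc, unknown


def _probe_region_ids(probes: pd.DataFrame, regions: pd.DataFrame) -> dict[str, list[str]]:
    """Map each probe id to the ids of all super-regions containing it."""
    out: dict[str, list[str]] = defaultdict(list)
    chroms = probes["chrom"].to_numpy()
    pos0 = probes["pos0"].to_numpy()
    pids = probes["probe_id"].to_numpy()
    for (_cl, _kind), sub in regions.groupby(["cell_line", "kind"], sort=False):
        hit, rid = _PointIndex(sub, payload_col="region_id").lookup(chroms, pos0)
        for i in np.flatnonzero(hit):
            out[pids[i]].append(rid[i])
    return out


def build_annotation(
    probes: pd.DataFrame,
    regions: pd.DataFrame,
    transcripts: pd.DataFrame,
    islands: pd.DataFrame | None = None,
    atlas: pd.DataFrame | None = None,
    shore_flank: int = 2000,
) -> pd.DataFrame:
    """Produce the full per-probe annotation table.

    Columns: probe_id, chrom, position, category, cgi_context, one
    ``state_<cell line>`` column per cell line, and the four transcript
    association lists.  Probes inside Enhancer super-regions whose regions
    all lack an EnhancerAtlas target get ``["unknown"]`` as target list.
    """
    categories, states = classify_probes(probes, regions, transcripts)
    if islands is None:
        islands = pd.DataFrame(columns=["chrom", "start", "end"])
    cgi = assign_cgi_context(probes, islands, flank=shore_flank)

    tss_assoc = associate_tss(transcripts, regions)
    if atlas is not None and len(atlas):
        target_assoc, _unknown = map_enhancer_targets(regions, atlas)
    else:
        target_assoc = pd.DataFrame(columns=["transcript_id", "region_id", "association_type", "cell_line"])

    by_region: dict[str, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    for t in pd.concat([tss_assoc, target_assoc], ignore_index=True).itertuples():
        by_region[t.region_id][t.association_type].add(t.transcript_id)

    probe_regions = _probe_region_ids(probes, regions)

    # gene-body association: all transcripts whose span contains the probe point
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in transcripts.groupby("chrom", sort=False):
        tree = IntervalTree()
        for r in grp.itertuples():
            tree.addi(r.start, r.end, r.transcript_id)
        trees[chrom] = tree

    records = []
    for r in probes.itertuples():
        prom_tx: set = set()
        erna_tx: set = set()
        targets: set = set()
        in_enhancer_region = False
        for rid in probe_regions.get(r.probe_id, ()):  # region ids carry the kind
            kind = rid.split(":")[1]
            assoc = by_region.get(rid, {})
            if kind == "Promoter":
                prom_tx |= assoc.get("TSS-promoter", set())
            else:
                in_enhancer_region = True
                erna_tx |= assoc.get("eRNA", set())
                targets |= assoc.get("enhancer-target", set())
        tree = trees.get(r.chrom)
        body_tx = sorted(iv.data for iv in tree[r.pos0]) if tree is not None else []
        target_list = sorted(targets) if targets else (["unknown"] if in_enhancer_region else [])
        records.append(
            {
                "probe_id": r.probe_id,
                "chrom": r.chrom,
                "position": r.position,
                "category": categories.loc[r.probe_id],
                "cgi_context": cgi.loc[r.probe_id],
                "promoter_transcripts": sorted(prom_tx),
                "erna_transcripts": sorted(erna_tx),
                "enhancer_targets": target_list,
                "gene_body_transcripts": body_tx,
            }
        )
    out = pd.DataFrame.from_records(records)
    for cl in states.columns:
        out[f"state_{cl}"] = states[cl].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Illumina default annotation collapse

_PROMOTER_TERMS = {"TSS1500", "TSS200", "1stExon", "5'UTR"}
_BODY_TERMS = {"Body", "3'UTR"}
_KNOWN_TERMS = _PROMOTER_TERMS | _BODY_TERMS | {"ExonBnd"}

_GROUP_COLS = ("UCSC_RefGene_Group", "GencodeCompV12_Group")
_ENHANCER_COLS = ("Phantom4_Enhancers", "Phantom5_Enhancers", "450k_Enhancer", "Enhancer")


def _split_terms(value) -> set[str]:
    if not isinstance(value, str) or not value:
        return set()
    return {t.strip() for t in value.split(";") if t.strip()}


def collapse_illumina_default(probes: pd.DataFrame) -> pd.Series:
    """Collapse Illumina's default manifest annotation onto the five categories.

    Gene-group terms TSS1500/TSS200/1stExon/5'UTR imply Promoter; Body/3'UTR
    imply GeneBody.  Any non-empty FANTOM/450k enhancer column implies
    Enhancer, upgraded to Dual for probes that are also Promoter.  The
    remainder is Intergenic.  Unrecognized group terms are warned about and
    ignored.
    """
    cats = []
    unknown_terms: set[str] = set()
    group_cols = [c for c in _GROUP_COLS if c in probes.columns]
    enh_cols = [c for c in _ENHANCER_COLS if c in probes.columns]
    for r in probes.itertuples():
        terms: set[str] = set()
        for c in group_cols:
            terms |= _split_terms(getattr(r, c, ""))
        unknown_terms |= terms - _KNOWN_TERMS
        terms &= _KNOWN_TERMS
        is_prom = bool(terms & _PROMOTER_TERMS)
        is_body = bool(terms & _BODY_TERMS)
        is_enh = any(str(getattr(r, c, "") or "").strip() not in ("", "FALSE", "False", "0") for c in enh_cols)
        if is_enh and is_prom:
            cats.append("Dual")
        elif is_enh:
            cats.append("Enhancer")
        elif is_prom:
            cats.append("Promoter")
        elif is_body:
            cats.append("GeneBody")
        else:
            cats.append("Intergenic")
    if unknown_terms:
        warnings.warn(f"unrecognized gene-group terms ignored: {sorted(unknown_terms)}")
    return pd.Series(cats, index=probes["probe_id"], name="illumina_category")


def promoter_nonpromoter(categories: pd.Series) -> pd.Series:
    """Collapse the five categories onto Promoter / NonPromoter.

    Promoter and Dual count as Promoter; Enhancer, GeneBody and Intergenic
    as NonPromoter.
    """
    values = categories.map(lambda c: "Promoter" if c in ("Promoter", "Dual") else "NonPromoter")
    return values.rename("promoter_group")


def signed_tss_distance(
    probes: pd.DataFrame, tx_ids_per_probe: pd.Series, transcripts: pd.DataFrame
) -> pd.Series:
    """Signed strand-aware distance from each probe to its nearest associated TSS.

    Negative = upstream of the TSS in transcript orientation.  Probes whose
    association list is empty or references unknown transcripts get NaN.
    """
    tx = transcripts.set_index("transcript_id")
    out = np.full(len(probes), np.nan)
    for i, r in enumerate(probes.itertuples()):
        ids = tx_ids_per_probe.get(r.probe_id, [])
        best = None
        for tid in ids:
            if tid not in tx.index:
                continue
            t = tx.loc[tid]
            d = r.pos0 - t["tss0"] if t["strand"] == "+" else t["tss0"] - r.pos0
            if best is None or abs(d) < abs(best):
                best = d
        if best is not None:
            out[i] = best
    return pd.Series(out, index=probes["probe_id"], name="tss_distance")


def promoter_discrepancy_profile(
    probes: pd.DataFrame,
    illumina_categories: pd.Series,
    encode_categories: pd.Series,
    tx_ids_per_probe: pd.Series,
    transcripts: pd.DataFrame,
    bin_width: int = 200,
) -> tuple[pd.DataFrame, int]:
    """Per-TSS-distance-bin discordance between Illumina and ENCODE promoter calls.

    Restricted to probes Illumina classifies as Promoter.  A probe is
    discordant when its ENCODE category is neither Promoter nor Dual.
    Returns (profile, n_excluded) where the profile has one row per
    ``bin_width``-bp distance bin with the percentage of discordant probes,
    and n_excluded counts Illumina-promoter probes with no usable TSS.
    """
    sel = probes[illumina_categories.reindex(probes["probe_id"]).to_numpy() == "Promoter"]
    dist = signed_tss_distance(sel, tx_ids_per_probe, transcripts)
    n_excluded = int(dist.isna().sum())
    ok = dist.dropna()
    if len(ok) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n", "n_discordant", "pct_discordant"]), n_excluded
    bins = (np.floor(ok.to_numpy() / bin_width) * bin_width).astype(int)
    discord = ~encode_categories.reindex(ok.index).isin(["Promoter", "Dual"])
    df = pd.DataFrame({"bin_left": bins, "discordant": discord.to_numpy()})
    grp = df.groupby("bin_left")["discordant"].agg(["size", "sum"]).reset_index()
    grp.columns = ["bin_left", "n", "n_discordant"]
    grp["bin_right"] = grp["bin_left"] + bin_width
    grp["pct_discordant"] = 100.0 * grp["n_discordant"] / grp["n"]
    return grp[["bin_left", "bin_right", "n", "n_discordant", "pct_discordant"]], n_excluded
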