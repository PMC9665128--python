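"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are normalized at the boundary to a single internal
convention: 0-based, half-open intervals and 0-based points.  Columns named
``position`` keep the 1-based convention of the source (Illumina MAPINFO,
GFF/GTF, RRBS calls); the matching internal point is ``pos0 = position - 1``.
Chromosome names are normalized to the ``chr``-prefixed dialect.  Gzip is
supported transparently on every reader and writer (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "BetaMatrix",
    "CHROMHMM_STATES",
    "read_manifest",
    "read_chromatin_bed",
    "read_bed_intervals",
    "read_transcripts",
    "combine_transcripts",
    "read_rrbs",
    "write_rrbs",
    "read_enhancer_atlas",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_id_list",
    "write_platform_annotation",
    "read_platform_annotation",
]


class FormatError(ValueError):
    """An input file does not conform to its declared dialect."""


#: The fixed 15-label chromHMM vocabulary (ENCODE HMM genome segmentation).
CHROMHMM_STATES = (
    "1_Active_Promoter",
    "2_Weak_Promoter",
    "3_Poised_Promoter",
    "4_Strong_Enhancer",
    "5_Strong_Enhancer",
    "6_Weak_Enhancer",
    "7_Weak_Enhancer",
    "8_Insulator",
    "9_Txn_Transition",
    "10_Txn_Elongation",
    "11_Weak_Txn",
    "12_Repressed",
    "13_Heterochrom/lo",
    "14_Repetitive/CNV",
    "15_Repetitive/CNV",
)

SEX_CHROMOSOMES = frozenset({"chrX", "chrY"})


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed dialect."""
    name = str(name).strip()
    if not name:
        raise FormatError("empty chromosome name")
    return name if name.startswith("chr") else "chr" + name


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass
class BetaMatrix:
    """Beta values (probes x samples), optional detection p-values and sample metadata.

    ``values`` rows are probe ids, columns are sample ids; entries are beta
    fractions in [0, 1] or NaN for missing.  ``detection_p`` (if present)
    is aligned cell-for-cell.  ``sample_meta`` is indexed by sample id and
    may carry ``group`` and ``technology`` columns.  ``method`` tags the
    normalization provenance ("RAW" for unnormalized data).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None
    method: str = "RAW"

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate probe ids in beta matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in beta matrix")
        arr = v.to_numpy(dtype=float)
        bad = np.isfinite(arr) & ((arr < 0) | (arr > 1))
        if bad.any():
            raise ValueError("beta values outside [0, 1]")
        if self.detection_p is not None:
            p = self.detection_p
            if not (p.index.equals(v.index) and p.columns.equals(v.columns)):
                raise ValueError("detection_p not aligned with values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        keep = self.values.index.isin(set(probe_ids))
        return BetaMatrix(
            self.values.loc[keep],
            None if self.detection_p is None else self.detection_p.loc[keep],
            self.sample_meta,
            self.method,
        )

    def with_values(self, values: pd.DataFrame, method: str | None = None) -> "BetaMatrix":
        return BetaMatrix(values, self.detection_p, self.sample_meta, method or self.method)


# ---------------------------------------------------------------------------
# Illumina manifests

_REQUIRED_MANIFEST_COLS = ("IlmnID", "CHR", "MAPINFO", "Infinium_Design_Type")

#: Default-annotation columns preserved for the Illumina category collapse.
MANIFEST_ANNOTATION_COLS = (
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "GencodeCompV12_Group",
    "Phantom4_Enhancers",
    "Phantom5_Enhancers",
    "450k_Enhancer",
    "Enhancer",
)


def read_manifest(path, platform: str) -> pd.DataFrame:
    """Read an Illumina array manifest CSV (450k or 850k dialect).

    The manifest carries a free-length header block, an ``[Assay]`` section
    with one row per probe and (usually) a trailing ``[Controls]`` section,
    which is excluded.  Returns a DataFrame with normalized columns
    ``probe_id, chrom, position (1-based), pos0, design_type, platform,
    cross_reactive, snp_overlap`` plus any default-annotation columns
    present in the file.
    """
    if platform not in ("450k", "850k"):
        raise ValueError(f"unknown platform {platform!r}")
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    assay_at = None
    for i, line in enumerate(lines):
        if line.split(",")[0].strip() == "[Assay]":
            assay_at = i
            break
    if assay_at is None:
        raise FormatError("no [Assay] section found in manifest")
    end = len(lines)
    for j in range(assay_at + 1, len(lines)):
        if lines[j].startswith("["):
            end = j
            break
    body = "\n".join(lines[assay_at + 1 : end])
    df = pd.read_csv(io.StringIO(body), dtype=str, keep_default_na=False)
    for col in _REQUIRED_MANIFEST_COLS:
        if col not in df.columns:
            raise FormatError(f"manifest missing required column {col!r}")
    bad_type = ~df["Infinium_Design_Type"].isin(["I", "II"])
    if bad_type.any():
        pid = df.loc[bad_type, "IlmnID"].iloc[0]
        raise FormatError(f"probe {pid}: invalid Infinium_Design_Type")
    mapinfo = pd.to_numeric(df["MAPINFO"], errors="coerce")
    bad = mapinfo.isna()
    if bad.any():
        pid = df.loc[bad, "IlmnID"].iloc[0]
        raise FormatError(f"probe {pid}: non-numeric MAPINFO {df.loc[bad, 'MAPINFO'].iloc[0]!r}")
    out = pd.DataFrame(
        {
            "probe_id": df["IlmnID"],
            "chrom": df["CHR"].map(normalize_chrom),
            "position": mapinfo.astype(int),
            "design_type": df["Infinium_Design_Type"],
            "platform": platform,
        }
    )
    out["pos0"] = out["position"] - 1
    out["cross_reactive"] = False
    out["snp_overlap"] = False
    for col in MANIFEST_ANNOTATION_COLS:
        if col in df.columns:
            out[col] = df[col]
    if out["probe_id"].duplicated().any():
        dup = out.loc[out["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe id in manifest: {dup}")
    return out


def read_probe_id_list(path) -> set[str]:
    """Read a plain-text probe-id exclusion list (one id per line)."""
    with _open_text(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def flag_probes(probes: pd.DataFrame, cross_reactive=(), snp=()) -> pd.DataFrame:
    """Return a copy of the probe table with exclusion-list flags set."""
    out = probes.copy()
    out["cross_reactive"] = out["probe_id"].isin(set(cross_reactive))
    out["snp_overlap"] = out["probe_id"].isin(set(snp))
    return out


# ---------------------------------------------------------------------------
# BED tracks

def read_chromatin_bed(path, cell_line: str) -> pd.DataFrame:
    """Read a chromHMM segmentation BED for one cell line.

    BED is 0-based half-open; the name field must carry one of the 15
    chromHMM state labels.  Returns columns chrom, start, end, state,
    cell_line.
    """
    rows = []
    known = set(CHROMHMM_STATES)
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected >= 4 BED fields")
            chrom, start, end, state = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start ({start}, {end})")
            if state not in known:
                raise FormatError(f"{path}:{ln}: unknown chromHMM state label {state!r}")
            rows.append((normalize_chrom(chrom), start, end, state))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    df["cell_line"] = cell_line
    return df


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a plain interval BED (e.g. UCSC CpG islands): chrom, start, end."""
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED fields")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{ln}: end <= start")
            rows.append((normalize_chrom(parts[0]), start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Transcripts (LNCipedia GFF / Ensembl GTF)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF_ATTR = re.compile(r"(\w+)=([^;]*)")

_LNC_BIOTYPES = {"lncRNA", "lincRNA", "antisense", "sense_intronic", "sense_overlapping"}


def _parse_attributes(attr: str) -> dict[str, str]:
    if "=" in attr.split(";")[0]:
        return dict(_GFF_ATTR.findall(attr))
    return dict(_GTF_ATTR.findall(attr))


def _map_biotype(raw: str, source_db: str) -> str:
    if source_db == "LNCipedia":
        return "lncRNA"
    if raw == "protein_coding":
        return "coding"
    if raw in _LNC_BIOTYPES:
        return "lncRNA"
    return "other-noncoding"


def read_transcripts(path, source_db: str) -> pd.DataFrame:
    """Read transcript models from a GFF (LNCipedia) or GTF (Ensembl) file.

    Only ``transcript`` features are used.  GFF/GTF 1-based inclusive
    [a, b] coordinates map to internal [a-1, b).  TSS/TTS are derived
    strand-aware (TSS = 5' end) and kept 1-based, with ``tss0`` the
    internal point.  All LNCipedia entries are lncRNA; the Ensembl biotype
    attribute maps onto {coding, lncRNA, other-noncoding}.
    """
    if source_db not in ("LNCipedia", "Ensembl"):
        raise ValueError(f"unknown source_db {source_db!r}")
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{ln}: expected 9 GFF/GTF fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = parts[:9]
            if feature != "transcript":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: missing or invalid strand {strand!r}")
            a, b = int(start), int(end)
            if b < a:
                raise FormatError(f"{path}:{ln}: end < start")
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id") or attrs.get("ID")
            if not tid:
                raise FormatError(f"{path}:{ln}: no transcript id attribute")
            biotype = _map_biotype(attrs.get("transcript_biotype", attrs.get("biotype", "")), source_db)
            tss, tts = (a, b) if strand == "+" else (b, a)
            rows.append((tid, source_db, biotype, normalize_chrom(chrom), a - 1, b, strand, tss, tts))
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "source_db", "biotype", "chrom", "start", "end", "strand", "tss", "tts"],
    )
    df["tss0"] = df["tss"] - 1
    df["tts0"] = df["tts"] - 1
    return df


def combine_transcripts(
    lncipedia: pd.DataFrame, ensembl: pd.DataFrame, duplicates: set[str] | None = None
) -> pd.DataFrame:
    """Merge the two transcript sources, keeping the LNCipedia version of duplicates.

    ``duplicates`` is an optional explicit set of Ensembl transcript ids known
    to duplicate an LNCipedia entry; ids present in both tables are dropped
    from the Ensembl side regardless.
    """
    drop = set(duplicates or ()) | set(lncipedia["transcript_id"])
    ens = ensembl[~ensembl["transcript_id"].isin(drop)]
    return pd.concat([lncipedia, ens], ignore_index=True)


# ---------------------------------------------------------------------------
# RRBS per-CpG methylation calls

RRBS_DIALECTS = ("bedgraph-cov", "encode")


def read_rrbs(path, dialect: str = "bedgraph-cov") -> pd.DataFrame:
    """Read per-CpG RRBS methylation calls.

    Both dialects are headerless, whitespace-delimited, one site per row:
    ``chrom  position(1-based)  strand  coverage  methylation``.  In the
    ``bedgraph-cov`` dialect methylation is a percentage (0-100); in the
    ``encode`` dialect it is already a fraction (0-1).  ``meth_fraction``
    is normalized to [0, 1]; sites with coverage 0 are retained with an
    undefined (NaN) fraction.
    """
    if dialect not in RRBS_DIALECTS:
        raise ValueError(f"unknown RRBS dialect {dialect!r}")
    scale = 100.0 if dialect == "bedgraph-cov" else 1.0
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: expected 5 fields")
            chrom, pos, strand, cov, meth = parts[:5]
            cov = int(cov)
            if cov < 0:
                raise FormatError(f"{path}:{ln}: negative coverage {cov}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{ln}: invalid strand {strand!r}")
            if cov == 0:
                frac = np.nan
            else:
                frac = float(meth.rstrip("%")) / scale
                if not 0.0 <= frac <= 1.0:
                    raise FormatError(f"{path}:{ln}: methylation fraction {frac} outside [0, 1]")
            rows.append((normalize_chrom(chrom), int(pos), strand, cov, frac))
    df = pd.DataFrame(rows, columns=["chrom", "position", "strand", "coverage", "meth_fraction"])
    dup = df.duplicated(subset=["chrom", "position", "strand"], keep=False)
    if dup.any():
        sites = df.loc[dup, ["chrom", "position", "strand"]].drop_duplicates()
        listing = "; ".join(f"{r.chrom}:{r.position}({r.strand})" for r in sites.head(10).itertuples())
        raise FormatError(f"duplicate RRBS sites: {listing}")
    df["pos0"] = df["position"] - 1
    return df


def write_rrbs(sites: pd.DataFrame, path, dialect: str = "bedgraph-cov") -> None:
    """Write RRBS sites back to a headerless 5-column table (inverse of read_rrbs)."""
    if dialect not in RRBS_DIALECTS:
        raise ValueError(f"unknown RRBS dialect {dialect!r}")
    scale = 100.0 if dialect == "bedgraph-cov" else 1.0
    with _open_text(path, "wt") as fh:
        for r in sites.itertuples():
            meth = "0" if not np.isfinite(r.meth_fraction) else repr(r.meth_fraction * scale)
            fh.write(f"{r.chrom}\t{r.position}\t{r.strand}\t{r.coverage}\t{meth}\n")


# ---------------------------------------------------------------------------
# Enhancer atlas tables

def read_enhancer_atlas(path) -> pd.DataFrame:
    """Read an enhancer -> target-transcript table.

    Tab-delimited with header: cell_line, chrom, start (0-based), end,
    target_transcript.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_line": str, "chrom": str, "target_transcript": str})
    required = {"cell_line", "chrom", "start", "end", "target_transcript"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"enhancer atlas missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["end"] <= df["start"]).any():
        raise FormatError("enhancer atlas contains empty or inverted intervals")
    return df


# ---------------------------------------------------------------------------
# Beta matrices

def read_beta_matrix(path, detection_p_path=None, sample_meta_path=None, method: str = "RAW") -> BetaMatrix:
    """Read a probes x samples beta matrix TSV (first column = probe id)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    detp = None
    if detection_p_path is not None:
        detp = pd.read_csv(detection_p_path, sep="\t", index_col=0)
        detp = detp.reindex(index=values.index, columns=values.columns)
    meta = None
    if sample_meta_path is not None:
        meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
    return BetaMatrix(values, detp, meta, method)


def write_beta_matrix(matrix: BetaMatrix, path, detection_p_path=None) -> None:
    with _open_text(path, "wt") as fh:
        matrix.values.to_csv(fh, sep="\t", index_label="probe_id")
    if detection_p_path is not None:
        if matrix.detection_p is None:
            raise ValueError("matrix has no detection p-value layer")
        with _open_text(detection_p_path, "wt") as fh:
            matrix.detection_p.to_csv(fh, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Platform annotation (GEO-platform-style tab-delimited output)

_LIST_COLS = ("promoter_transcripts", "erna_transcripts", "enhancer_targets", "gene_body_transcripts")


def write_platform_annotation(records: pd.DataFrame, path) -> None:
    """Write the per-probe annotation table as a GEO-platform-style TSV.

    One row per probe, sorted by (chrom, position, probe id); list-valued
    fields joined with ";"; gzip-compressed when the path ends in ``.gz``.
    """
    if records["probe_id"].duplicated().any():
        dup = records.loc[records["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe id in annotation: {dup}")
    out = records.copy()
    for col in _LIST_COLS:
        if col in out.columns:
            out[col] = out[col].map(lambda xs: ";".join(xs) if isinstance(xs, (list, tuple)) else (xs or ""))
    out = out.sort_values(["chrom", "position", "probe_id"], kind="mergesort")
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def read_platform_annotation(path) -> pd.DataFrame:
    """Read back a platform annotation TSV written by :func:`write_platform_annotation`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _LIST_COLS:
        if col in df.columns:
            df[col] = df[col].map(lambda s: s.split(";") if s else [])
    if "position" in df.columns:
        df["position"] = df["position"].astype(int)
    return df
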