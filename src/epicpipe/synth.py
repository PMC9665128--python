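"""Seeded synthetic fixtures with the statistical structure of the real inputs.

The generator emits toy genomes (chromHMM tracks for the nine ENCODE cell
lines, CpG islands, LNCipedia/Ensembl transcript models, an enhancer-target
atlas, Illumina-style manifests), beta matrices with the Infinium type I /
type II bias planted on the M scale (type II peak compression plus additive
replicate noise), and RRBS calls with negative-binomial coverage.  Every
file parses through :mod:`epicpipe.io_formats`, and a GroundTruth table
records the planted truth so recovery can be tested.

Defaults emulate the observed behaviour of real arrays: type I density
peaks near M = +/-4.5 (beta ~ 0.044/0.956), type II peaks compressed by
c = 0.6, and replicate noise calibrated so the median replicate beta-scale
SD is about 0.013 for type I and 0.034 for type II probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate
from .io_formats import CHROMHMM_STATES, BetaMatrix

__all__ = ["CELL_LINES", "SimConfig", "gen_genome_fixtures", "gen_beta_matrix", "gen_rrbs"]

#: The nine ENCODE cell lines with chromHMM segmentations.
CELL_LINES = ("HMEC", "HSMM", "K562", "NHEK", "NHLF", "HEPG2", "HUVEC", "HESC", "GM12878")

# default chromHMM state frequencies: ~9% promoter, ~16% enhancer states
_DEFAULT_STATE_PROBS = (
    0.04, 0.03, 0.02,          # 1-3 promoter flavours
    0.04, 0.04, 0.04, 0.04,    # 4-7 enhancer flavours
    0.05, 0.05, 0.10, 0.10, 0.15, 0.20, 0.05, 0.05,  # 8-15 ignored states
)


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with deterministic-seed semantics.

    The same seed and config always produce byte-identical fixtures.
    """

    seed: int = 0
    genome: dict = field(default_factory=lambda: {"chr1": 60_000, "chr2": 40_000, "chrX": 20_000})
    n_probes: int = 2_000
    fraction_type_ii: float = 0.84
    # two-peak mixture of true methylation states on the M scale
    peak_unmeth: float = -4.5
    peak_meth: float = 4.5
    peak_sd: float = 0.5
    compression: float = 0.6          # type II M-scale peak compression c
    noise_sd_type_i: float = 0.585    # replicate noise SD, M scale
    noise_sd_type_ii: float = 0.52
    hetero_b: float = 0.0             # SD inflation per unit |true M|
    noise_scale: str = "M"            # "M" or "beta"
    beta_noise_sd: float = 0.03       # replicate noise SD when noise_scale == "beta"
    dm_fraction: float = 0.05
    dm_delta_beta: float = 0.3
    # DMC probes carry intermediate methylation (a beta shift of dm_delta_beta
    # is only meaningful away from the saturated extremes of the logit scale)
    dm_beta_range: tuple = (0.1, 0.6)
    detection_fail_rate: float = 0.001
    rrbs_n_sites: int = 3_000
    rrbs_mean_coverage: float = 30.0
    rrbs_dispersion: float = 3.0
    rrbs_missing_rate: float = 0.10
    rrbs_strand_divergence_rate: float = 0.05
    n_cell_lines: int = 9
    n_transcripts: int = 300
    n_islands: int = 40
    segment_mean_length: int = 800
    state_probs: tuple = _DEFAULT_STATE_PROBS

    def __post_init__(self):
        for name in ("fraction_type_ii", "dm_fraction", "detection_fail_rate",
                     "rrbs_missing_rate", "rrbs_strand_divergence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.compression <= 1.0:
            raise ValueError("compression must be in (0, 1]")
        lo, hi = self.dm_beta_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("dm_beta_range must satisfy 0 < low < high < 1")
        if any(length <= 0 for length in self.genome.values()):
            raise ValueError("chromosome lengths must be positive")
        if len(self.state_probs) != 15 or abs(sum(self.state_probs) - 1.0) > 1e-9:
            raise ValueError("state_probs must be 15 probabilities summing to 1")
        if self.noise_scale not in ("M", "beta"):
            raise ValueError("noise_scale must be 'M' or 'beta'")
        if not 1 <= self.n_cell_lines <= len(CELL_LINES):
            raise ValueError(f"n_cell_lines must be in [1, {len(CELL_LINES)}]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "state_probs" in raw:
            raw["state_probs"] = tuple(raw["state_probs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["state_probs"] = list(d["state_probs"])
        return d


def _sigmoid_beta(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-m))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


# ---------------------------------------------------------------------------
# genome-level fixtures

def _tile_chromatin(rng, config: SimConfig) -> pd.DataFrame:
    rows = []
    states = np.array(CHROMHMM_STATES)
    probs = np.asarray(config.state_probs, dtype=float)
    for chrom, length in config.genome.items():
        pos = 0
        while pos < length:
            seg_len = int(rng.exponential(config.segment_mean_length)) + 100
            end = min(pos + seg_len, length)
            state = rng.choice(states, p=probs)
            rows.append((chrom, pos, end, state))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def brute_force_category(
    chrom: str, pos0: int, segments_by_cell_line: dict[str, pd.DataFrame], transcripts: pd.DataFrame
) -> str:
    """Reference per-position classification by direct scan of the raw tracks.

    Intentionally naive: walks every chromHMM segment of every cell line and
    every transcript span, without interval fusion or indexing.  Membership
    in a fused super-region equals membership in one of its member states,
    so this is an independent route to the five-category call.
    """
    any_prom = any_enh = False
    for seg in segments_by_cell_line.values():
        for r in seg.itertuples():
            if r.chrom == chrom and r.start <= pos0 < r.end:
                kind = annotate.state_kind(r.state)
                if kind == "Promoter":
                    any_prom = True
                elif kind == "Enhancer":
                    any_enh = True
    if any_prom and any_enh:
        return "Dual"
    if any_prom:
        return "Promoter"
    if any_enh:
        return "Enhancer"
    for t in transcripts.itertuples():
        if t.chrom == chrom and t.start <= pos0 < t.end:
            return "GeneBody"
    return "Intergenic"


def _place_transcripts(rng, config: SimConfig, regions: pd.DataFrame) -> pd.DataFrame:
    chroms = list(config.genome)
    lengths = config.genome
    rows = []
    prom = regions[regions["kind"] == "Promoter"].reset_index(drop=True)
    enh = regions[regions["kind"] == "Enhancer"].reset_index(drop=True)
    n_lnc = int(round(config.n_transcripts * 0.4))
    for i in range(config.n_transcripts):
        is_lnc = i < n_lnc
        if is_lnc:
            source, tid, biotype = "LNCipedia", f"lnc-TX{i:04d}", "lncRNA"
        else:
            source = "Ensembl"
            tid = f"ENST{i:08d}"
            u = rng.random()
            biotype = "coding" if u < 0.7 else ("lncRNA" if u < 0.9 else "other-noncoding")
        # place the TSS: half in regulatory regions (lncRNAs favour enhancers -> eRNAs)
        u = rng.random()
        pool = None
        if u < 0.5:
            pool = enh if (is_lnc and rng.random() < 0.5 and len(enh)) else (prom if len(prom) else None)
        if pool is not None and len(pool):
            reg = pool.iloc[int(rng.integers(len(pool)))]
            chrom = reg["chrom"]
            tss0 = int(rng.integers(reg["start"], reg["end"]))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            tss0 = int(rng.integers(0, lengths[chrom]))
        tx_len = int(rng.integers(500, 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start0 = tss0
            end = min(tss0 + tx_len, lengths[chrom])
        else:
            start0 = max(tss0 - tx_len, 0)
            end = tss0 + 1
        if end - start0 < 2:
            start0 = max(end - 2, 0)
        tss = (start0 + 1) if strand == "+" else end
        tts = end if strand == "+" else (start0 + 1)
        rows.append((tid, source, biotype, chrom, start0, end, strand, tss, tts))
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "source_db", "biotype", "chrom", "start", "end", "strand", "tss", "tts"],
    )
    df["tss0"] = df["tss"] - 1
    df["tts0"] = df["tts"] - 1
    return df


def _write_gff(transcripts: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts.itertuples():
            fh.write(
                f"{t.chrom}\tlncipedia\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                f"ID={t.transcript_id};gene_id={t.transcript_id}\n"
            )


def _write_gtf(transcripts: pd.DataFrame, path: Path) -> None:
    biotype_names = {"coding": "protein_coding", "lncRNA": "lncRNA", "other-noncoding": "snoRNA"}
    with open(path, "w") as fh:
        for t in transcripts.itertuples():
            fh.write(
                f"{t.chrom}\tensembl\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t"
                f'gene_id "{t.transcript_id}G"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{biotype_names[t.biotype]}";\n'
            )


def _illumina_columns(rng, probes: pd.DataFrame, transcripts: pd.DataFrame,
                      segments_by_cl: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Plausible Illumina default-annotation columns derived from the toy genome."""
    groups, names, phantom5 = [], [], []
    enh_states = {s for s in CHROMHMM_STATES if annotate.state_kind(s) == "Enhancer"}
    for r in probes.itertuples():
        terms, ids = [], []
        for t in transcripts.itertuples():
            if t.chrom != r.chrom:
                continue
            d = r.pos0 - t.tss0 if t.strand == "+" else t.tss0 - r.pos0
            inside = t.start <= r.pos0 < t.end
            if -200 <= d < 0:
                terms.append("TSS200")
            elif -1500 <= d < -200:
                terms.append("TSS1500")
            elif inside and 0 <= d < 300:
                terms.append("1stExon" if rng.random() < 0.5 else "5'UTR")
            elif inside and d >= (t.end - t.start) - 300:
                terms.append("3'UTR")
            elif inside:
                terms.append("Body")
            else:
                continue
            ids.append(t.transcript_id)
        groups.append(";".join(terms))
        names.append(";".join(ids))
        in_enh = any(
            ((seg["chrom"] == r.chrom) & (seg["start"] <= r.pos0) & (r.pos0 < seg["end"])
             & seg["state"].isin(enh_states)).any()
            for seg in segments_by_cl.values()
        )
        phantom5.append(f"{r.chrom}:{r.pos0}-{r.pos0 + 400}" if in_enh and rng.random() < 0.3 else "")
    out = probes[["probe_id"]].copy()
    out["UCSC_RefGene_Group"] = groups
    out["UCSC_RefGene_Name"] = names
    out["GencodeCompV12_Group"] = groups
    out["Phantom4_Enhancers"] = ""
    out["Phantom5_Enhancers"] = phantom5
    out["450k_Enhancer"] = ""
    return out


def _write_manifest(probes: pd.DataFrame, illumina_cols: pd.DataFrame, path: Path, platform: str) -> None:
    name = "MethylationEPIC_v-1-0_B4.csv" if platform == "850k" else "HumanMethylation450_15017482_v.1.2.csv"
    merged = probes.merge(illumina_cols, on="probe_id")
    with open(path, "w") as fh:
        fh.write("Illumina Inc. synthetic manifest\n[Heading]\n")
        fh.write(f"Descriptor File Name,{name}\nAssay Format,Infinium HD\n")
        fh.write("[Assay]\n")
        cols = ["IlmnID", "Name", "Infinium_Design_Type", "CHR", "MAPINFO",
                "UCSC_RefGene_Name", "UCSC_RefGene_Group", "GencodeCompV12_Group",
                "Phantom4_Enhancers", "Phantom5_Enhancers"]
        cols.append("450k_Enhancer" if platform == "850k" else "Enhancer")
        fh.write(",".join(cols) + "\n")
        for _, row in merged.iterrows():
            chrom = row["chrom"].removeprefix("chr")
            fields = [row["probe_id"], row["probe_id"], row["design_type"], chrom, str(row["position"]),
                      row["UCSC_RefGene_Name"], row["UCSC_RefGene_Group"], row["GencodeCompV12_Group"],
                      row["Phantom4_Enhancers"], row["Phantom5_Enhancers"], row["450k_Enhancer"]]
            fh.write(",".join(str(f) for f in fields) + "\n")
        fh.write("[Controls]\n")
        fh.write("ctrl_1,NEGATIVE,Red,\nctrl_2,NORM_A,Green,\n")


def gen_genome_fixtures(config: SimConfig, outdir) -> dict:
    """Generate and write the full genome-level fixture set.

    Returns a dict with the emitted file paths, the in-memory tables
    (segments per cell line, transcripts, islands, atlas, probes) and the
    ``ground_truth`` table carrying the brute-force per-probe category.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 0)
    cell_lines = CELL_LINES[: config.n_cell_lines]

    segments_by_cl: dict[str, pd.DataFrame] = {}
    bed_paths = {}
    regions_all = []
    for cl in cell_lines:
        seg = _tile_chromatin(rng, config)
        seg["cell_line"] = cl
        segments_by_cl[cl] = seg
        path = outdir / f"chromatin_{cl}.bed"
        seg[["chrom", "start", "end", "state"]].to_csv(path, sep="\t", header=False, index=False)
        bed_paths[cl] = path
        regions_all.append(annotate.build_super_regions(seg, cl))
    regions = pd.concat(regions_all, ignore_index=True)

    # CpG islands: non-overlapping random intervals
    island_rows = []
    for _ in range(config.n_islands):
        chrom = list(config.genome)[int(rng.integers(len(config.genome)))]
        length = int(rng.integers(300, 1_500))
        start = int(rng.integers(0, max(config.genome[chrom] - length, 1)))
        island_rows.append((chrom, start, start + length))
    islands = annotate.merge_intervals(pd.DataFrame(island_rows, columns=["chrom", "start", "end"]))
    cgi_path = outdir / "cgi.bed"
    islands.to_csv(cgi_path, sep="\t", header=False, index=False)

    transcripts = _place_transcripts(rng, config, regions)
    gff_path = outdir / "lncipedia.gff"
    gtf_path = outdir / "ensembl.gtf"
    _write_gff(transcripts[transcripts["source_db"] == "LNCipedia"], gff_path)
    _write_gtf(transcripts[transcripts["source_db"] == "Ensembl"], gtf_path)

    # enhancer atlas: jittered copies of ~30% of enhancer super-regions
    ens_ids = transcripts.loc[transcripts["source_db"] == "Ensembl", "transcript_id"].to_numpy()
    atlas_rows = []
    enh = regions[regions["kind"] == "Enhancer"]
    for r in enh.itertuples():
        if rng.random() < 0.3 and len(ens_ids):
            jitter = int(rng.integers(-100, 100))
            start = max(r.start + jitter, 0)
            end = max(r.end + jitter, start + 50)
            atlas_rows.append((r.cell_line, r.chrom, start, end, ens_ids[int(rng.integers(len(ens_ids)))]))
    atlas = pd.DataFrame(atlas_rows, columns=["cell_line", "chrom", "start", "end", "target_transcript"])
    atlas_path = outdir / "enhancer_atlas.tsv"
    atlas.to_csv(atlas_path, sep="\t", index=False)

    # probes: unique positions, 30% enriched into promoter regions / islands
    total_len = sum(config.genome.values())
    if config.n_probes > total_len // 2:
        raise ValueError("probe count exceeds genome capacity")
    chrom_names = list(config.genome)
    chrom_probs = np.array([config.genome[c] for c in chrom_names], dtype=float) / total_len
    positions: set[tuple[str, int]] = set()
    prom = regions[regions["kind"] == "Promoter"].reset_index(drop=True)
    enriched = pd.concat([prom[["chrom", "start", "end"]], islands], ignore_index=True)
    while len(positions) < config.n_probes:
        if len(enriched) and rng.random() < 0.3:
            reg = enriched.iloc[int(rng.integers(len(enriched)))]
            positions.add((reg["chrom"], int(rng.integers(reg["start"], reg["end"]))))
        else:
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_probs))]
            positions.add((chrom, int(rng.integers(0, config.genome[chrom]))))
    ordered = sorted(positions)
    probes = pd.DataFrame(ordered, columns=["chrom", "pos0"])
    probes["position"] = probes["pos0"] + 1
    probes["probe_id"] = [f"cg{i:08d}" for i in range(len(probes))]
    probes["design_type"] = np.where(rng.random(len(probes)) < config.fraction_type_ii, "II", "I")
    probes["platform"] = "850k"
    probes["cross_reactive"] = False
    probes["snp_overlap"] = False

    illumina_cols = _illumina_columns(rng, probes, transcripts, segments_by_cl)
    manifest_850k = outdir / "manifest_850k.csv"
    _write_manifest(probes, illumina_cols, manifest_850k, "850k")
    shared = rng.random(len(probes)) < 0.55
    manifest_450k = outdir / "manifest_450k.csv"
    _write_manifest(probes[shared], illumina_cols[shared], manifest_450k, "450k")

    # exclusion lists
    ids = probes["probe_id"].to_numpy()
    cross = set(ids[rng.random(len(ids)) < 0.02])
    snp = set(ids[rng.random(len(ids)) < 0.02])
    (outdir / "cross_reactive.txt").write_text("\n".join(sorted(cross)) + "\n")
    (outdir / "snp_probes.txt").write_text("\n".join(sorted(snp)) + "\n")

    truth_cat = [
        brute_force_category(r.chrom, r.pos0, segments_by_cl, transcripts) for r in probes.itertuples()
    ]
    ground_truth = probes[["probe_id", "chrom", "position", "pos0", "design_type"]].copy()
    ground_truth["true_category"] = truth_cat
    ground_truth["on_450k"] = shared
    ground_truth["cross_reactive"] = ground_truth["probe_id"].isin(cross)
    ground_truth["snp_overlap"] = ground_truth["probe_id"].isin(snp)
    ground_truth.to_csv(outdir / "ground_truth_probes.tsv", sep="\t", index=False)

    return {
        "paths": {
            "chromatin": bed_paths,
            "cgi": cgi_path,
            "lncipedia": gff_path,
            "ensembl": gtf_path,
            "atlas": atlas_path,
            "manifest_850k": manifest_850k,
            "manifest_450k": manifest_450k,
            "cross_reactive": outdir / "cross_reactive.txt",
            "snp": outdir / "snp_probes.txt",
        },
        "segments_by_cell_line": segments_by_cl,
        "regions": regions,
        "islands": islands,
        "transcripts": transcripts,
        "atlas": atlas,
        "probes": probes,
        "ground_truth": ground_truth,
    }


# ---------------------------------------------------------------------------
# beta matrices

def gen_beta_matrix(
    config: SimConfig,
    probes: pd.DataFrame,
    n_replicates_per_group: int = 3,
    groups: int = 1,
    unbiased: bool = False,
    stream: int = 1,
    true_m: np.ndarray | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Generate a beta matrix with the planted type I / type II bias.

    True per-probe M values are drawn from the two-peak mixture; observed
    type II M values are compressed by ``config.compression`` before adding
    replicate noise (SD per design type, inflated by ``hetero_b`` per unit
    |true M|).  With ``groups=2``, a ``dm_fraction`` of probes gets the
    group-B beta shifted by ``dm_delta_beta``.  ``unbiased=True`` emulates a
    reference technology: no compression and type I noise everywhere; pass
    the ``true_m`` of a previous call so the reference measures the same
    underlying methylome.  Returns the matrix (with detection p layer and
    sample metadata) and a ground-truth table (true_m per group, is_dmc,
    direction).
    """
    rng = _rng(config, stream)
    n = len(probes)
    ids = probes["probe_id"].to_numpy()
    design = probes["design_type"].to_numpy()
    if true_m is None:
        meth_state = rng.random(n) < 0.5
        true_m = np.where(
            meth_state,
            rng.normal(config.peak_meth, config.peak_sd, n),
            rng.normal(config.peak_unmeth, config.peak_sd, n),
        )
    else:
        true_m = np.asarray(true_m, dtype=float).copy()
        if len(true_m) != n:
            raise ValueError("true_m length does not match the probe table")
    true_beta = _sigmoid_beta(true_m)

    is_dmc = np.zeros(n, dtype=bool)
    dm_direction = np.full(n, "", dtype=object)
    true_beta_b = true_beta.copy()
    if groups >= 2 and config.dm_fraction > 0:
        is_dmc = rng.random(n) < config.dm_fraction
        lo, hi = config.dm_beta_range
        true_beta = np.where(is_dmc, rng.uniform(lo, hi, n), true_beta)
        up_ok = true_beta + config.dm_delta_beta <= 0.98
        down_ok = true_beta - config.dm_delta_beta >= 0.02
        go_up = np.where(up_ok & down_ok, rng.random(n) < 0.5, up_ok)
        shift = np.where(go_up, config.dm_delta_beta, -config.dm_delta_beta)
        true_beta_b = np.where(is_dmc, np.clip(true_beta + shift, 0.01, 0.99), true_beta)
        dm_direction = np.where(is_dmc, np.where(go_up, "hypo", "hyper"), "")  # relative to group A
        true_m = np.log2(true_beta / (1.0 - true_beta))
    true_m_b = np.log2(true_beta_b / (1.0 - true_beta_b))

    sd_base = np.where(design == "II", config.noise_sd_type_ii, config.noise_sd_type_i)
    c = np.where(design == "II", config.compression, 1.0)
    if unbiased:
        sd_base = np.full(n, config.noise_sd_type_i)
        c = np.ones(n)

    cols, names, meta_rows = {}, [], []
    group_labels = [chr(ord("A") + g) for g in range(groups)]
    for g, glabel in enumerate(group_labels):
        tm = true_m if g == 0 else true_m_b
        sd = sd_base * (1.0 + config.hetero_b * np.abs(tm))
        for rep in range(n_replicates_per_group):
            name = f"{glabel}{rep + 1}"
            if config.noise_scale == "M":
                obs_m = tm * c + rng.normal(0.0, 1.0, n) * sd
                beta = _sigmoid_beta(obs_m)
            else:
                sd_b = config.beta_noise_sd * (1.0 + config.hetero_b * np.abs(tm))
                beta = np.clip(_sigmoid_beta(tm * c) + rng.normal(0.0, 1.0, n) * sd_b, 0.0, 1.0)
            cols[name] = beta
            names.append(name)
            meta_rows.append({"sample_id": name, "group": glabel, "technology": "850k"})
    values = pd.DataFrame(cols, index=pd.Index(ids, name="probe_id"))
    fail = rng.random(values.shape) < config.detection_fail_rate
    detp = pd.DataFrame(
        np.where(fail, rng.uniform(0.05, 1.0, values.shape), rng.uniform(0.0, 0.05, values.shape)),
        index=values.index,
        columns=values.columns,
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(
        {
            "probe_id": ids,
            "design_type": design,
            "true_m": true_m,
            "true_m_b": true_m_b,
            "is_dmc": is_dmc,
            "dm_direction": dm_direction,
        }
    ).set_index("probe_id")
    return BetaMatrix(values, detp, meta), truth


# ---------------------------------------------------------------------------
# RRBS

def gen_rrbs(config: SimConfig, n_samples: int = 3, stream: int = 2) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Generate per-sample RRBS call tables (both strands, binomial counts).

    Coverage is negative-binomial; a ``rrbs_missing_rate`` fraction of
    site/sample pairs is dropped (inconsistent coverage across replicates);
    a ``rrbs_strand_divergence_rate`` fraction of sites gets a minus-strand
    methylation fraction displaced by more than the 0.10 merge tolerance.
    """
    rng = _rng(config, stream)
    chrom_names = list(config.genome)
    total = sum(config.genome.values())
    probs = np.array([config.genome[c] for c in chrom_names], dtype=float) / total
    seen: set[tuple[str, int]] = set()
    while len(seen) < config.rrbs_n_sites:
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=probs))]
        seen.add((chrom, int(rng.integers(1, config.genome[chrom] - 1))))
    sites = sorted(seen)
    meth_state = rng.random(len(sites)) < 0.5
    true_f = np.where(
        meth_state,
        _sigmoid_beta(rng.normal(config.peak_meth, config.peak_sd, len(sites))),
        _sigmoid_beta(rng.normal(config.peak_unmeth, config.peak_sd, len(sites))),
    )
    divergent = rng.random(len(sites)) < config.rrbs_strand_divergence_rate
    minus_f = np.where(
        divergent,
        np.clip(np.where(true_f < 0.5, true_f + 0.3, true_f - 0.3), 0.0, 1.0),
        true_f,
    )
    nb_n = config.rrbs_dispersion
    nb_p = nb_n / (nb_n + config.rrbs_mean_coverage)
    out = []
    for _s in range(n_samples):
        rows = []
        for i, (chrom, pos) in enumerate(sites):
            for strand, f in (("+", true_f[i]), ("-", minus_f[i])):
                if rng.random() < config.rrbs_missing_rate:
                    continue
                cov = int(rng.negative_binomial(nb_n, nb_p))
                meth = float(rng.binomial(cov, f)) / cov if cov > 0 else np.nan
                p = pos if strand == "+" else pos + 1
                rows.append((chrom, p, strand, cov, meth))
        df = pd.DataFrame(rows, columns=["chrom", "position", "strand", "coverage", "meth_fraction"])
        df["pos0"] = df["position"] - 1
        out.append(df)
    truth = pd.DataFrame(
        {
            "chrom": [c for c, _ in sites],
            "position": [p for _, p in sites],
            "true_fraction": true_f,
            "strand_divergent": divergent,
        }
    )
    return out, truth
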