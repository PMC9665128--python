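"""Super-region construction, five-category classification and associations."""

import numpy as np
import pandas as pd
import pytest

from epicpipe import annotate, synth


def seg(chrom, start, end, state, cl="K562"):
    return {"chrom": chrom, "start": start, "end": end, "state": state, "cell_line": cl}


def probes_at(points):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(points))],
            "chrom": [c for c, _ in points],
            "pos0": [p for _, p in points],
            "position": [p + 1 for _, p in points],
        }
    )


def tx(tid, chrom, start, end, strand, biotype="coding", source="Ensembl"):
    tss = start + 1 if strand == "+" else end
    tts = end if strand == "+" else start + 1
    return {
        "transcript_id": tid, "source_db": source, "biotype": biotype, "chrom": chrom,
        "start": start, "end": end, "strand": strand, "tss": tss, "tts": tts,
        "tss0": tss - 1, "tts0": tts - 1,
    }


EMPTY_TX = pd.DataFrame(columns=["transcript_id", "source_db", "biotype", "chrom", "start",
                                 "end", "strand", "tss", "tts", "tss0", "tts0"])


class TestSuperRegions:
    def test_adjacent_enhancer_states_fuse(self):
        segs = pd.DataFrame([seg("chr1", 100, 200, "4_Strong_Enhancer"), seg("chr1", 200, 300, "6_Weak_Enhancer")])
        out = annotate.build_super_regions(segs, "K562")
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"], r["kind"]) == (100, 300, "Enhancer")
        assert r["region_id"] == "K562:Enhancer:chr1:100"

    def test_ignored_states_emit_nothing_and_break_fusion(self):
        segs = pd.DataFrame(
            [
                seg("chr1", 0, 100, "1_Active_Promoter"),
                seg("chr1", 100, 150, "8_Insulator"),
                seg("chr1", 150, 250, "2_Weak_Promoter"),
            ]
        )
        out = annotate.build_super_regions(segs, "K562")
        assert list(out["kind"]) == ["Promoter", "Promoter"]
        assert list(out["start"]) == [0, 150]

    def test_empty_input(self):
        segs = pd.DataFrame(columns=["chrom", "start", "end", "state", "cell_line"])
        assert len(annotate.build_super_regions(segs, "K562")) == 0

    def test_overlapping_segments_rejected(self):
        segs = pd.DataFrame([seg("chr1", 100, 300, "8_Insulator"), seg("chr1", 200, 400, "1_Active_Promoter")])
        with pytest.raises(ValueError, match="overlap"):
            annotate.build_super_regions(segs, "K562")

    def test_fusion_is_maximal_within_kind(self):
        """Same-kind runs merge completely; kind changes split."""
        segs = pd.DataFrame(
            [
                seg("chr1", 0, 50, "1_Active_Promoter"),
                seg("chr1", 50, 80, "3_Poised_Promoter"),
                seg("chr1", 80, 120, "5_Strong_Enhancer"),
                seg("chr1", 120, 200, "7_Weak_Enhancer"),
            ]
        )
        out = annotate.build_super_regions(segs, "K562")
        assert [(r.kind, r.start, r.end) for r in out.itertuples()] == [
            ("Promoter", 0, 80), ("Enhancer", 80, 200),
        ]


def _regions(*cell_line_segments):
    parts = []
    for cl, segs in cell_line_segments:
        parts.append(annotate.build_super_regions(pd.DataFrame([dict(s, cell_line=cl) for s in segs]), cl))
    return pd.concat(parts, ignore_index=True)


class TestClassification:
    def test_promoter_plus_enhancer_across_cell_lines_is_dual(self):
        regions = _regions(
            ("HMEC", [seg("chr1", 100, 300, "1_Active_Promoter")]),
            ("K562", [seg("chr1", 150, 400, "4_Strong_Enhancer")]),
        )
        cat, states = annotate.classify_probes(probes_at([("chr1", 200)]), regions, EMPTY_TX)
        assert cat.iloc[0] == "Dual"
        assert states.iloc[0]["HMEC"] == "Promoter" and states.iloc[0]["K562"] == "Enhancer"

    def test_dual_symmetry_under_cell_line_swap(self):
        a = _regions(
            ("HMEC", [seg("chr1", 100, 300, "1_Active_Promoter")]),
            ("K562", [seg("chr1", 150, 400, "4_Strong_Enhancer")]),
        )
        b = _regions(
            ("HMEC", [seg("chr1", 150, 400, "4_Strong_Enhancer")]),
            ("K562", [seg("chr1", 100, 300, "1_Active_Promoter")]),
        )
        pr = probes_at([("chr1", 200)])
        assert annotate.classify_probes(pr, a, EMPTY_TX)[0].iloc[0] == annotate.classify_probes(pr, b, EMPTY_TX)[0].iloc[0]

    def test_gene_body_fallback_inside_transcript_span(self):
        regions = _regions(("HMEC", [seg("chr1", 100, 300, "1_Active_Promoter")]))
        transcripts = pd.DataFrame([tx("t1", "chr1", 1000, 2000, "+")])
        cat, _ = annotate.classify_probes(probes_at([("chr1", 1500)]), regions, transcripts)
        assert cat.iloc[0] == "GeneBody"

    def test_intergenic_fallthrough(self):
        regions = _regions(("HMEC", [seg("chr1", 100, 300, "1_Active_Promoter")]))
        cat, states = annotate.classify_probes(probes_at([("chr2", 5000)]), regions, EMPTY_TX)
        assert cat.iloc[0] == "Intergenic"
        assert (states.iloc[0] == "none").all()

    def test_unmapped_probe_rejected(self):
        pr = probes_at([("chr1", 200)])
        pr.loc[0, "pos0"] = np.nan
        with pytest.raises(ValueError, match="position"):
            annotate.classify_probes(pr, _regions(("HMEC", [seg("chr1", 0, 10, "8_Insulator")])), EMPTY_TX)

    def test_adding_cell_line_only_moves_categories_forward(self):
        """Intergenic/GeneBody -> single-kind -> Dual, never backwards."""
        rank = {"Intergenic": 0, "GeneBody": 0, "Promoter": 1, "Enhancer": 1, "Dual": 2}
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = probes_at([("chr1", int(p)) for p in rng.integers(0, 2000, 15)])
            states = list(np.array(synth.CELL_LINES)[:3])
            tracks = []
            for cl in states:
                segs, pos = [], 0
                while pos < 2000:
                    ln = int(rng.integers(100, 400))
                    st = rng.choice(["1_Active_Promoter", "4_Strong_Enhancer", "8_Insulator"])
                    segs.append(seg("chr1", pos, pos + ln, st, cl))
                    pos += ln
                tracks.append((cl, segs))
            base = _regions(*tracks[:2])
            more = _regions(*tracks)
            cat_base, _ = annotate.classify_probes(pts, base, EMPTY_TX)
            cat_more, _ = annotate.classify_probes(pts, more, EMPTY_TX)
            assert (cat_base.map(rank) <= cat_more.map(rank)).all()

    def test_partition_is_exhaustive(self, toy_fixtures):
        cat, _ = annotate.classify_probes(
            toy_fixtures["probes"], toy_fixtures["regions"], toy_fixtures["transcripts"]
        )
        counts = cat.value_counts()
        assert counts.sum() == len(toy_fixtures["probes"])
        assert set(counts.index) <= set(annotate.CATEGORIES)

    def test_matches_brute_force_scan_on_toy_genomes(self):
        """Oracle equivalence against a per-base scan of the raw tracks."""
        rng = np.random.default_rng(11)
        for trial in range(10):
            cfg = synth.SimConfig(
                seed=int(rng.integers(2**31)),
                genome={"chr1": 6_000, "chr2": 4_000},
                n_probes=40,
                n_transcripts=12,
                n_cell_lines=int(rng.integers(1, 10)),
                segment_mean_length=250,
            )
            srng = synth._rng(cfg, 0)
            segs_by_cl = {}
            parts = []
            for cl in synth.CELL_LINES[: cfg.n_cell_lines]:
                s = synth._tile_chromatin(srng, cfg)
                s["cell_line"] = cl
                segs_by_cl[cl] = s
                parts.append(annotate.build_super_regions(s, cl))
            regions = pd.concat(parts, ignore_index=True)
            transcripts = synth._place_transcripts(srng, cfg, regions)
            pts = probes_at(
                [("chr1", int(p)) for p in srng.integers(0, 6_000, 25)]
                + [("chr2", int(p)) for p in srng.integers(0, 4_000, 15)]
            )
            cat, _ = annotate.classify_probes(pts, regions, transcripts)
            for r in pts.itertuples():
                expected = synth.brute_force_category(r.chrom, r.pos0, segs_by_cl, transcripts)
                assert cat.loc[r.probe_id] == expected


class TestCGIContext:
    islands = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [11_000]})

    def cgi(self, pos, islands=None):
        return annotate.assign_cgi_context(probes_at([("chr1", pos)]), self.islands if islands is None else islands).iloc[0]

    def test_inside_island(self):
        assert self.cgi(10_500) == "Island"

    def test_shore_within_2kb(self):
        assert self.cgi(12_500) == "Shore"  # 1,500 bp downstream of the island end

    def test_open_sea_beyond_2kb(self):
        assert self.cgi(16_000) == "OpenSea"

    def test_shore_clipped_at_zero(self):
        islands = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [700]})
        assert self.cgi(0, islands) == "Shore"

    def test_no_islands_means_open_sea(self):
        assert self.cgi(10_500, self.islands.iloc[:0]) == "OpenSea"

    def test_island_precedence_between_adjacent_islands(self):
        islands = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 1_500], "end": [1_000, 2_000]})
        assert self.cgi(1_600, islands) == "Island"


class TestAssociations:
    regions = None

    @classmethod
    def setup_class(cls):
        cls.regions = _regions(
            ("K562", [seg("chr1", 100, 300, "1_Active_Promoter"), seg("chr1", 500, 800, "4_Strong_Enhancer")]),
        )

    def test_coding_tss_in_promoter(self):
        transcripts = pd.DataFrame([tx("t1", "chr1", 150, 900, "+")])
        out = annotate.associate_tss(transcripts, self.regions)
        assert list(out["association_type"]) == ["TSS-promoter"]

    def test_lncrna_tss_in_enhancer_is_erna(self):
        transcripts = pd.DataFrame([tx("l1", "chr1", 600, 1_200, "+", biotype="lncRNA", source="LNCipedia")])
        out = annotate.associate_tss(transcripts, self.regions)
        assert list(out["association_type"]) == ["eRNA"]

    def test_coding_tss_in_enhancer_gives_nothing(self):
        transcripts = pd.DataFrame([tx("t1", "chr1", 600, 1_200, "+")])
        assert len(annotate.associate_tss(transcripts, self.regions)) == 0

    def test_tss_outside_regions_gives_nothing(self):
        transcripts = pd.DataFrame([tx("t1", "chr1", 2_000, 3_000, "+")])
        assert len(annotate.associate_tss(transcripts, self.regions)) == 0

    def test_erna_only_for_lncrna_biotype(self):
        """eRNA transcripts are a subset of lncRNAs."""
        transcripts = pd.DataFrame(
            [
                tx("l1", "chr1", 600, 1_200, "+", biotype="lncRNA"),
                tx("c1", "chr1", 610, 1_200, "+", biotype="coding"),
                tx("o1", "chr1", 620, 1_200, "+", biotype="other-noncoding"),
            ]
        )
        out = annotate.associate_tss(transcripts, self.regions)
        erna = set(out.loc[out["association_type"] == "eRNA", "transcript_id"])
        assert erna == {"l1"}

    def atlas(self, cl, start, end, target="tx9"):
        return pd.DataFrame({"cell_line": [cl], "chrom": ["chr1"], "start": [start], "end": [end], "target_transcript": [target]})

    def test_enhancer_target_same_cell_line(self):
        assoc, unknown = annotate.map_enhancer_targets(self.regions, self.atlas("K562", 700, 1_000))
        assert list(assoc["transcript_id"]) == ["tx9"]
        assert unknown == set()

    def test_different_cell_line_leaves_unknown_target(self):
        with pytest.warns(UserWarning, match="HMEC"):
            assoc, unknown = annotate.map_enhancer_targets(self.regions, self.atlas("HMEC", 700, 1_000))
        assert len(assoc) == 0
        assert unknown == {"K562:Enhancer:chr1:500"}

    def test_touching_intervals_do_not_overlap(self):
        assoc, unknown = annotate.map_enhancer_targets(self.regions, self.atlas("K562", 800, 1_000))
        assert len(assoc) == 0 and unknown == {"K562:Enhancer:chr1:500"}


class TestIlluminaCollapse:
    def collapse(self, group="", phantom5=""):
        probes = pd.DataFrame(
            {"probe_id": ["p0"], "UCSC_RefGene_Group": [group], "Phantom5_Enhancers": [phantom5]}
        )
        return annotate.collapse_illumina_default(probes).iloc[0]

    @pytest.mark.parametrize(
        "group,phantom5,expected",
        [
            ("TSS200", "", "Promoter"),
            ("Body", "chr1:1-2", "Enhancer"),
            ("TSS1500;Body", "chr1:1-2", "Dual"),
            ("Body;3'UTR", "", "GeneBody"),
            ("", "", "Intergenic"),
        ],
    )
    def test_category_rules(self, group, phantom5, expected):
        assert self.collapse(group, phantom5) == expected

    def test_unknown_term_warned_and_ignored(self):
        with pytest.warns(UserWarning, match="Exon9"):
            assert self.collapse("Exon9") == "Intergenic"


def test_promoter_nonpromoter_exhaustive():
    cats = pd.Series(list(annotate.CATEGORIES), index=[f"p{i}" for i in range(5)])
    out = annotate.promoter_nonpromoter(cats)
    assert out.to_dict() == {
        "p0": "NonPromoter",  # Enhancer
        "p1": "Promoter",     # Dual
        "p2": "Promoter",     # Promoter
        "p3": "NonPromoter",  # GeneBody
        "p4": "NonPromoter",  # Intergenic
    }


class TestDiscrepancyProfile:
    def test_binning_and_discordance(self):
        transcripts = pd.DataFrame([tx("t1", "chr1", 10_000, 20_000, "+")])
        # probe 100 bp downstream of the TSS, concordant; probe 1,900 bp upstream, discordant
        pr = probes_at([("chr1", 10_100), ("chr1", 8_100)])
        illumina = pd.Series(["Promoter", "Promoter"], index=pr["probe_id"])
        encode = pd.Series(["Promoter", "Enhancer"], index=pr["probe_id"])
        tx_ids = pd.Series([["t1"], ["t1"]], index=pr["probe_id"])
        profile, excluded = annotate.promoter_discrepancy_profile(pr, illumina, encode, tx_ids, transcripts)
        assert excluded == 0
        by_bin = profile.set_index("bin_left")
        assert by_bin.loc[0, "pct_discordant"] == 0.0        # bin [0, 200) holds d = +100
        assert by_bin.loc[-2000, "pct_discordant"] == 100.0  # bin [-2000, -1800) holds d = -1900

    def test_probes_without_transcripts_excluded(self):
        transcripts = pd.DataFrame([tx("t1", "chr1", 10_000, 20_000, "+")])
        pr = probes_at([("chr1", 10_100)])
        illumina = pd.Series(["Promoter"], index=pr["probe_id"])
        encode = pd.Series(["Promoter"], index=pr["probe_id"])
        tx_ids = pd.Series([[]], index=pr["probe_id"])
        profile, excluded = annotate.promoter_discrepancy_profile(pr, illumina, encode, tx_ids, transcripts)
        assert excluded == 1 and len(profile) == 0

    def test_planted_discordance_outside_2kb_matches_brute_force(self):
        """Cohort planted discordant beyond +/-2 kb shows discordance exactly there."""
        transcripts = pd.DataFrame([tx("t1", "chr1", 50_000, 60_000, "+")])
        rng = np.random.default_rng(3)
        dists = rng.integers(-5_000, 5_000, 200)
        pr = probes_at([("chr1", 50_000 - 1 + int(d)) for d in dists])
        pr = pr.drop_duplicates(subset="pos0").reset_index(drop=True)
        dist_vals = pr["pos0"].to_numpy() - (50_000 - 1)
        encode = pd.Series(
            np.where(np.abs(dist_vals) > 2_000, "Enhancer", "Promoter"), index=pr["probe_id"]
        )
        illumina = pd.Series("Promoter", index=pr["probe_id"])
        tx_ids = pd.Series([["t1"]] * len(pr), index=pr["probe_id"])
        profile, _ = annotate.promoter_discrepancy_profile(pr, illumina, encode, tx_ids, transcripts)
        for r in profile.itertuples():
            # brute force: a 200-bp bin fully outside [-2000, 2000] must be 100% discordant,
            # a bin fully inside 0%
            if r.bin_right <= -2_000 or r.bin_left > 2_000:
                assert r.pct_discordant == 100.0
            elif r.bin_left >= -2_000 and r.bin_right <= 2_000:
                assert r.pct_discordant == 0.0
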