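import numpy as np
import pandas as pd
import pytest

from nichefx import regulatory


def peak_frame(summits, chrom="chr1"):
    s = np.asarray(summits)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.maximum(s - 250, 0),
            "end": s + 250,
            "name": [f"p{i}" for i in range(len(s))],
            "summit": s,
        }
    )


class TestMergePeaks:
    def test_two_close_summits_merge_to_midpoint(self):
        merged = regulatory.merge_peaks(peak_frame([1100, 1250]))
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row["summit"], row["start"], row["end"]) == (1175, 675, 1675)

    def test_single_summit_fixed_width(self):
        row = regulatory.merge_peaks(peak_frame([5000])).iloc[0]
        assert (row["start"], row["end"]) == (4500, 5500)

    def test_chain_merges_transitively(self):
        merged = regulatory.merge_peaks(peak_frame([1100, 1280, 1460]))
        assert len(merged) == 1 and merged.iloc[0]["summit"] == 1280

    def test_far_summits_stay_separate(self):
        merged = regulatory.merge_peaks(peak_frame([1000, 1300]))
        assert len(merged) == 2

    def test_idempotent(self, rng):
        raw = peak_frame(np.sort(rng.integers(0, 100_000, size=60)))
        once = regulatory.merge_peaks(raw)
        twice = regulatory.merge_peaks(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


class TestDifferentialAccessibility:
    def _design(self, reps=3):
        return pd.DataFrame(
            {
                "sample_id": [f"{a}_r{r}" for a in ("young", "aged") for r in range(1, reps + 1)],
                "age": ["young"] * reps + ["aged"] * reps,
                "time": "T0",
                "batch": "b1",
            }
        )

    def _counts(self, young, aged, reps=3, n=4, anchors=12, anchor_level=700):
        """Patterned peaks plus constant-majority anchors (stable size factors)."""
        design = self._design(reps)
        base = np.array(
            [[young] * reps + [aged] * reps] * n
            + [[anchor_level] * 2 * reps] * anchors,
            dtype=np.int64,
        )
        return (
            pd.DataFrame(
                base,
                index=pd.Index([f"p{i}" for i in range(n + anchors)], name="peak_id"),
                columns=design["sample_id"],
            ),
            design,
        )

    def test_shared_doubling_cancels(self):
        """Peak and background doubling together: background-normalized LFC 0."""
        pk, design = self._counts(200, 400)
        bg, _ = self._counts(1000, 2000)
        out = regulatory.differential_accessibility(pk, bg, design)
        assert np.allclose(out["lfc"].iloc[:4], 0.0, atol=1e-4)

    def test_peak_doubles_background_flat(self):
        pk, design = self._counts(200, 400)
        bg, _ = self._counts(1000, 1000)
        out = regulatory.differential_accessibility(pk, bg, design)
        assert np.allclose(out["lfc"].iloc[:4], 1.0, atol=1e-4)

    def test_zero_background_falls_back_flagged(self):
        pk, design = self._counts(200, 400, n=2)
        bg, _ = self._counts(1000, 1000, n=2)
        bg.iloc[0] = 0
        out = regulatory.differential_accessibility(pk, bg, design)
        assert bool(out["background_fallback"].iloc[0])
        assert not out["background_fallback"].iloc[1:].any()
        assert np.isfinite(out["lfc"].iloc[0])


class TestRegulatoryDomains:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])

    def test_isolated_plus_strand_gene(self):
        dom = regulatory.build_regulatory_domains(
            self._genes([("g1", "chr1", 2_000_000, "+")])
        ).iloc[0]
        assert (dom["basal_start"], dom["basal_end"]) == (1_995_000, 2_001_000)
        assert (dom["ext_start"], dom["ext_end"]) == (1_000_000, 3_000_000)

    def test_minus_strand_mirrored(self):
        dom = regulatory.build_regulatory_domains(
            self._genes([("g1", "chr1", 2_000_000, "-")])
        ).iloc[0]
        # 1 kb downstream leftward, 5 kb upstream rightward
        assert dom["basal_end"] - dom["basal_start"] == 6000
        assert dom["basal_start"] == 2_000_000 - 999
        assert dom["basal_end"] == 2_000_000 + 5001

    def test_extension_stops_at_neighbour_basal(self):
        doms = regulatory.build_regulatory_domains(
            self._genes(
                [("a", "chr1", 1_000_000, "+"), ("b", "chr1", 1_200_000, "+")]
            )
        ).set_index("gene_id")
        assert doms.loc["a", "ext_end"] == doms.loc["b", "basal_start"]
        assert doms.loc["b", "ext_start"] == doms.loc["a", "basal_end"]

    def test_invariants_on_random_gene_sets(self, rng):
        """Basal within extended; extensions never enter a neighbour's basal."""
        for _ in range(5):
            genes = self._genes(
                [
                    (f"g{i}", "chr1", int(t), rng.choice(["+", "-"]))
                    for i, t in enumerate(
                        np.sort(rng.integers(100_000, 5_000_000, size=12))
                    )
                ]
            )
            doms = regulatory.build_regulatory_domains(genes)
            assert (doms["ext_start"] <= doms["basal_start"]).all()
            assert (doms["ext_end"] >= doms["basal_end"]).all()
            for i, d in doms.iterrows():
                for j, o in doms.iterrows():
                    if i == j:
                        continue
                    # extension beyond own basal never overlaps another basal
                    left_ext = (d["ext_start"], d["basal_start"])
                    right_ext = (d["basal_end"], d["ext_end"])
                    for lo, hi in (left_ext, right_ext):
                        overlap = min(hi, o["basal_end"]) - max(lo, o["basal_start"])
                        if o["basal_start"] >= d["basal_end"] or o["basal_end"] <= d["basal_start"]:
                            assert overlap <= 0


class TestAssignment:
    def _setup(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "chrom": ["chr1", "chr1"],
                "tss": [1_000_000, 1_200_000],
                "strand": ["+", "+"],
            }
        )
        return regulatory.build_regulatory_domains(genes)

    def test_peak_in_basal_domain(self):
        doms = self._setup()
        peaks = peak_frame([999_000])
        out = regulatory.assign_peaks_to_genes(peaks, doms)
        assert ("p0", "a") in set(map(tuple, out.to_numpy()))

    def test_peak_overlapping_boundary_hits_both(self):
        doms = self._setup()
        # straddles a's ext_end == b's basal_start
        boundary = int(doms.set_index("gene_id").loc["b", "basal_start"])
        peaks = peak_frame([boundary])
        out = set(map(tuple, regulatory.assign_peaks_to_genes(peaks, doms).to_numpy()))
        assert ("p0", "a") in out and ("p0", "b") in out

    def test_distant_peak_unassociated(self):
        doms = self._setup()
        peaks = peak_frame([5_000_000])
        assert regulatory.assign_peaks_to_genes(peaks, doms).empty

    def test_matches_bruteforce_overlap_oracle(self, rng):
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(15)],
                "chrom": "chr1",
                "tss": np.sort(rng.integers(0, 3_000_000, size=15)),
                "strand": rng.choice(["+", "-"], size=15),
            }
        )
        doms = regulatory.build_regulatory_domains(genes)
        peaks = peak_frame(rng.integers(0, 3_000_000, size=80))
        got = set(map(tuple, regulatory.assign_peaks_to_genes(peaks, doms).to_numpy()))
        expected = set()
        for _, p in peaks.iterrows():
            for _, d in doms.iterrows():
                if p["start"] < d["ext_end"] and p["end"] > d["ext_start"]:
                    expected.add((p["name"], d["gene_id"]))
        assert got == expected


class TestDistanceBins:
    def _genes(self):
        return pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [1_000_000], "strand": ["+"]}
        )

    def _diff(self, summits, sig=True, lfc=1.5):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "summit": summits,
                "significant": sig,
                "lfc": lfc,
            },
            index=[f"p{i}" for i in range(len(summits))],
        )

    def test_nested_counts(self):
        diff = self._diff([1_005_000, 1_050_000, 1_500_000])
        out = regulatory.peaks_per_gene_by_distance(diff, self._genes())
        assert out.loc["g"].tolist() == [1, 2, 3]

    def test_no_peaks_zero(self):
        out = regulatory.peaks_per_gene_by_distance(self._diff([]), self._genes())
        assert out.loc["g"].tolist() == [0, 0, 0]

    def test_monotone_in_window_size(self, rng):
        diff = self._diff(rng.integers(0, 3_000_000, size=50))
        out = regulatory.peaks_per_gene_by_distance(diff, self._genes())
        vals = out.loc["g"].tolist()
        assert vals == sorted(vals)

    def test_direction_filter(self):
        diff = self._diff([1_005_000, 1_006_000], lfc=1.5)
        diff.loc["p1", "lfc"] = -1.5
        up = regulatory.peaks_per_gene_by_distance(diff, self._genes(), direction="up")
        assert up.loc["g"].tolist()[0] == 1


class TestPileup:
    def test_uniform_coverage_flat_profile(self):
        cov = {"young": {"chr1": np.full(10_000, 3.0)}}
        anchors = pd.DataFrame({"chrom": ["chr1"], "start": [4000], "end": [4100]})
        prof = regulatory.pileup(cov, anchors, flank=500)
        assert np.allclose(prof["young"], prof["young"].iloc[0])

    def test_planted_signal_peaks_at_zero_offset(self, rng):
        vec = np.full(20_000, 1.0)
        vec[9_950:10_050] += 10.0
        cov = {"aged": {"chr1": vec}}
        anchors = pd.DataFrame({"chrom": ["chr1"], "start": [9_950], "end": [10_050]})
        prof = regulatory.pileup(cov, anchors, flank=1000)
        assert abs(prof["aged"].idxmax()) <= 50
        assert prof["aged"].loc[0] > prof["aged"].loc[-900]

    def test_depth_normalization_invariant(self):
        vec = np.random.default_rng(0).uniform(1, 5, size=8000)
        anchors = pd.DataFrame({"chrom": ["chr1"], "start": [3900], "end": [4100]})
        p1 = regulatory.pileup({"c": {"chr1": vec}}, anchors, flank=500)
        p2 = regulatory.pileup({"c": {"chr1": vec * 2}}, anchors, flank=500)
        assert np.allclose(p1["c"], p2["c"])

    def test_off_chromosome_anchor_skipped(self, caplog):
        cov = {"c": {"chr1": np.ones(1000)}}
        anchors = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 500], "end": [110, 520]}
        )
        with caplog.at_level("INFO", logger="nichefx.regulatory"):
            prof = regulatory.pileup(cov, anchors, flank=400)
        assert any("skipped" in r.message for r in caplog.records)
        assert np.allclose(prof["c"], prof["c"].iloc[0])  # only the inner anchor used


class TestCpGIslandProximity:
    def _genes(self, tss=100_000):
        return pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "tss": [tss], "strand": ["+"]}
        )

    def _islands(self, start, end):
        return pd.DataFrame([("chr1", start, end)], columns=["chrom", "start", "end"])

    def test_island_spanning_tss(self):
        flags = regulatory.cpg_island_proximity(self._genes(), self._islands(99_900, 100_200))
        assert bool(flags.loc["g"])

    def test_boundary_at_5kb(self):
        # island's last base 4,999 bp upstream of the TSS
        near = self._islands(95_000, 100_000 - 4_999 + 1)
        assert bool(regulatory.cpg_island_proximity(self._genes(), near).loc["g"])
        far = self._islands(90_000, 100_000 - 5_001 + 1)
        assert not bool(regulatory.cpg_island_proximity(self._genes(), far).loc["g"])

    def test_percentage_is_mean_of_flags(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "chrom": "chr1",
                "tss": [100_000, 900_000],
                "strand": "+",
            }
        )
        flags = regulatory.cpg_island_proximity(genes, self._islands(99_000, 101_000))
        assert flags.mean() == 0.5
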