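"""Distances, metagene binning, methylation deltas and rank statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xcierosion import predictors as pred
from xcierosion.io_formats import SignalTrack


def genes_frame(rows):
    """rows: (gene_id, chrom, start, end[, strand])"""
    df = pd.DataFrame(
        [r + ("+",) * (5 - len(r)) for r in rows],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    return df.set_index("gene_id")


class TestNearestEscapeeDistance:
    def test_overlap_is_zero(self):
        d = pred.nearest_escapee_distance(
            genes_frame([("g", "chrX", 100, 200)]),
            genes_frame([("e", "chrX", 150, 400)]),
        )
        assert d["g"] == 0

    def test_gap_convention(self):
        d = pred.nearest_escapee_distance(
            genes_frame([("g", "chrX", 100, 200)]),
            genes_frame([("e", "chrX", 500, 600)]),
        )
        assert d["g"] == 300

    def test_bookended_is_zero(self):
        d = pred.nearest_escapee_distance(
            genes_frame([("g", "chrX", 100, 200)]),
            genes_frame([("e", "chrX", 200, 300)]),
        )
        assert d["g"] == 0

    def test_minimum_over_escapees(self):
        d = pred.nearest_escapee_distance(
            genes_frame([("g", "chrX", 100, 200)]),
            genes_frame([("e1", "chrX", 500, 600), ("e2", "chrX", 250, 300)]),
        )
        assert d["g"] == 50

    def test_self_distance_zero(self):
        g = genes_frame([("e1", "chrX", 100, 200)])
        assert pred.nearest_escapee_distance(g, g)["e1"] == 0

    def test_empty_escapee_set_errors(self):
        with pytest.raises(ValueError):
            pred.nearest_escapee_distance(
                genes_frame([("g", "chrX", 0, 1)]), genes_frame([])
            )

    def test_translation_invariance(self):
        base = [("g", "chrX", 100, 200), ("h", "chrX", 900, 1000)]
        esc = [("e", "chrX", 400, 500)]
        shift = 1_000_000
        d0 = pred.nearest_escapee_distance(genes_frame(base), genes_frame(esc))
        d1 = pred.nearest_escapee_distance(
            genes_frame([(g, c, s + shift, e + shift) for g, c, s, e in base]),
            genes_frame([(g, c, s + shift, e + shift) for g, c, s, e in esc]),
        )
        assert (d0 == d1).all()


def constant_track(value, lo=-100_000, hi=1_000_000):
    return SignalTrack(pd.DataFrame(
        {"chrom": ["chrX"], "start": [max(lo, 0)], "end": [hi], "value": [value]}
    ))


class TestMetageneProfile:
    def test_constant_track_gives_constant_bins(self):
        genes = genes_frame([("g", "chrX", 200_000, 240_000)])
        matrix, mean = pred.metagene_profile(constant_track(3.0), genes)
        assert np.allclose(matrix.to_numpy(), 3.0)
        assert np.allclose(mean.to_numpy(), 3.0)

    def test_body_one_flank_zero(self):
        genes = genes_frame([("g", "chrX", 100_000, 150_000)])
        track = SignalTrack(pd.DataFrame({
            "chrom": ["chrX"] * 3,
            "start": [0, 100_000, 150_000],
            "end": [100_000, 150_000, 400_000],
            "value": [0.0, 1.0, 0.0],
        }))
        matrix, _ = pred.metagene_profile(track, genes)
        row = matrix.loc["g"]
        assert np.allclose(row[[c for c in row.index if c.startswith("body")]], 1.0)
        assert np.allclose(row[[c for c in row.index if not c.startswith("body")]], 0.0)

    def test_half_covered_bin_coverage_weighted(self):
        # upstream bin [95000, 96000): half covered by 2, half by 0 -> 1
        genes = genes_frame([("g", "chrX", 100_000, 110_000)])
        track = SignalTrack(pd.DataFrame({
            "chrom": ["chrX"] * 2,
            "start": [95_500, 96_000],
            "end": [96_000, 500_000],
            "value": [2.0, 0.0],
        }))
        matrix, _ = pred.metagene_profile(track, genes)
        assert matrix.loc["g", "up_0"] == pytest.approx(1.0)

    def test_minus_strand_flipped(self):
        genes = genes_frame([("g", "chrX", 100_000, 110_000, "-")])
        track = SignalTrack(pd.DataFrame({
            "chrom": ["chrX"] * 2,
            "start": [0, 110_000],
            "end": [110_000, 400_000],
            "value": [0.0, 5.0],
        }))
        matrix, _ = pred.metagene_profile(track, genes)
        # genomic downstream (high coords, value 5) becomes the 5' flank
        assert matrix.loc["g", "up_0"] == pytest.approx(5.0)
        assert matrix.loc["g", "down_0"] == pytest.approx(0.0)

    def test_absent_chromosome_gives_na_row(self):
        genes = genes_frame([("g", "chr7", 100_000, 110_000)])
        matrix, _ = pred.metagene_profile(constant_track(1.0), genes)
        assert matrix.loc["g"].isna().all()

    def test_bin_must_divide_lengths(self):
        with pytest.raises(ValueError):
            pred.metagene_profile(
                constant_track(1.0),
                genes_frame([("g", "chrX", 0, 10)]),
                body_length=5000, bin_size=999, flank=5000,
            )


class TestPromoterMethylationDelta:
    def probes(self, positions, betas):
        return pd.DataFrame({"chrom": "chrX", "pos": positions, "beta": betas})

    def test_identical_tables_zero_delta(self):
        genes = genes_frame([("g", "chrX", 10_000, 20_000)])
        t = self.probes([9_500, 10_200], [0.8, 0.6])
        out = pred.promoter_methylation_delta(t, t, genes)
        assert out.loc["g", "delta_beta"] == pytest.approx(0.0)

    def test_loss_of_methylation(self):
        genes = genes_frame([("g", "chrX", 10_000, 20_000)])
        out = pred.promoter_methylation_delta(
            self.probes([10_000], [0.8]), self.probes([10_000], [0.2]), genes
        )
        assert out.loc["g", "delta_beta"] == pytest.approx(0.6)

    def test_minus_strand_window_at_interval_end(self):
        genes = genes_frame([("g", "chrX", 10_000, 20_000, "-")])
        near_end = self.probes([19_900], [0.9])
        out = pred.promoter_methylation_delta(near_end, near_end, genes)
        assert out.loc["g", "promoter_beta_ref"] == pytest.approx(0.9)
        # the same probe is far from the + TSS window
        plus = genes_frame([("g", "chrX", 10_000, 20_000, "+")])
        out_plus = pred.promoter_methylation_delta(near_end, near_end, plus)
        assert np.isnan(out_plus.loc["g", "promoter_beta_ref"])

    def test_no_probes_gives_na(self):
        genes = genes_frame([("g", "chrX", 10_000, 20_000)])
        empty = self.probes([], [])
        out = pred.promoter_methylation_delta(empty, empty, genes)
        assert np.isnan(out.loc["g", "delta_beta"])


def mw_enumeration_p(x, y):
    """Exact two-sided p by enumerating all group labelings (no ties)."""
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    observed = u_stat(x, y)
    n = len(pooled)
    mean_u = n_x * (n - n_x) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_n3(self):
        res = pred.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings

    def test_interleaved_symmetry(self):
        res = pred.mann_whitney_u([1, 3, 5], [2, 4, 6])
        assert res.value == pytest.approx(len([1, 3, 5]) * 3 / 2, abs=1.6)

    def test_all_tied_p_one(self):
        res = pred.mann_whitney_u([2, 2, 2], [2, 2])
        assert res.p_value == pytest.approx(1.0)
        assert res.value == pytest.approx(3.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            pred.mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n_x,n_y", [(2, 2), (2, 3), (3, 3), (4, 3), (5, 5)])
    def test_matches_enumeration_oracle(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 10 + n_y)
        for _ in range(5):
            x = rng.normal(size=n_x)
            y = rng.normal(size=n_y) + rng.normal()
            res = pred.mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(mw_enumeration_p(x, y), abs=1e-9)


class TestCategoryFeatureTests:
    def make(self, rng, shift):
        genes = [f"g{i}" for i in range(120)]
        cats = pd.DataFrame({
            "gene_id": genes,
            "category": ["consistently_up"] * 40 + ["sporadically_up"] * 40
                        + ["unchanged"] * 40,
        })
        feats = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
        base = rng.normal(size=120)
        offsets = np.repeat([0.0, shift, 2 * shift], 40)
        feats["dist_to_escapee"] = np.abs(base + offsets) * 1e5
        feats["k27_meta"] = 5.0 - offsets + rng.normal(0, 0.5, 120)
        return feats, cats

    def test_identical_distributions_near_null(self):
        rng = np.random.default_rng(21)
        feats, cats = self.make(rng, shift=0.0)
        out = pred.category_feature_tests(feats, cats)
        assert (out["p_value"].dropna() > 0.01).all()
        assert (out["cohens_d"].abs().dropna() < 0.8).all()

    def test_built_in_ordering_detected(self):
        rng = np.random.default_rng(22)
        feats, cats = self.make(rng, shift=1.5)
        out = pred.category_feature_tests(feats, cats)
        extreme = out[
            (out["group_a"] == "consistently_up") & (out["group_b"] == "unchanged")
        ]
        assert (extreme["p_value"] < 0.01).all()

    def test_degenerate_group_gives_na_row(self):
        cats = pd.DataFrame({
            "gene_id": ["g0", "g1", "g2"],
            "category": ["consistently_up", "unchanged", "unchanged"],
        })
        feats = pd.DataFrame(
            {"dist_to_escapee": [1.0, 2.0, 3.0]},
            index=pd.Index(["g0", "g1", "g2"], name="gene_id"),
        )
        out = pred.category_feature_tests(feats, cats)
        single = out[(out["group_a"] == "consistently_up")
                     & (out["feature"] == "dist_to_escapee")]
        assert single["p_value"].isna().all()


def test_metagene_conservation_on_generator_track(small_truth):
    """Mean metagene of a constant-plus-domain track stays within its range."""
    from xcierosion.simulate import simulate_epitracks

    tracks, _ = simulate_epitracks(small_truth)
    genes = small_truth.genes[["chrom", "start", "end", "strand"]]
    matrix, mean = pred.metagene_profile(tracks["XIST+"], genes.head(30))
    enrich = small_truth.config.k27_enrichment
    assert ((mean >= 1.0 - 1e-9) & (mean <= enrich + 1e-9)).all()
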