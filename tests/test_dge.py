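"""Size factors, TPM, BH, the NB Wald stand-in and gene categorization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xcierosion import dge


def matrix(data, samples=None):
    data = np.atleast_2d(np.asarray(data))
    samples = samples or [f"s{i}" for i in range(data.shape[1])]
    return pd.DataFrame(
        data, index=pd.Index([f"g{i}" for i in range(len(data))], name="gene_id"),
        columns=samples,
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = matrix([[10, 10], [20, 20], [5, 5]])
        assert np.allclose(dge.size_factors(m), 1.0)

    def test_doubled_column_ratio(self):
        m = matrix([[10, 20], [30, 60], [7, 14]])
        f = dge.size_factors(m)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_zero_containing_row_excluded(self):
        # hand computation: rows (10,20) and (40,80) -> ratios to geomean
        # are (1/sqrt2, sqrt2) for both; the (0, 5) row is ignored
        m = matrix([[10, 20], [0, 5], [40, 80]])
        f = dge.size_factors(m)
        assert f.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert f.iloc[1] == pytest.approx(np.sqrt(2))

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ValueError, match="all counts positive"):
            dge.size_factors(matrix([[0, 1], [1, 0]]))


class TestTpm:
    def test_single_gene_is_one_million(self):
        m = matrix([[50]], samples=["s0"])
        lengths = pd.Series([1000], index=m.index)
        assert dge.tpm(m, lengths).iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalization_hand_values(self):
        m = matrix([[100, 100], [100, 100]])
        lengths = pd.Series([1000, 2000], index=m.index)
        out = dge.tpm(m, lengths)
        assert out.iloc[0, 0] == pytest.approx(666_666.6667, rel=1e-6)
        assert out.iloc[1, 0] == pytest.approx(333_333.3333, rel=1e-6)

    def test_sums_to_one_million(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.integers(1, 1000, size=(30, 4)))
        lengths = pd.Series(rng.integers(200, 5000, size=30), index=m.index)
        assert np.allclose(dge.tpm(m, lengths).sum(axis=0), 1e6)

    def test_all_zero_sample_reported_zero(self):
        m = matrix([[0, 5], [0, 5]])
        out = dge.tpm(m, pd.Series([1000, 1000], index=m.index))
        assert (out["s0"] == 0).all()

    def test_zero_length_errors(self):
        m = matrix([[1]], samples=["s0"])
        with pytest.raises(ValueError):
            dge.tpm(m, pd.Series([0], index=m.index))


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert dge.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        # sorted p_i * m / i = (.04, .04, .04, .04) after cumulative min
        assert np.allclose(dge.bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones(self):
        assert np.allclose(dge.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            dge.bh_adjust([0.5, 1.5])

    def test_matches_step_up_oracle(self):
        """Independent step-up implementation: cumulative min of sorted p*m/i."""
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        oracle_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        assert np.allclose(dge.bh_adjust(p), oracle)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(size=25))
        adj = dge.bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()


def nb_counts(rng, mean, alpha, size):
    lam = rng.gamma(1 / alpha, np.maximum(mean, 1e-12) * alpha, size=size)
    return rng.poisson(lam)


class TestNbWaldTest:
    def test_identical_group_means_near_null(self):
        rng = np.random.default_rng(8)
        mu = np.full(300, 500.0)
        counts = matrix(
            np.column_stack([rng.poisson(mu) for _ in range(6)]),
        )
        res = dge.nb_wald_test(counts, ["a"] * 3 + ["b"] * 3)
        assert res["log2fc"].abs().median() < 0.05
        assert res["p_value"].median() > 0.2

    def test_twofold_recovery(self):
        """200 genes at an exact 2x shift, tight dispersion: median log2fc in
        [0.9, 1.1]."""
        rng = np.random.default_rng(9)
        mu = np.full(200, 1000.0)
        counts = matrix(np.column_stack(
            [nb_counts(rng, mu, 0.01, 200) for _ in range(3)]
            + [nb_counts(rng, 2 * mu, 0.01, 200) for _ in range(3)]
        ))
        res = dge.nb_wald_test(
            counts, ["a"] * 3 + ["b"] * 3,
            pd.Series(1.0, index=counts.columns),
        )
        assert 0.9 <= res["log2fc"].median() <= 1.1

    def test_all_zero_gene_reported_na(self):
        counts = matrix([[0, 0, 0, 0], [10, 12, 9, 11]])
        res = dge.nb_wald_test(counts, ["a", "a", "b", "b"],
                               pd.Series(1.0, index=counts.columns))
        assert res.loc[res["gene_id"] == "g0", "de_call"].iloc[0] == "na"
        assert np.isnan(res.loc[res["gene_id"] == "g0", "p_value"].iloc[0])

    def test_requires_two_groups_with_replicates(self):
        counts = matrix([[1, 2, 3]])
        with pytest.raises(ValueError):
            dge.nb_wald_test(counts, ["a", "a", "b"])


def brute_force_category(call_table, consistent_min=3):
    """Enumeration oracle for the five-way rule, one gene at a time."""
    lines = {}
    for (test, _), _ in call_table.items():
        lines.setdefault(test, [])
    for (test, control), call in call_table.items():
        lines[test].append(call)
    up = sum(1 for calls in lines.values() if all(c == "up" for c in calls))
    down = sum(1 for calls in lines.values() if all(c == "down" for c in calls))
    if up >= consistent_min and down == 0:
        return "consistently_up"
    if 1 <= up < consistent_min and down == 0:
        return "sporadically_up"
    if down >= consistent_min and up == 0:
        return "consistently_down"
    if 1 <= down < consistent_min and up == 0:
        return "sporadically_down"
    return "unchanged"


def calls_frame(per_gene):
    rows = []
    for gene, table in per_gene.items():
        for (test, control), call in table.items():
            rows.append((gene, test, control, call))
    return pd.DataFrame(rows, columns=["gene_id", "test_line", "control_line", "de_call"])


TESTS = [f"t{i}" for i in range(4)]
CONTROLS = ["c0", "c1"]


def table_from_calls(calls):
    return dict(zip(itertools.product(TESTS, CONTROLS), calls))


class TestCategorizeGenes:
    def test_paper_rule_examples(self):
        per_gene = {
            # up vs both controls in 3 of 4 lines, never down
            "cons_up": table_from_calls(
                ["up", "up", "up", "up", "up", "up", "ns", "ns"]),
            # up vs both controls in exactly one line
            "spor_up": table_from_calls(
                ["up", "up", "ns", "ns", "ns", "ns", "ns", "ns"]),
            # up vs control c0 only, in all lines -> unchanged
            "ctrl_conflict": table_from_calls(
                ["up", "ns", "up", "ns", "up", "ns", "up", "ns"]),
            # two lines up, one line down -> unchanged (cross-line conflict)
            "cross_conflict": table_from_calls(
                ["up", "up", "up", "up", "down", "down", "ns", "ns"]),
        }
        got = dge.categorize_genes(calls_frame(per_gene)).set_index("gene_id")
        assert got.loc["cons_up", "category"] == "consistently_up"
        assert got.loc["spor_up", "category"] == "sporadically_up"
        assert got.loc["ctrl_conflict", "category"] == "unchanged"
        assert got.loc["cross_conflict", "category"] == "unchanged"

    def test_missing_contrast_errors(self):
        frame = calls_frame({"g": table_from_calls(["up"] * 8)})
        with pytest.raises(ValueError, match="missing contrasts"):
            dge.categorize_genes(frame.iloc[:-1])

    def test_partition_property(self):
        rng = np.random.default_rng(12)
        per_gene = {
            f"g{i}": table_from_calls(rng.choice(["up", "down", "ns"], 8))
            for i in range(200)
        }
        got = dge.categorize_genes(calls_frame(per_gene))
        assert len(got) == 200
        assert set(got["category"]) <= set(dge.CATEGORIES)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        per_gene = {
            f"g{i}": table_from_calls(rng.choice(["up", "down", "ns"], 8))
            for i in range(300)
        }
        got = dge.categorize_genes(calls_frame(per_gene)).set_index("gene_id")
        for gene, table in per_gene.items():
            assert got.loc[gene, "category"] == brute_force_category(table), gene


class TestXciStatus:
    def test_absent_genes_undefined(self):
        ref = pd.DataFrame({"gene_id": ["g1"], "status": ["escape"]})
        got = dge.assign_xci_status(["g1", "g2"], ref)
        assert got["g1"] == "escape" and got["g2"] == "undefined"

    def test_empty_reference_all_undefined(self):
        ref = pd.DataFrame({"gene_id": [], "status": []})
        assert (dge.assign_xci_status(["g1"], ref) == "undefined").all()

    def test_duplicate_reference_errors(self):
        ref = pd.DataFrame({"gene_id": ["g1", "g1"], "status": ["escape", "inactive"]})
        with pytest.raises(ValueError, match="duplicate"):
            dge.assign_xci_status(["g1"], ref)


class TestCategoryEnrichment:
    def test_all_inactive(self):
        cats = pd.DataFrame({"gene_id": ["g1", "g2"],
                             "category": ["consistently_up", "unchanged"],
                             "n_lines_up": [4, 0], "n_lines_down": [0, 0]})
        statuses = pd.Series({"g1": "inactive", "g2": "inactive"})
        out = dge.category_enrichment(cats, statuses)
        assert (out["fraction"] == 1.0).all()

    def test_escape_fraction_like_study(self):
        """34 categorizable genes of which 12 escape -> 35.3%."""
        genes = [f"g{i}" for i in range(34)]
        cats = pd.DataFrame({"gene_id": genes, "category": "consistently_up",
                             "n_lines_up": 4, "n_lines_down": 0})
        statuses = pd.Series(
            {g: ("escape" if i < 12 else "inactive") for i, g in enumerate(genes)}
        )
        out = dge.category_enrichment(cats, statuses)
        esc = out[out["xci_status"] == "escape"].iloc[0]
        assert esc["count"] == 12
        assert esc["fraction"] == pytest.approx(12 / 34)
        assert round(100 * esc["fraction"], 1) == 35.3

    def test_undefined_excluded_from_denominator(self):
        cats = pd.DataFrame({"gene_id": ["g1", "g2"], "category": "unchanged",
                             "n_lines_up": 0, "n_lines_down": 0})
        statuses = pd.Series({"g1": "escape", "g2": "undefined"})
        out = dge.category_enrichment(cats, statuses)
        assert out.iloc[0]["n_defined_in_category"] == 1
        assert out.iloc[0]["fraction"] == 1.0


def test_high_susceptibility_genes_enriched_in_upregulated(small_truth, small_expression):
    """Generator-marked susceptible genes end up upregulated more often."""
    from xcierosion.simulate import annotation_frame

    counts, _, _ = small_expression
    ann = annotation_frame(small_truth)
    expressed = dge.filter_expressed(dge.tpm(counts, ann["length_bp"]))
    sample_lines = {s: s.rsplit("_r", 1)[0] for s in counts.columns}
    calls = dge.run_contrasts(
        counts.loc[expressed], sample_lines, ["line1_e0.9"], ["line0_e0"]
    )
    x_calls = calls[calls["gene_id"].str.startswith("XG")]
    up = set(x_calls.loc[x_calls["de_call"] == "up", "gene_id"])
    genes = small_truth.genes
    sus = genes["susceptibility"] > genes["susceptibility"].median()
    up_mask = genes.index.isin(up)
    if up_mask.any():
        odds_up = (sus & up_mask).sum() / max((~sus & up_mask).sum(), 1)
        odds_all = sus.sum() / (~sus).sum()
        assert odds_up > odds_all
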