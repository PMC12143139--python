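"""Simulation studies of the pipeline's operating characteristics.

Each function regenerates its inputs from a seed, runs the corresponding
pipeline operations, and measures a recovery/calibration quantity:
allelic-classification accuracy at known Xi shares, erosion-ranking
fidelity of the X:A and allelic-class proxies, categorization-rule
correctness against brute-force enumeration, NB-test calibration (type-I
error and BH false-discovery rate), the eroded-gene caller's operating
point, predictor-feature separation across gene categories, and UMI
deduplication accuracy. All problem sizes are chosen to finish on a single
CPU in seconds to a few minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ampseq, ase, dge, erosion, predictors
from .simulate import (
    SimConfig,
    annotation_frame,
    build_x_landscape,
    default_amplicon_panel,
    simulate_ampseq_reads,
    simulate_epitracks,
    simulate_expression,
)


def _seeds(seed: int, n: int) -> list[int]:
    """Derive independent child seeds below 2**31."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _truth_snps(truth):
    from .io_formats import PhasedSnp

    return [
        PhasedSnp(
            chrom=r.chrom, pos=r.pos, ref_allele=r.ref, alt_allele=r.alt,
            hapA_allele=(r.ref if r.alt_on_xi else r.alt),
            hapB_allele=(r.alt if r.alt_on_xi else r.ref),
            snp_id=r.snp_id, gene_id=r.gene_id,
        )
        for r in truth.snps.itertuples(index=False)
    ]


def _line_of(sample: str) -> str:
    return sample.rsplit("_r", 1)[0]


# ---------------------------------------------------------------------------
# allelic classification recovery at known Xi shares
# ---------------------------------------------------------------------------

def classification_recovery(seed: int, n_genes: int = 600) -> dict:
    """Classify genes generated at Xi shares {0, 0.25, 1.0} at depth >= 500.

    Share 0 must classify monoallelic, 0.25 intermediate (allele fraction
    0.2), 1.0 biallelic (balanced). Returns the fraction recovered.
    """
    per = n_genes // 3
    conditions = [
        (0.0, "monoallelic",
         dict(escape_frac=0.0, variable_frac=0.0, leak=0.0,
              erosion_degrees=(0.0,))),
        (0.25, "intermediate",
         dict(escape_frac=1.0, variable_frac=0.0,
              escape_xi_share_range=(0.25, 0.25), erosion_degrees=(0.0,))),
        (1.0, "biallelic",
         dict(escape_frac=1.0, variable_frac=0.0, erosion_degrees=(1.0,))),
    ]
    correct = total = 0
    for child, (share, expected, overrides) in zip(_seeds(seed, 3), conditions):
        cfg = SimConfig(
            n_x_genes=per, n_autosomal_genes=10, n_replicates=1,
            mean_depth_per_gene=6000, mean_snps_per_gene=1.5,
            seed=child, **overrides,
        )
        truth = build_x_landscape(cfg)
        _, allelic, _ = simulate_expression(truth)
        profiles = ase.profiles_from_counts(allelic, _truth_snps(truth))
        pooled = ase.pool_profiles(profiles, min_depth=500)
        det = pooled[pooled["allelic_class"] != "undetermined"]
        correct += int((det["allelic_class"] == expected).sum())
        total += len(det)
    return {"fraction_correct": correct / total, "n": total}


# ---------------------------------------------------------------------------
# erosion ordering across synthetic lines
# ---------------------------------------------------------------------------

def erosion_ordering(
    seed: int,
    degrees: tuple[float, ...] = (0.0, 0.1, 0.3, 0.6, 1.0),
) -> dict:
    """Rank 5 synthetic lines by X:A ratio and biallelic fraction.

    Returns the Spearman correlation of each proxy with the true erosion
    degrees (3 replicates per line, pooled allelic profiles per line).
    """
    cfg = SimConfig(erosion_degrees=degrees, n_replicates=3, seed=_seeds(seed, 1)[0])
    truth = build_x_landscape(cfg)
    counts, allelic, _ = simulate_expression(truth)
    ann = annotation_frame(truth)
    summary = erosion.x_autosome_ratio(counts, ann)
    summary["line"] = summary["sample"].map(_line_of)
    xa = summary.groupby("line")["xa_ratio"].mean()

    profiles = ase.profiles_from_counts(allelic, _truth_snps(truth))
    frac_bi = {}
    for line in truth.lines["line"]:
        pooled = ase.pool_profiles(
            profiles[profiles["sample"].map(_line_of) == line]
        )
        det = pooled[pooled["allelic_class"] != "undetermined"]
        frac_bi[line] = float((det["allelic_class"] == "biallelic").mean())

    lines = list(truth.lines["line"])
    e = list(truth.lines["erosion"])
    rho_xa = float(stats.spearmanr(e, [xa[l] for l in lines]).statistic)
    rho_bi = float(stats.spearmanr(e, [frac_bi[l] for l in lines]).statistic)
    return {
        "rho_xa": rho_xa,
        "rho_biallelic": rho_bi,
        "n_lines": len(lines),
        "frac_biallelic": [frac_bi[l] for l in lines],
    }


# ---------------------------------------------------------------------------
# categorization vs brute-force enumeration
# ---------------------------------------------------------------------------

def _brute_force_category(per_line_calls: dict[str, list[str]],
                          consistent_min: int = 3) -> str:
    up = sum(1 for c in per_line_calls.values() if all(v == "up" for v in c))
    down = sum(1 for c in per_line_calls.values() if all(v == "down" for v in c))
    if up >= consistent_min and down == 0:
        return "consistently_up"
    if 1 <= up < consistent_min and down == 0:
        return "sporadically_up"
    if down >= consistent_min and up == 0:
        return "consistently_down"
    if 1 <= down < consistent_min and up == 0:
        return "sporadically_down"
    return "unchanged"


def categorization_oracle(seed: int, n_tables: int = 1000) -> dict:
    """Random 4-test-line x 2-control call tables vs rule enumeration."""
    rng = np.random.default_rng(seed)
    tests = [f"t{i}" for i in range(4)]
    controls = ["c0", "c1"]
    rows = []
    expected = {}
    for i in range(n_tables):
        gene = f"g{i:04d}"
        calls = rng.choice(["up", "down", "ns"], size=(4, 2))
        per_line = {t: list(calls[j]) for j, t in enumerate(tests)}
        expected[gene] = _brute_force_category(per_line)
        for j, t in enumerate(tests):
            for k, c in enumerate(controls):
                rows.append((gene, t, c, calls[j, k]))
    frame = pd.DataFrame(
        rows, columns=["gene_id", "test_line", "control_line", "de_call"]
    )
    got = dge.categorize_genes(frame).set_index("gene_id")["category"]
    agree = sum(got[g] == expected[g] for g in expected)
    return {"fraction_agreement": agree / n_tables, "n": n_tables}


# ---------------------------------------------------------------------------
# NB test calibration
# ---------------------------------------------------------------------------

def nb_calibration(
    seed: int,
    n_genes: int = 10_000,
    dispersion: float = 0.01,
    mean_depth: float = 1000.0,
) -> dict:
    """Type-I error on a null 3v3 design and empirical FDR with 10% true
    genes at log2fc = 1 under BH selection at nominal 0.05."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mean_depth), 1.0, n_genes)

    def nb(mean):
        lam = rng.gamma(1 / dispersion, np.maximum(mean, 1e-12) * dispersion)
        return rng.poisson(lam)

    samples = [f"s{i}" for i in range(6)]
    groups = ["ctl"] * 3 + ["test"] * 3
    null = pd.DataFrame(
        np.column_stack([nb(mu) for _ in range(6)]),
        index=[f"g{i}" for i in range(n_genes)], columns=samples,
    )
    res0 = dge.nb_wald_test(null, groups)
    p0 = res0["p_value"].dropna()
    type1 = float((p0 < 0.05).mean())

    true = rng.random(n_genes) < 0.10
    mu_alt = mu * np.where(true, 2.0, 1.0)
    alt = pd.DataFrame(
        np.column_stack([nb(mu) for _ in range(3)] + [nb(mu_alt) for _ in range(3)]),
        index=null.index, columns=samples,
    )
    res1 = dge.nb_wald_test(alt, groups)
    sel = (res1["adjusted_p"] < 0.05).to_numpy()
    n_sel = int(sel.sum())
    fdr = float((sel & ~true).sum() / n_sel) if n_sel else 0.0
    power = float((sel & true).sum() / true.sum())
    return {"type_i_error": type1, "fdr": fdr, "power": power,
            "n_selected": n_sel, "n": n_genes}


# ---------------------------------------------------------------------------
# eroded-gene caller operating point
# ---------------------------------------------------------------------------

def eroded_call_operating_point(
    seed: int, n_null: int = 500, n_true: int = 500, depth: int = 200
) -> dict:
    """Sensitivity and false-positive rate at true delta-MAF 0.25 vs 0."""
    rng = np.random.default_rng(seed)
    maf_ref = np.concatenate([
        rng.uniform(0.0, 0.20, n_null), rng.uniform(0.0, 0.20, n_true)
    ])
    delta = np.concatenate([np.zeros(n_null), np.full(n_true, 0.25)])
    maf_test = maf_ref + delta

    def draw(p):
        minor = rng.binomial(depth, p)
        return ase.build_profiles(pd.DataFrame({
            "sample": "s",
            "gene_id": [f"g{i}" for i in range(len(p))],
            "hapA": depth - minor, "hapB": minor,
        }))

    calls = erosion.call_eroded_genes(draw(maf_ref), draw(maf_test))
    calls = calls.set_index("gene_id")
    called = np.array([
        bool(calls.loc[f"g{i}", "eroded"]) for i in range(n_null + n_true)
    ])
    truth = delta > 0
    return {
        "sensitivity": float(called[truth].mean()),
        "false_positive_rate": float(called[~truth].mean()),
        "n": n_null + n_true,
    }


# ---------------------------------------------------------------------------
# predictor structure end-to-end
# ---------------------------------------------------------------------------

def predictor_structure(seed: int, n_x_genes: int = 1500) -> dict:
    """Full pipeline: DE, categorization, features, category contrasts.

    The gene panel is sized so the consistently-up group reaches the
    40-gene scale; returns the extreme-pair (consistently-up vs unchanged)
    p-values for escapee distance and H3K27me3 body signal.
    """
    cfg = SimConfig(
        n_x_genes=n_x_genes, n_autosomal_genes=2 * n_x_genes,
        seed=_seeds(seed, 1)[0],
    )
    truth = build_x_landscape(cfg)
    counts, _, _ = simulate_expression(truth)
    ann = annotation_frame(truth)
    expressed = dge.filter_expressed(dge.tpm(counts, ann["length_bp"]))
    sample_lines = {s: _line_of(s) for s in counts.columns}
    xist_neg = [l for l, e in zip(truth.lines["line"], truth.lines["erosion"]) if e > 0]
    xist_pos = [l for l, e in zip(truth.lines["line"], truth.lines["erosion"]) if e == 0]
    calls = dge.run_contrasts(counts.loc[expressed], sample_lines, xist_neg, xist_pos)
    x_calls = calls[calls["gene_id"].str.startswith("XG")]
    cats = dge.categorize_genes(
        x_calls[["gene_id", "test_line", "control_line", "de_call"]]
    )

    x_ann = ann[ann["chrom"] == "chrX"].drop("XIST")
    genes_df = x_ann.loc[[g for g in cats["gene_id"] if g in x_ann.index]]
    esc = predictors.upregulated_escapees(cats, x_ann["status"])
    feats = pd.DataFrame(index=genes_df.index)
    feats["dist_to_escapee"] = predictors.nearest_escapee_distance(
        genes_df, x_ann.loc[esc]
    )
    tracks, _ = simulate_epitracks(truth)
    matrix, _ = predictors.metagene_profile(tracks["XIST+"], genes_df)
    feats["k27_meta"] = predictors.gene_body_k27(matrix)
    tests = predictors.category_feature_tests(feats, cats)

    extreme = tests[
        (tests["group_a"] == "consistently_up") & (tests["group_b"] == "unchanged")
    ].set_index("feature")
    sizes = cats["category"].value_counts()
    return {
        "p_distance": float(extreme.loc["dist_to_escapee", "p_value"]),
        "p_k27": float(extreme.loc["k27_meta", "p_value"]),
        "n_consistently_up": int(sizes.get("consistently_up", 0)),
        "n_unchanged": int(sizes.get("unchanged", 0)),
        "n": int(len(cats)),
    }


# ---------------------------------------------------------------------------
# UMI deduplication accuracy
# ---------------------------------------------------------------------------

def umi_dedup_accuracy(
    seed: int, n_amplicons: int = 12, n_replicate_sets: int = 8
) -> dict:
    """Exact-mode recovery on clean reads; directional error with 1% noise.

    Clean reads must reproduce the truth table exactly per (amplicon,
    allele). Under a 1% per-base error on the UMI and SNP base, the
    directional mode's total identified molecules (allele assignment is a
    separate step) are compared to truth; the relative error is averaged
    over ``n_replicate_sets`` independent read sets to estimate the mode's
    bias rather than a single panel's sampling noise.
    """
    children = _seeds(seed, n_replicate_sets + 1)

    def run(error_rate, child_seed):
        cfg = SimConfig(
            n_x_genes=60, n_autosomal_genes=10,
            ampseq_error_rate=error_rate, mean_snps_per_gene=2.0,
            seed=child_seed,
        )
        truth = build_x_landscape(cfg)
        panel = default_amplicon_panel(truth, n_amplicons)
        rs = simulate_ampseq_reads(truth, panel)
        records, _ = ampseq.process_reads(
            list(rs.reads.itertuples(index=False, name=None)), panel
        )
        return rs.truth_molecules, records

    truth_clean, rec_clean = run(0.0, children[0])
    exact = ampseq.dedup_molecules(rec_clean, "exact")
    merged = exact.merge(
        truth_clean, on=["amplicon_id", "allele"], how="outer",
        suffixes=("_obs", "_true"),
    ).fillna(0)
    merged = merged[merged["allele"].isin(["ref", "alt"])]
    exact_match = float(
        (merged["molecules_obs"] == merged["molecules_true"]).mean()
    )

    rel_errors = []
    n_total = 0
    for child in children[1:]:
        truth_err, rec_err = run(0.01, child)
        directional = ampseq.dedup_molecules(rec_err, "directional")
        obs = int(directional["molecules"].sum())
        want = int(truth_err["molecules"].sum())
        rel_errors.append((obs - want) / want)
        n_total += want
    return {
        "exact_match_fraction": exact_match,
        "directional_relative_error": float(abs(np.mean(rel_errors))),
        "n_molecules": n_total,
    }


# ---------------------------------------------------------------------------
# deterministic exact statistics
# ---------------------------------------------------------------------------

def exact_statistics() -> dict:
    """Closed-form checks: exact Mann-Whitney p and the BH step-up."""
    mw = predictors.mann_whitney_u([1, 2, 3], [4, 5, 6])
    bh = dge.bh_adjust([0.01, 0.02, 0.03, 0.04])
    return {
        "mw_exact_p_n3": float(mw.p_value),
        "bh_adjusted_max": float(np.max(bh)),
        "bh_all_equal": bool(np.allclose(bh, bh[0])),
    }
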