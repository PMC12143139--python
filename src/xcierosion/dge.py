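"""Minimal negative-binomial differential expression and gene categorization.

The DE stage is a deliberately small stand-in for a full NB GLM tool:
median-of-ratios size factors, per-gene method-of-moments dispersion shrunk
50/50 toward a mean-dispersion trend, and a Wald test on the log ratio of
group means. It does no outlier handling, independent filtering or logFC
shrinkage, so gene counts will not match a full DE tool at equality; the
calls feed the consistency-based five-way categorization, which is the
substantive rule here.

Categorization: against a panel of control lines, a test line "counts as
up" for a gene only when the gene is significantly up versus EVERY control.
With U up-lines and D down-lines out of four test lines: U >= 3 and D = 0 is
consistently upregulated, U in {1, 2} and D = 0 sporadically upregulated
(symmetric for down), and anything else — including cross-line conflicts —
is unchanged.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LOG2FC_THRESHOLD = 0.33
ALPHA = 0.05
CATEGORIES = (
    "consistently_up",
    "sporadically_up",
    "consistently_down",
    "sporadically_down",
    "unchanged",
)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios scaling factors.

    factor_s = median over all-positive genes of count_{g,s} / geomean_g.
    Genes with any zero count are excluded from the medians.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene with all counts positive; consider a pseudo-reference fallback"
        )
    log_mat = np.log(mat[positive])
    log_geomean = log_mat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_mat - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates summing to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"genes without length: {missing[:5]} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        log.warning("sample(s) with all-zero counts: %s",
                    totals.index[totals == 0].tolist())
        totals = totals.replace(0, np.nan)
    out = rates.div(totals, axis=1) * 1e6
    return out.fillna(0.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu across genes (least squares, coefs clipped >= 0)."""
    ok = (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 10:
        fallback = float(np.nanmedian(alpha_mom[ok])) if ok.any() else 0.1
        return np.full_like(mu, max(fallback, 1e-8))
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(design, alpha_mom[ok], rcond=None)
    a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    return a0 + a1 / np.maximum(mu, 1e-8)


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    factors: pd.Series | None = None,
    lfc_threshold: float = LOG2FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Two-group NB Wald test on size-factor-normalized counts.

    Per gene: group means of normalized counts q0, q1; dispersion by the
    method of moments shrunk 50/50 toward the fitted trend; Wald statistic
    on beta = ln(q1/q0) with delta-method variance, referred to a moderated
    Student-t with 3*(n0 + n1 - 2) df; BH adjustment across tested genes. Genes with all-zero counts in both
    groups are reported with NA statistics and no call.
    """
    groups = pd.Series(list(groups), index=counts.columns)
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    g0, g1 = levels  # g0 = reference/control
    n0, n1 = int((groups == g0).sum()), int((groups == g1).sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("need >= 2 replicates per group")
    if factors is None:
        factors = size_factors(counts)
    sf = factors.reindex(counts.columns).to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / sf

    m0 = norm[:, (groups == g0).to_numpy()]
    m1 = norm[:, (groups == g1).to_numpy()]
    q0, q1 = m0.mean(axis=1), m1.mean(axis=1)
    tested = (q0 + q1) > 0

    # method-of-moments dispersion on normalized counts, pooled within groups
    c1 = float(np.mean(1.0 / sf))
    within_var = (
        m0.var(axis=1, ddof=1) * (n0 - 1) + m1.var(axis=1, ddof=1) * (n1 - 1)
    ) / (n0 + n1 - 2)
    q_pool = (q0 * n0 + q1 * n1) / (n0 + n1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (within_var - q_pool * c1) / q_pool**2
    alpha_mom = np.clip(alpha_mom, 1e-8, 10.0)
    trend = _dispersion_trend(q_pool, np.where(tested, alpha_mom, np.nan))
    disp = 0.5 * alpha_mom + 0.5 * trend

    # Wald on beta = ln(q1/q0), half-count stabilization for zero group means
    inv0 = float(np.mean(1.0 / sf[(groups == g0).to_numpy()]))
    inv1 = float(np.mean(1.0 / sf[(groups == g1).to_numpy()]))
    q0s = np.where(q0 > 0, q0, 0.5 / n0)
    q1s = np.where(q1 > 0, q1, 0.5 / n1)
    beta = np.log(q1s) - np.log(q0s)
    var_q0 = (q0s * inv0 + disp * q0s**2) / n0
    var_q1 = (q1s * inv1 + disp * q1s**2) / n1
    var_beta = var_q0 / q0s**2 + var_q1 / q1s**2
    # moderated-t reference: the trend-shrunk dispersion behaves like extra
    # residual information, so the tail is lighter than t(n-2) but heavier
    # than normal; 3x the residual df calibrates both the 5% level and the
    # far tail for triplicate designs and tends to normal with replication.
    wald = beta / np.sqrt(var_beta)
    p = 2.0 * stats.t.sf(np.abs(wald), df=3 * (n0 + n1 - 2))

    log2fc = beta / np.log(2.0)
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": q_pool,
            "log2fc": np.where(tested, log2fc, np.nan),
            "dispersion": np.where(tested, disp, np.nan),
            "stat": np.where(tested, wald, np.nan),
            "p_value": np.where(tested, p, np.nan),
        }
    )
    padj = np.full(len(out), np.nan)
    padj[tested] = bh_adjust(out.loc[tested, "p_value"].to_numpy())
    out["adjusted_p"] = padj
    calls = np.full(len(out), "ns", dtype=object)
    sig = tested & (padj < alpha)
    calls[sig & (out["log2fc"].to_numpy() > lfc_threshold)] = "up"
    calls[sig & (out["log2fc"].to_numpy() < -lfc_threshold)] = "down"
    calls[~tested] = "na"
    out["de_call"] = calls
    return out


def run_contrasts(
    counts: pd.DataFrame,
    sample_lines: Mapping[str, str],
    test_lines: Sequence[str],
    control_lines: Sequence[str],
    lfc_threshold: float = LOG2FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run every (test line, control line) contrast; one DE table, labeled.

    Size factors are estimated once on the full matrix so contrasts share a
    normalization, then each contrast tests its two lines' replicates.
    """
    factors = size_factors(counts)
    lines = pd.Series({s: sample_lines[s] for s in counts.columns})
    tables = []
    for test in test_lines:
        for control in control_lines:
            cols = lines[lines.isin([control, test])].index.tolist()
            sub = counts[cols]
            res = nb_wald_test(
                sub,
                lines[cols],
                factors[cols],
                lfc_threshold=lfc_threshold,
                alpha=alpha,
            )
            res.insert(1, "test_line", test)
            res.insert(2, "control_line", control)
            tables.append(res)
    return pd.concat(tables, ignore_index=True)


def categorize_genes(
    calls: pd.DataFrame,
    consistent_min: int = 3,
) -> pd.DataFrame:
    """Five-way consistency categorization from per-contrast DE calls.

    ``calls`` needs columns gene_id, test_line, control_line, de_call; every
    (test, control) pair must be present for every gene ("ns" where not
    significant). A test line counts as up/down only when the call agrees
    against every control line. Cross-line conflicts (U > 0 and D > 0) and
    U = D = 0 are unchanged.
    """
    required = {"gene_id", "test_line", "control_line", "de_call"}
    if not required <= set(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    test_lines = sorted(calls["test_line"].unique())
    control_lines = sorted(calls["control_line"].unique())
    n_pairs = len(test_lines) * len(control_lines)
    sizes = calls.groupby("gene_id").size()
    bad = sizes[sizes != n_pairs]
    if len(bad):
        raise ValueError(
            f"missing contrasts for gene(s) {bad.index.tolist()[:5]}: "
            f"expected {n_pairs} rows per gene"
        )
    dup = calls.duplicated(["gene_id", "test_line", "control_line"])
    if dup.any():
        raise ValueError("duplicated (gene, test, control) rows")

    # per (gene, test line): up iff up against EVERY control; ditto down
    pivot = calls.pivot_table(
        index=["gene_id", "test_line"],
        columns="control_line",
        values="de_call",
        aggfunc="first",
    )
    all_up = (pivot == "up").all(axis=1)
    all_down = (pivot == "down").all(axis=1)
    per_gene = pd.DataFrame({"up": all_up, "down": all_down}).groupby("gene_id").sum()

    u = per_gene["up"].astype(int)
    d = per_gene["down"].astype(int)
    category = np.full(len(per_gene), "unchanged", dtype=object)
    category[(u >= consistent_min) & (d == 0)] = "consistently_up"
    category[(u >= 1) & (u < consistent_min) & (d == 0)] = "sporadically_up"
    category[(d >= consistent_min) & (u == 0)] = "consistently_down"
    category[(d >= 1) & (d < consistent_min) & (u == 0)] = "sporadically_down"
    return pd.DataFrame(
        {
            "gene_id": per_gene.index,
            "category": category,
            "n_lines_up": u.to_numpy(),
            "n_lines_down": d.to_numpy(),
        }
    )


def assign_xci_status(
    genes: Sequence[str] | pd.Index, reference: pd.DataFrame
) -> pd.Series:
    """Join the reference XCI status table; absent genes become 'undefined'."""
    if reference["gene_id"].duplicated().any():
        dup = reference.loc[reference["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene in reference: {dup}")
    lookup = reference.set_index("gene_id")["status"]
    return pd.Series(
        [lookup.get(g, "undefined") for g in genes], index=list(genes), name="xci_status"
    )


def category_enrichment(
    categories: pd.DataFrame, statuses: pd.Series
) -> pd.DataFrame:
    """Per (category x XCI status) counts and within-category fractions.

    Fractions are computed over genes with a defined status only; empty
    categories are absent from the output.
    """
    df = categories.copy()
    df["xci_status"] = statuses.reindex(df["gene_id"]).to_numpy()
    rows = []
    for cat, sub in df.groupby("category"):
        defined = sub[sub["xci_status"] != "undefined"]
        n_def = len(defined)
        for status, cnt in defined["xci_status"].value_counts().items():
            rows.append(
                {
                    "category": cat,
                    "xci_status": status,
                    "count": int(cnt),
                    "n_defined_in_category": n_def,
                    "fraction": cnt / n_def,
                }
            )
    return pd.DataFrame(rows, columns=[
        "category", "xci_status", "count", "n_defined_in_category", "fraction"
    ])


def filter_expressed(
    tpm_table: pd.DataFrame, min_mean_tpm: float = 1.0
) -> pd.Index:
    """Expressed-gene filter: mean TPM across all samples >= threshold."""
    return tpm_table.index[tpm_table.mean(axis=1) >= min_mean_tpm]
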