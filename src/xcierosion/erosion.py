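"""Line-level erosion proxies and isogenic-pair eroded-gene calls.

The X:autosome read ratio (summed raw counts of X genes over autosomal
genes) is the per-sample erosion proxy; group differences are assessed with
a two-sample t test plus Cohen's d. Within an isogenic pair, a gene is
called eroded when its MAF rises by at least 0.10 (absolute) from the less
to the more eroded line.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneAnnotation

log = logging.getLogger(__name__)

ERODED_DELTA_MAF = 0.10

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
_X_NAMES = {"chrX", "X"}


def _chrom_map(annotation) -> Mapping[str, str]:
    if isinstance(annotation, pd.DataFrame):
        return dict(zip(annotation.index, annotation["chrom"]))
    return {g.gene_id: g.chrom for g in annotation}


def x_autosome_ratio(
    counts: pd.DataFrame,
    annotation: pd.DataFrame | Sequence[GeneAnnotation],
    exclude_xist: bool = False,
) -> pd.DataFrame:
    """Per-sample X and autosomal read totals and their ratio.

    Genes on other chromosomes (Y, MT, ...) are excluded from both sums.
    ``exclude_xist`` drops the XIST gene from the X total (the lncRNA falls
    with erosion while the rest of the chromosome rises).
    """
    chrom = _chrom_map(annotation)
    missing = [g for g in counts.index if g not in chrom]
    if missing:
        raise ValueError(f"genes without chromosome assignment: {missing[:5]} ...")
    chroms = pd.Series([chrom[g] for g in counts.index], index=counts.index)
    x_mask = chroms.isin(_X_NAMES)
    if exclude_xist:
        x_mask &= counts.index != "XIST"
    a_mask = chroms.isin(_AUTOSOMES)
    x_reads = counts[x_mask].sum(axis=0)
    a_reads = counts[a_mask].sum(axis=0)
    if (a_reads == 0).any():
        bad = a_reads.index[a_reads == 0].tolist()
        raise ValueError(f"zero autosomal total for sample(s) {bad}")
    return pd.DataFrame(
        {
            "sample": counts.columns,
            "x_reads": x_reads.to_numpy(),
            "autosomal_reads": a_reads.to_numpy(),
            "xa_ratio": (x_reads / a_reads).to_numpy(),
        }
    )


def allelic_class_fractions(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions of mono/intermediate/biallelic over determined genes."""
    rows = []
    for sample, sub in profiles.groupby("sample"):
        det = sub[sub["allelic_class"] != "undetermined"]
        n = len(det)
        rows.append(
            {
                "sample": sample,
                "n_determined": n,
                "frac_monoallelic": (det["allelic_class"] == "monoallelic").sum() / n if n else np.nan,
                "frac_intermediate": (det["allelic_class"] == "intermediate").sum() / n if n else np.nan,
                "frac_biallelic": (det["allelic_class"] == "biallelic").sum() / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def erosion_summary(
    counts: pd.DataFrame,
    annotation,
    profiles: pd.DataFrame | None = None,
    exclude_xist: bool = False,
) -> pd.DataFrame:
    """X:A ratio per sample, joined with allelic-class fractions when given."""
    summary = x_autosome_ratio(counts, annotation, exclude_xist=exclude_xist)
    if profiles is not None and len(profiles):
        summary = summary.merge(allelic_class_fractions(profiles), on="sample", how="left")
    return summary


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Pooled-SD effect size (mean_b - mean_a) / s_pooled."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    pooled_var = (
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled_var == 0:
        raise ValueError("zero pooled SD: Cohen's d is undefined")
    return float((b.mean() - a.mean()) / np.sqrt(pooled_var))


def compare_erosion_groups(
    ratios_a: Sequence[float],
    ratios_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t test (pooled by default) plus Cohen's d between line groups."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    d = cohens_d(a, b)
    t, p = stats.ttest_ind(b, a, equal_var=not welch)
    return float(t), float(p), d


def call_eroded_genes(
    profiles_reference: pd.DataFrame,
    profiles_test: pd.DataFrame,
    threshold: float = ERODED_DELTA_MAF,
) -> pd.DataFrame:
    """Eroded-gene calls for an isogenic pair: delta MAF >= threshold.

    Only genes determined (depth filter passed) in both lines are compared;
    the delta is the absolute increase in MAF from reference to test.
    """
    ref = profiles_reference[profiles_reference["allelic_class"] != "undetermined"]
    test = profiles_test[profiles_test["allelic_class"] != "undetermined"]
    merged = ref.merge(
        test, on="gene_id", suffixes=("_ref", "_test"), how="inner"
    )
    if merged.empty:
        log.warning("no shared determined genes between the two lines")
        return pd.DataFrame(
            columns=["gene_id", "maf_reference", "maf_test", "delta_maf", "eroded"]
        )
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "maf_reference": merged["maf_ref"],
            "maf_test": merged["maf_test"],
        }
    )
    out["delta_maf"] = out["maf_test"] - out["maf_reference"]
    out["eroded"] = out["delta_maf"] >= threshold
    return out


def persistence_comparison(
    profiles_state1: pd.DataFrame, profiles_state2: pd.DataFrame
) -> pd.DataFrame:
    """Pair MAF and allelic class across two states (e.g. D0 vs D7)."""
    s1 = profiles_state1[profiles_state1["allelic_class"] != "undetermined"]
    s2 = profiles_state2[profiles_state2["allelic_class"] != "undetermined"]
    merged = s1.merge(s2, on="gene_id", suffixes=("_1", "_2"), how="inner")
    if merged.empty:
        log.warning("no shared determined genes between the two states")
    out = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "maf_1": merged["maf_1"],
            "maf_2": merged["maf_2"],
            "class_1": merged["allelic_class_1"],
            "class_2": merged["allelic_class_2"],
        }
    )
    out["changed"] = out["class_1"] != out["class_2"]
    return out
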