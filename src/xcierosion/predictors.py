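"""Reactivation-predictor features and their comparisons across categories.

Features per gene: distance to the nearest upregulated escapee (bp; 0 for
overlapping/bookended intervals and for the escapees themselves), mean
H3K27me3 metagene signal over the scaled gene body, promoter methylation in
reference and eroded states with their delta, and membership of the
reactivation-prone bands (Xp22, Xq22-q23). Category contrasts use
Mann-Whitney for distances and two-sample t tests for signal/methylation,
with Cohen's d alongside.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .erosion import cohens_d
from .io_formats import GeneAnnotation, SignalTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatResult:
    statistic: str
    value: float
    p_value: float | None
    n_x: int
    n_y: int


def _intervals(genes) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        return genes
    return pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [getattr(g, "strand", "+") for g in genes],
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )


def nearest_escapee_distance(
    genes: pd.DataFrame | Sequence[GeneAnnotation],
    escapees: pd.DataFrame | Sequence[GeneAnnotation],
) -> pd.Series:
    """Distance (bp) from each gene to the nearest upregulated escapee.

    0-based half-open intervals; overlap or bookending gives 0, otherwise
    the gap between the closer ends. A gene that is itself in the escapee
    set gets 0. Strand is ignored.
    """
    g = _intervals(genes)
    e = _intervals(escapees)
    if e.empty:
        raise ValueError("empty escapee set")
    out = pd.Series(np.nan, index=g.index, name="dist_to_escapee")
    for chrom, sub in g.groupby("chrom"):
        esc = e[e["chrom"] == chrom]
        if esc.empty:
            continue
        es = esc["start"].to_numpy()
        ee = esc["end"].to_numpy()
        for gene_id, row in sub.iterrows():
            s, en = int(row["start"]), int(row["end"])
            overlap = (es < en) & (ee > s)
            gaps = np.where(overlap, 0, np.maximum(es - en, s - ee))
            out[gene_id] = float(np.maximum(gaps, 0).min())
    return out


def metagene_profile(
    track: SignalTrack,
    genes: pd.DataFrame | Sequence[GeneAnnotation],
    body_length: int = 5000,
    bin_size: int = 1000,
    flank: int = 5000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Binned signal over scaled gene bodies with fixed flanks.

    Each gene body is linearly rescaled to ``body_length`` and split into
    ``body_length / bin_size`` bins (each body bin maps back to an equal
    fraction of the real gene); flanks are taken in real coordinates. Bin
    values are coverage-weighted means of the track (uncovered bp count as
    0). Minus-strand genes are flipped so the profile reads 5' to 3'.
    Returns (per-gene matrix, mean profile across genes with signal).
    """
    if flank % bin_size or body_length % bin_size:
        raise ValueError("bin size must divide flank and body lengths")
    g = _intervals(genes)
    n_flank = flank // bin_size
    n_body = body_length // bin_size
    n_bins = 2 * n_flank + n_body
    labels = (
        [f"up_{i}" for i in range(n_flank)]
        + [f"body_{i}" for i in range(n_body)]
        + [f"down_{i}" for i in range(n_flank)]
    )
    rows = np.full((len(g), n_bins), np.nan)
    for i, (gene_id, row) in enumerate(g.iterrows()):
        chrom = str(row["chrom"])
        if chrom not in track.chromosomes:
            log.warning("%s: chromosome %s absent from track", gene_id, chrom)
            continue
        s, e = int(row["start"]), int(row["end"])
        bounds = []
        for b in range(n_flank):  # upstream, real coordinates
            bounds.append((s - flank + b * bin_size, s - flank + (b + 1) * bin_size))
        for b in range(n_body):  # body, equal real fractions
            lo = s + round((e - s) * b / n_body)
            hi = s + round((e - s) * (b + 1) / n_body)
            bounds.append((lo, max(hi, lo + 1)))
        for b in range(n_flank):  # downstream
            bounds.append((e + b * bin_size, e + (b + 1) * bin_size))
        vals = [
            track.window_mean(chrom, max(lo, 0), hi) if hi > 0 else 0.0
            for lo, hi in bounds
        ]
        if str(row.get("strand", "+")) == "-":
            vals = vals[::-1]
        rows[i] = vals
    matrix = pd.DataFrame(rows, index=g.index, columns=labels)
    return matrix, matrix.mean(axis=0, skipna=True)


def gene_body_k27(matrix: pd.DataFrame) -> pd.Series:
    """Mean metagene signal over the body bins, per gene."""
    body_cols = [c for c in matrix.columns if c.startswith("body_")]
    return matrix[body_cols].mean(axis=1).rename("k27_meta")


def promoter_methylation_delta(
    beta_ref: pd.DataFrame,
    beta_eroded: pd.DataFrame,
    genes: pd.DataFrame | Sequence[GeneAnnotation],
    window: int = 1000,
) -> pd.DataFrame:
    """Per-gene mean promoter beta in each state and their difference.

    The promoter is [TSS - window, TSS + window) with a strand-aware TSS
    (interval start for + genes, end for - genes). Genes without probes in
    the window get NA.
    """
    g = _intervals(genes)
    rows = []
    for gene_id, row in g.iterrows():
        tss = int(row["start"]) if str(row.get("strand", "+")) == "+" else int(row["end"])
        lo, hi = tss - window, tss + window
        vals = {}
        for name, table in (("ref", beta_ref), ("eroded", beta_eroded)):
            sel = table[
                (table["chrom"] == row["chrom"])
                & (table["pos"] >= lo)
                & (table["pos"] < hi)
            ]
            vals[name] = float(sel["beta"].mean()) if len(sel) else np.nan
        rows.append(
            {
                "gene_id": gene_id,
                "promoter_beta_ref": vals["ref"],
                "promoter_beta_eroded": vals["eroded"],
                "delta_beta": vals["ref"] - vals["eroded"],
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 400
) -> StatResult:
    """Mann-Whitney U with midranks; exact p by enumeration for small
    tie-free samples (n_x * n_y <= exact_limit), else the tie-corrected
    normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(np.unique(np.concatenate([x, y]))) == 1:
        # all values identical: the tie-corrected statistic is 0
        return StatResult("mann_whitney_U", float(len(x) * len(y) / 2), 1.0, len(x), len(y))
    method = "exact" if (not has_ties and len(x) * len(y) <= exact_limit) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StatResult("mann_whitney_U", float(res.statistic), float(res.pvalue), len(x), len(y))


def category_feature_tests(
    features: pd.DataFrame,
    categories: pd.DataFrame,
    category_order: Sequence[str] = (
        "consistently_up", "sporadically_up", "unchanged",
    ),
) -> pd.DataFrame:
    """Pairwise category contrasts for each predictor feature.

    Distances use Mann-Whitney; metagene signal and methylation delta use
    an unpaired two-sample t test; Cohen's d accompanies every pair.
    Degenerate groups (< 2 members or zero pooled SD) yield NA rows.
    """
    merged = categories.merge(
        features, left_on="gene_id", right_index=True, how="inner"
    )
    feature_tests = {
        "dist_to_escapee": "mann_whitney",
        "k27_meta": "t",
        "delta_beta": "t",
    }
    rows = []
    for feat, test in feature_tests.items():
        if feat not in merged.columns:
            continue
        for cat_a, cat_b in itertools.combinations(category_order, 2):
            a = merged.loc[merged["category"] == cat_a, feat].dropna().to_numpy()
            b = merged.loc[merged["category"] == cat_b, feat].dropna().to_numpy()
            row = {
                "feature": feat, "group_a": cat_a, "group_b": cat_b,
                "n_a": len(a), "n_b": len(b),
                "test": test, "statistic": np.nan, "p_value": np.nan,
                "cohens_d": np.nan,
            }
            if len(a) >= 2 and len(b) >= 2:
                if test == "mann_whitney":
                    res = mann_whitney_u(a, b)
                    row["statistic"], row["p_value"] = res.value, res.p_value
                else:
                    t, p = stats.ttest_ind(a, b)
                    row["statistic"], row["p_value"] = float(t), float(p)
                try:
                    row["cohens_d"] = cohens_d(b, a)  # positive when a > b
                except ValueError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)


def upregulated_escapees(
    categories: pd.DataFrame, statuses: pd.Series
) -> list[str]:
    """Escape-status genes called consistently or sporadically upregulated."""
    up = categories[
        categories["category"].isin(["consistently_up", "sporadically_up"])
    ]["gene_id"]
    return [g for g in up if statuses.get(g) == "escape"]
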