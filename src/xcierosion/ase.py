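"""Gene-level allele-specific expression: haplotype aggregation, MAF, classes.

Allelic imbalance is summarized by the minor allele frequency (MAF), the
read share of the less expressed haplotype, min(a, b) / (a + b) in [0, 0.5].
Genes are classified as monoallelic (MAF <= 0.10), biallelic (MAF >= 0.40)
or intermediate, with genes below the depth filter left undetermined.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import PhasedSnp

ALLELIC_CLASSES = ("monoallelic", "intermediate", "biallelic", "undetermined")

#: MAF class bounds: minor share at or below MONO_MAX is monoallelic, at or
#: above BI_MIN biallelic (inclusive convention; a strict switch is exposed).
MONO_MAX = 0.10
BI_MIN = 0.40
MIN_DEPTH = 10


class PhaseError(ValueError):
    """A SNP lacks a haplotype phase and no fallback was requested."""


def compute_maf(hap_a: int, hap_b: int) -> float:
    """Minor allele frequency min(a, b)/(a + b); caller must ensure depth > 0."""
    depth = hap_a + hap_b
    if depth <= 0:
        raise ValueError("MAF is undefined at zero depth; filter first")
    return min(hap_a, hap_b) / depth


def classify_allelic_state(
    maf: float | None,
    depth: int,
    min_depth: int = MIN_DEPTH,
    inclusive: bool = True,
) -> str:
    """Map a gene MAF onto {monoallelic, intermediate, biallelic, undetermined}.

    ``inclusive`` keeps boundary values (0.10, 0.40) in the extreme classes;
    the strict alternative assigns them to intermediate.
    """
    if depth < min_depth:
        return "undetermined"
    if maf is None or not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    if inclusive:
        if maf <= MONO_MAX:
            return "monoallelic"
        if maf >= BI_MIN:
            return "biallelic"
    else:
        if maf < MONO_MAX:
            return "monoallelic"
        if maf > BI_MIN:
            return "biallelic"
    return "intermediate"


def phase_by_concordance(
    snp_counts: pd.DataFrame,
    snp_alleles: Mapping[str, tuple[str, str]],
) -> dict[str, bool]:
    """Assign a deterministic phase to the SNPs of one gene.

    ``snp_counts`` holds REF/ALT-oriented rows (any number of samples) for a
    single gene. For each SNP the allele with the larger pooled count across
    samples goes to hapA, so majority alleles co-phase; an exact tie puts the
    lexicographically smaller allele on hapA. Returns snp_id -> flip, where
    flip=True means ALT sits on hapA.
    """
    pooled = snp_counts.groupby("snp_id")[["hapA_count", "hapB_count"]].sum()
    if int(pooled.to_numpy().sum()) == 0:
        raise PhaseError("all-zero counts: concordance phase is undefined")
    flips: dict[str, bool] = {}
    for snp_id, row in pooled.iterrows():
        ref_n, alt_n = int(row["hapA_count"]), int(row["hapB_count"])
        ref, alt = snp_alleles[snp_id]
        if alt_n > ref_n:
            flips[snp_id] = True
        elif alt_n < ref_n:
            flips[snp_id] = False
        else:
            flips[snp_id] = alt < ref  # tie: smaller allele to hapA
    return flips


def aggregate_haplotype_counts(
    snp_counts: pd.DataFrame,
    phased_snps: Sequence[PhasedSnp],
    concordance_fallback: bool = False,
) -> pd.DataFrame:
    """Sum REF/ALT-oriented SNP counts into per-(sample, gene) haplotype totals.

    The count table's two columns are oriented on the VCF (REF, ALT) alleles;
    each SNP's phase decides which column feeds hapA. SNPs with unknown phase
    raise unless ``concordance_fallback`` re-phases them by pooled majority.
    Genes with zero SNPs are absent from the output.
    """
    snps_by_id = {s.snp_id: s for s in phased_snps}
    unknown = [
        sid for sid in snp_counts["snp_id"].unique()
        if sid in snps_by_id and not snps_by_id[sid].phase_known
    ]
    flips: dict[str, bool] = {}
    if unknown:
        if not concordance_fallback:
            raise PhaseError(
                "SNPs without phase (pass concordance_fallback=True to re-phase): "
                + ", ".join(sorted(unknown))
            )
        for gene_id, sub in snp_counts[snp_counts["snp_id"].isin(unknown)].groupby(
            "gene_id"
        ):
            alleles = {
                sid: (snps_by_id[sid].ref_allele, snps_by_id[sid].alt_allele)
                for sid in sub["snp_id"].unique()
            }
            flips.update(phase_by_concordance(sub, alleles))

    rows = []
    for snp_row in snp_counts.itertuples(index=False):
        snp = snps_by_id.get(snp_row.snp_id)
        if snp is None:
            raise PhaseError(f"SNP {snp_row.snp_id} missing from the phased set")
        if snp.phase_known:
            flip = snp.hapA_allele == snp.alt_allele
        else:
            flip = flips[snp_row.snp_id]
        a, b = (
            (snp_row.hapB_count, snp_row.hapA_count)
            if flip
            else (snp_row.hapA_count, snp_row.hapB_count)
        )
        rows.append((snp_row.sample, snp_row.gene_id, a, b))
    if not rows:
        return pd.DataFrame(columns=["sample", "gene_id", "hapA", "hapB"])
    df = pd.DataFrame(rows, columns=["sample", "gene_id", "hapA", "hapB"])
    return (
        df.groupby(["sample", "gene_id"], as_index=False)[["hapA", "hapB"]]
        .sum()
        .sort_values(["sample", "gene_id"], ignore_index=True)
    )


def build_profiles(
    hap_counts: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Attach depth, MAF and allelic class to per-(sample, gene) totals.

    MAF is reported as NaN below the depth filter (class undetermined).
    """
    df = hap_counts.copy()
    df["depth"] = df["hapA"] + df["hapB"]
    df["maf"] = np.where(
        df["depth"] > 0,
        np.minimum(df["hapA"], df["hapB"]) / df["depth"].replace(0, np.nan),
        np.nan,
    )
    df["allelic_class"] = [
        classify_allelic_state(
            None if np.isnan(m) else float(m), int(d), min_depth, inclusive
        )
        for m, d in zip(df["maf"], df["depth"])
    ]
    df.loc[df["allelic_class"] == "undetermined", "maf"] = np.nan
    return df


def profiles_from_counts(
    snp_counts: pd.DataFrame,
    phased_snps: Sequence[PhasedSnp],
    min_depth: int = MIN_DEPTH,
    inclusive: bool = True,
    concordance_fallback: bool = False,
) -> pd.DataFrame:
    """End-to-end: SNP count table + phase -> per-(sample, gene) profiles."""
    hap = aggregate_haplotype_counts(snp_counts, phased_snps, concordance_fallback)
    return build_profiles(hap, min_depth=min_depth, inclusive=inclusive)


def pool_profiles(
    profiles: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Pool replicate samples of one line into a single per-gene profile.

    Haplotype counts are summed across samples before MAF/classification,
    so deep replicates dominate, matching how pooled read counts behave.
    """
    pooled = profiles.groupby("gene_id", as_index=False)[["hapA", "hapB"]].sum()
    pooled.insert(0, "sample", "pooled")
    return build_profiles(pooled, min_depth=min_depth, inclusive=inclusive)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    out = profiles.rename(columns={"allelic_class": "class"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
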