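"""Ground-truthed synthetic data with the statistical structure of XCI erosion.

The generator emulates a clonal female X chromosome: ~15% escapees, ~10%
variable genes and ~75% inactive genes; per-line erosion degrees e in [0, 1];
gene-specific reactivation susceptibility driven by cytogenetic band,
H3K27me3-domain membership and proximity to escapees; negative-binomial
totals with binomial allelic splits at heterozygous SNPs; and UMI-tagged
amplicon reads with geometric PCR duplication.

Generative model
----------------
Each gene g gets a susceptibility

    s_g = logistic(w0 + w1*band_hit + w2*k27_domain + w3*exp(-d_g / tau))

where d_g is the distance to the nearest escapee; escapees themselves have
s_g = 1. For a line with erosion degree e, the share of Xa-level output
produced by the inactive/eroding allele is

    inactive/variable:  x = leak + (1 - leak) * e * s_g
    escape:             x = base + (1 - base) * e   (base ~ U[0.20, 0.35])

Totals scale with (1 + x) relative to the non-eroded reference; allelic
reads at a SNP are Binomial with p = x / (1 + x) on the Xi haplotype (hapB).
XIST is emitted as a pseudo-gene whose level falls linearly with erosion.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning: child 0 -> landscape, 1 -> expression, 2 -> epitracks, 3 -> ampseq,
so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import SignalTrack

X_CHROM = "chrX"
X_LENGTH = 155_000_000

# Coarse cytogenetic band map for the model X (start, end, label).
_BAND_MAP = [
    (0, 10_000_000, "Xp22.3"),
    (10_000_000, 20_000_000, "Xp22.2"),
    (20_000_000, 29_000_000, "Xp22.1"),
    (29_000_000, 37_000_000, "Xp21"),
    (37_000_000, 50_000_000, "Xp11.4"),
    (50_000_000, 61_000_000, "Xp11.2"),
    (61_000_000, 76_000_000, "Xq13"),
    (76_000_000, 85_000_000, "Xq21"),
    (85_000_000, 99_000_000, "Xq21.3"),
    (99_000_000, 110_000_000, "Xq22"),
    (110_000_000, 117_000_000, "Xq23"),
    (117_000_000, 130_000_000, "Xq24"),
    (130_000_000, 141_000_000, "Xq26"),
    (141_000_000, 148_000_000, "Xq27"),
    (148_000_000, X_LENGTH, "Xq28"),
]
# Bands the study associates with reactivation-prone genes.
SUSCEPTIBLE_BAND_PREFIXES = ("Xp22", "Xq22", "Xq23")


class ConfigError(ValueError):
    """A simulation parameter is outside its legal range."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic erosion experiment.

    Defaults mirror the study design: six clonal lines (two XIST+
    non-eroded references plus four XIST- lines with distinct erosion
    degrees), RNA-seq in triplicate, and an escapee/variable/inactive
    composition of roughly 15/10/75%.
    """

    n_x_genes: int = 600
    n_autosomal_genes: int = 2000
    escape_frac: float = 0.15
    variable_frac: float = 0.10
    erosion_degrees: tuple[float, ...] = (0.0, 0.0, 0.55, 0.70, 0.85, 0.95)
    line_names: tuple[str, ...] | None = None
    n_replicates: int = 3
    mean_depth_per_gene: float = 1000.0
    nb_dispersion: float = 0.01
    mean_snps_per_gene: float = 2.0
    snp_coverage_frac: float = 0.25
    escape_xi_share_range: tuple[float, float] = (0.20, 0.35)
    leak: float = 0.01
    # susceptibility weights: intercept, band, K27 domain, escapee proximity
    w0: float = -2.5
    w1: float = 1.0
    w2: float = 1.0
    w3: float = 2.0
    tau: float = 300_000.0
    k27_n_domains: int = 25
    k27_domain_mean_bp: float = 2_500_000.0
    k27_enrichment: float = 4.0
    k27_erosion_retention: float = 0.4
    track_bin_bp: int = 10_000
    beta_xist_pos_range: tuple[float, float] = (0.70, 0.90)
    probes_per_promoter: int = 3
    xist_max_level: float = 3000.0
    # amplicon sequencing
    ampseq_mean_molecules: float = 100.0
    ampseq_p_dup: float = 0.5
    ampseq_error_rate: float = 0.0
    umi_length: int = 8
    template_length: int = 60
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not 0 <= self.escape_frac <= 1 or not 0 <= self.variable_frac <= 1:
            raise ConfigError("fractions must lie in [0, 1]")
        if self.escape_frac + self.variable_frac > 1:
            raise ConfigError("escape_frac + variable_frac must not exceed 1")
        if any(not 0 <= e <= 1 for e in self.erosion_degrees):
            raise ConfigError("erosion degrees must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("NB dispersion must be positive")
        if self.n_x_genes <= 0:
            raise ConfigError("n_x_genes must be positive")
        if not 0 <= self.leak <= 0.02:
            raise ConfigError("leak must lie in [0, 0.02]")
        if self.line_names is None:
            self.line_names = tuple(
                f"line{i}_e{e:g}" for i, e in enumerate(self.erosion_degrees)
            )
        if len(self.line_names) != len(self.erosion_degrees):
            raise ConfigError("one line name per erosion degree")

    def child_rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("landscape", "expression", "epitracks", "ampseq")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class SimTruth:
    """Generator ground truth.

    ``genes`` carries one row per gene: gene_id, chrom, start, end, strand,
    band, band_hit, k27_domain, status, susceptibility, base_share,
    beta_baseline, mu (base NB mean), length_bp, n_snps. ``lines`` maps
    line name -> erosion degree. ``k27_domains`` lists (start, end) on X.
    """

    genes: pd.DataFrame
    lines: pd.DataFrame  # columns: line, erosion
    k27_domains: list[tuple[int, int]]
    config: SimConfig
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)

    def xi_share(self, gene_id: str, erosion: float) -> float:
        row = self.genes.loc[gene_id]
        return _xi_share(
            str(row["status"]), float(row["susceptibility"]),
            float(row["base_share"]), erosion, self.config.leak,
        )

    def xi_share_matrix(self) -> pd.DataFrame:
        """Per (gene, line) Xi share for X-linked genes."""
        out = {}
        for line, e in zip(self.lines["line"], self.lines["erosion"]):
            out[line] = [
                self.xi_share(g, float(e))
                for g in self.genes.index
            ]
        return pd.DataFrame(out, index=self.genes.index)


def _xi_share(status: str, s: float, base: float, e: float, leak: float) -> float:
    if status == "escape":
        return base + (1.0 - base) * e
    return leak + (1.0 - leak) * e * s


def _logistic(z: float | np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _band_of(pos: int) -> str:
    for start, end, label in _BAND_MAP:
        if start <= pos < end:
            return label
    return _BAND_MAP[-1][2]


def build_x_landscape(config: SimConfig) -> SimTruth:
    """Place genes on a model X and draw statuses and susceptibilities."""
    rng = config.child_rngs()["landscape"]
    n = config.n_x_genes

    starts = np.sort(rng.integers(0, X_LENGTH - 200_000, size=n))
    lengths = np.clip(rng.lognormal(math.log(30_000), 0.8, size=n), 2_000, 180_000)
    ends = starts + lengths.astype(np.int64)
    strands = rng.choice(["+", "-"], size=n)

    statuses = np.full(n, "inactive", dtype=object)
    n_escape = int(round(config.escape_frac * n))
    n_variable = int(round(config.variable_frac * n))
    order = rng.permutation(n)
    statuses[order[:n_escape]] = "escape"
    statuses[order[n_escape:n_escape + n_variable]] = "variable"

    bands = np.array([_band_of(int(s)) for s in starts], dtype=object)
    band_hit = np.array(
        [b.startswith(SUSCEPTIBLE_BAND_PREFIXES) for b in bands], dtype=bool
    )

    # H3K27me3 domains: random intervals on the model X
    dom_starts = np.sort(
        rng.integers(0, X_LENGTH, size=config.k27_n_domains)
    )
    dom_lengths = rng.exponential(config.k27_domain_mean_bp, size=config.k27_n_domains)
    domains: list[tuple[int, int]] = []
    for ds, dl in zip(dom_starts, dom_lengths):
        de = min(int(ds + max(dl, 200_000)), X_LENGTH)
        if domains and ds <= domains[-1][1]:
            domains[-1] = (domains[-1][0], max(domains[-1][1], de))
        else:
            domains.append((int(ds), de))
    mids = (starts + ends) // 2
    in_domain = np.zeros(n, dtype=bool)
    for ds, de in domains:
        in_domain |= (mids >= ds) & (mids < de)

    # distance to nearest escapee (gap between intervals; 0 for escapees)
    esc_mask = statuses == "escape"
    if esc_mask.any():
        d = _nearest_gap(starts, ends, starts[esc_mask], ends[esc_mask])
    else:
        d = np.full(n, X_LENGTH, dtype=float)

    z = (
        config.w0
        + config.w1 * band_hit.astype(float)
        + config.w2 * in_domain.astype(float)
        + config.w3 * np.exp(-d / config.tau)
    )
    susceptibility = _logistic(z)
    susceptibility[esc_mask] = 1.0

    base_share = rng.uniform(*config.escape_xi_share_range, size=n)
    beta = rng.uniform(*config.beta_xist_pos_range, size=n)
    beta[esc_mask] = rng.uniform(0.05, 0.20, size=int(esc_mask.sum()))

    mu = rng.lognormal(math.log(config.mean_depth_per_gene), 1.0, size=n)
    n_snps = rng.poisson(config.mean_snps_per_gene, size=n)

    gene_ids = [f"XG{i:04d}" for i in range(n)]
    genes = pd.DataFrame(
        {
            "chrom": X_CHROM,
            "start": starts,
            "end": ends,
            "strand": strands,
            "band": bands,
            "band_hit": band_hit,
            "k27_domain": in_domain,
            "status": statuses,
            "susceptibility": susceptibility,
            "base_share": base_share,
            "beta_baseline": beta,
            "mu": mu,
            "n_snps": n_snps,
            "length_bp": (ends - starts),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    lines = pd.DataFrame(
        {"line": list(config.line_names), "erosion": list(config.erosion_degrees)}
    )
    truth = SimTruth(genes=genes, lines=lines, k27_domains=domains, config=config)
    truth.snps = _draw_snps(truth, rng)
    return truth


def _nearest_gap(
    starts: np.ndarray, ends: np.ndarray,
    ref_starts: np.ndarray, ref_ends: np.ndarray,
) -> np.ndarray:
    """Gap (0 if overlapping/bookended) from each interval to the nearest reference."""
    out = np.empty(len(starts), dtype=float)
    for i, (s, e) in enumerate(zip(starts, ends)):
        gap_right = np.where(ref_starts >= e, ref_starts - e, 0)
        gap_left = np.where(ref_ends <= s, s - ref_ends, 0)
        overlap = (ref_starts < e) & (ref_ends > s)
        gaps = np.where(overlap, 0, np.maximum(gap_right, gap_left))
        out[i] = gaps.min()
    return out


_BASES = np.array(list("ACGT"))


def _draw_snps(truth: SimTruth, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for gene_id, row in truth.genes.iterrows():
        k = int(row["n_snps"])
        if k == 0:
            continue
        positions = np.sort(rng.integers(row["start"], row["end"], size=k))
        for j, pos in enumerate(positions):
            ref, alt = rng.choice(4, size=2, replace=False)
            # hapB is the Xi haplotype; random REF/ALT orientation per SNP
            alt_on_b = bool(rng.integers(0, 2))
            rows.append(
                {
                    "snp_id": f"{gene_id}_snp{j}",
                    "gene_id": gene_id,
                    "chrom": row["chrom"],
                    "pos": int(pos) + 1,  # 1-based, VCF style
                    "ref": _BASES[ref],
                    "alt": _BASES[alt],
                    "alt_on_xi": alt_on_b,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with Var = mu + alpha*mu^2 via the Gamma-Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    lam = np.where(
        mean > 0, rng.gamma(1.0 / alpha, np.maximum(mean, 1e-12) * alpha), 0.0
    )
    return rng.poisson(lam)


def simulate_expression(
    truth: SimTruth, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw the count matrix, per-SNP allelic table and per-line XIST levels.

    Returns ``(counts, allelic, xist)``: counts is gene x sample (samples
    named ``<line>_r<rep>``; X genes, autosomal genes and the XIST
    pseudo-gene); allelic has the io_formats schema with REF/ALT-oriented
    columns; xist maps line -> emitted XIST mean level.
    """
    config = config or truth.config
    rng = config.child_rngs()["expression"]
    alpha = config.nb_dispersion
    genes = truth.genes
    ref_e = float(truth.lines["erosion"].min())

    samples = [
        f"{line}_r{r + 1}"
        for line in truth.lines["line"]
        for r in range(config.n_replicates)
    ]
    sample_line = {
        s: (line, float(e))
        for line, e in zip(truth.lines["line"], truth.lines["erosion"])
        for s in [f"{line}_r{r + 1}" for r in range(config.n_replicates)]
    }

    x_share_ref = np.array(
        [truth.xi_share(g, ref_e) for g in genes.index]
    )
    counts: dict[str, np.ndarray] = {}
    allelic_rows = []
    auto_mu = rng.lognormal(
        math.log(config.mean_depth_per_gene), 1.0, size=config.n_autosomal_genes
    )
    auto_ids = [f"AG{i:04d}" for i in range(config.n_autosomal_genes)]
    auto_chroms = [f"chr{1 + i % 22}" for i in range(config.n_autosomal_genes)]

    snps = truth.snps
    for s in samples:
        line, e = sample_line[s]
        x = np.array([truth.xi_share(g, e) for g in genes.index])
        mean_x = genes["mu"].to_numpy() * (1.0 + x) / (1.0 + x_share_ref)
        cx = _nb_draw(rng, mean_x, alpha)
        ca = _nb_draw(rng, auto_mu, alpha)
        xist_mean = config.xist_max_level * (1.0 - e)
        cxist = _nb_draw(rng, np.array([xist_mean]), alpha)
        counts[s] = np.concatenate([cx, ca, cxist])

        if len(snps):
            gene_count = dict(zip(genes.index, cx))
            gene_x = dict(zip(genes.index, x))
            for snp in snps.itertuples(index=False):
                total = gene_count[snp.gene_id]
                n_reads = rng.binomial(int(total), config.snp_coverage_frac)
                p_xi = gene_x[snp.gene_id] / (1.0 + gene_x[snp.gene_id])
                xi_reads = rng.binomial(n_reads, p_xi)
                xa_reads = n_reads - xi_reads
                # columns are REF/ALT oriented; Xi haplotype carries ALT iff alt_on_xi
                ref_count, alt_count = (
                    (xa_reads, xi_reads) if snp.alt_on_xi else (xi_reads, xa_reads)
                )
                allelic_rows.append(
                    (s, snp.gene_id, snp.snp_id, ref_count, alt_count)
                )

    index = pd.Index(list(genes.index) + auto_ids + ["XIST"], name="gene_id")
    count_df = pd.DataFrame(counts, index=index)
    count_df.attrs["chrom"] = dict(
        zip(index, [X_CHROM] * len(genes) + auto_chroms + [X_CHROM])
    )
    allelic = pd.DataFrame(
        allelic_rows,
        columns=["sample", "gene_id", "snp_id", "hapA_count", "hapB_count"],
    )
    xist = pd.Series(
        {line: config.xist_max_level * (1.0 - float(e))
         for line, e in zip(truth.lines["line"], truth.lines["erosion"])},
        name="xist_level",
    )
    return count_df, allelic, xist


def annotation_frame(truth: SimTruth) -> pd.DataFrame:
    """Gene annotation for everything in the count matrix, incl. autosomes."""
    genes = truth.genes
    config = truth.config
    auto_ids = [f"AG{i:04d}" for i in range(config.n_autosomal_genes)]
    auto = pd.DataFrame(
        {
            "chrom": [f"chr{1 + i % 22}" for i in range(len(auto_ids))],
            "start": 1_000_000,
            "end": 1_030_000,
            "strand": "+",
            "band": "",
            "length_bp": 30_000,
            "status": "undefined",
        },
        index=pd.Index(auto_ids, name="gene_id"),
    )
    x = genes[["chrom", "start", "end", "strand", "band", "length_bp", "status"]].copy()
    xist = pd.DataFrame(
        {
            "chrom": [X_CHROM], "start": [73_820_000], "end": [73_852_000],
            "strand": ["-"], "band": ["Xq13"], "length_bp": [19_000],
            "status": ["escape"],
        },
        index=pd.Index(["XIST"], name="gene_id"),
    )
    return pd.concat([x, auto, xist])


def write_phase_vcf(truth: SimTruth, path: str | Path) -> None:
    """Write the simulated het SNPs as a minimal phased VCF (hapA|hapB)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={X_CHROM},length={X_LENGTH}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsim\n")
        snps = truth.snps.sort_values(["chrom", "pos"])
        for snp in snps.itertuples(index=False):
            # GT lists hapA|hapB with hapA = Xa; Xi (hapB) carries ALT iff alt_on_xi
            gt = "0|1" if snp.alt_on_xi else "1|0"
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref}\t{snp.alt}"
                f"\t.\tPASS\t.\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# Epigenomic tracks
# ---------------------------------------------------------------------------

def simulate_epitracks(
    truth: SimTruth, config: SimConfig | None = None
) -> tuple[dict[str, SignalTrack], pd.DataFrame]:
    """H3K27me3 tracks per XIST state and a promoter-methylation probe table.

    The XIST+ track carries ``k27_enrichment``-fold signal inside domains
    over a unit baseline; the XIST- track retains ``k27_erosion_retention``
    of the domain excess. Promoter beta in the eroded state shrinks with the
    gene's Xi share in the most-eroded line: beta_eroded = beta * (1 - x).
    """
    config = config or truth.config
    rng = config.child_rngs()["epitracks"]
    bin_bp = config.track_bin_bp
    edges = np.arange(0, X_LENGTH + bin_bp, bin_bp)
    n_bins = len(edges) - 1
    base = np.ones(n_bins)

    in_domain = np.zeros(n_bins, dtype=bool)
    mids = (edges[:-1] + edges[1:]) // 2
    for ds, de in truth.k27_domains:
        in_domain |= (mids >= ds) & (mids < de)

    def track(domain_level: float) -> SignalTrack:
        values = np.where(in_domain, domain_level, base)
        return SignalTrack(
            pd.DataFrame(
                {
                    "chrom": X_CHROM,
                    "start": edges[:-1],
                    "end": edges[1:],
                    "value": values,
                }
            )
        )

    enrich = config.k27_enrichment
    tracks = {
        "XIST+": track(enrich),
        "XIST-": track(1.0 + (enrich - 1.0) * config.k27_erosion_retention),
    }

    eroded_line = truth.lines.loc[truth.lines["erosion"].idxmax()]
    e_max = float(eroded_line["erosion"])
    rows = []
    for gene_id, row in truth.genes.iterrows():
        tss = int(row["start"]) if row["strand"] == "+" else int(row["end"])
        beta_ref = float(row["beta_baseline"])
        x = truth.xi_share(gene_id, e_max)
        beta_ero = float(np.clip(beta_ref * (1.0 - x), 0.0, 1.0))
        offsets = rng.integers(-900, 900, size=config.probes_per_promoter)
        for off in offsets:
            rows.append((row["chrom"], max(tss + int(off), 0), beta_ref, beta_ero))
    meth = pd.DataFrame(rows, columns=["chrom", "pos", "beta_ref", "beta_eroded"])
    return tracks, meth


# ---------------------------------------------------------------------------
# Amplicon sequencing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimReadSet:
    """FASTQ-like amplicon reads plus the generator's molecule truth table."""

    reads: pd.DataFrame  # columns: read_id, sequence
    truth_molecules: pd.DataFrame  # columns: amplicon_id, allele, molecules


def default_amplicon_panel(truth: SimTruth, n_amplicons: int = 6) -> pd.DataFrame:
    """A panel targeting the first het SNP of the n most SNP-rich genes."""
    rng = np.random.default_rng(np.random.SeedSequence(truth.config.seed).spawn(4)[3])
    with_snps = truth.snps.drop_duplicates("gene_id").head(n_amplicons)
    rows = []
    for i, snp in enumerate(with_snps.itertuples(index=False)):
        primer = "".join(rng.choice(_BASES, size=12))
        rows.append(
            {
                "amplicon_id": f"amp{i:02d}",
                "primer_prefix": primer,
                "snp_offset": 20,
                "ref": snp.ref,
                "alt": snp.alt,
                "gene_id": snp.gene_id,
                "snp_id": snp.snp_id,
            }
        )
    return pd.DataFrame(rows)


def simulate_ampseq_reads(
    truth: SimTruth,
    panel: pd.DataFrame,
    line: str | None = None,
    config: SimConfig | None = None,
) -> SimReadSet:
    """Poisson molecules per allele, 8-nt UMIs, geometric PCR duplication.

    Reads are ``UMI + primer_prefix + filler`` with the SNP base written at
    ``snp_offset`` of the template (post-UMI sequence). Per-base errors at
    ``ampseq_error_rate`` are applied to the UMI bases and the SNP base.
    """
    config = config or truth.config
    rng = config.child_rngs()["ampseq"]
    if line is None:
        line = str(truth.lines.loc[truth.lines["erosion"].idxmax(), "line"])
    e = float(truth.lines.set_index("line").loc[line, "erosion"])

    known = set(truth.snps["snp_id"]) if len(truth.snps) else set()
    reads = []
    truth_rows = []
    for amp in panel.itertuples(index=False):
        if amp.snp_id not in known:
            raise ConfigError(f"amplicon {amp.amplicon_id}: SNP {amp.snp_id} not in truth")
        snp = truth.snps.set_index("snp_id").loc[amp.snp_id]
        x = truth.xi_share(str(snp["gene_id"]), e)
        p_xi = x / (1.0 + x)
        p_alt = p_xi if bool(snp["alt_on_xi"]) else 1.0 - p_xi
        lam = config.ampseq_mean_molecules
        n_alt = rng.poisson(lam * p_alt)
        n_ref = rng.poisson(lam * (1.0 - p_alt))

        filler = rng.choice(_BASES, size=config.template_length)
        for allele, n_mol in (("ref", n_ref), ("alt", n_alt)):
            base = amp.ref if allele == "ref" else amp.alt
            # molecules sharing a (UMI, allele) tag are indistinguishable in
            # principle, so the truth table records identifiable molecules
            umis = {
                "".join(rng.choice(_BASES, size=config.umi_length))
                for _ in range(n_mol)
            }
            truth_rows.append((amp.amplicon_id, allele, len(umis), n_mol))
            for m, umi in enumerate(sorted(umis)):
                template = filler.copy()
                template[: len(amp.primer_prefix)] = list(amp.primer_prefix)
                template[amp.snp_offset] = base
                n_reads = (
                    int(rng.geometric(1.0 - config.ampseq_p_dup))
                    if config.ampseq_p_dup > 0 else 1
                )
                for d in range(n_reads):
                    seq = np.array(list(umi) + list(template))
                    if config.ampseq_error_rate > 0:
                        # errors hit the UMI and the interrogated SNP base only
                        error_sites = np.zeros(len(seq), dtype=bool)
                        error_sites[: config.umi_length] = True
                        error_sites[config.umi_length + amp.snp_offset] = True
                        hit = error_sites & (rng.random(len(seq)) < config.ampseq_error_rate)
                        if hit.any():
                            seq[hit] = _BASES[
                                (np.searchsorted(_BASES, seq[hit]) + rng.integers(1, 4, size=int(hit.sum()))) % 4
                            ]
                    reads.append(
                        (
                            f"{amp.amplicon_id}:{allele}:m{m}:d{d}",
                            "".join(seq),
                        )
                    )
    reads_df = pd.DataFrame(reads, columns=["read_id", "sequence"])
    truth_df = pd.DataFrame(
        truth_rows, columns=["amplicon_id", "allele", "molecules", "molecules_drawn"]
    )
    return SimReadSet(reads=reads_df, truth_molecules=truth_df)


def write_fastq(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads as FASTQ with uniform Q40 qualities (Biopython)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(row.sequence),
            id=row.read_id,
            description="",
            letter_annotations={"phred_quality": [40] * len(row.sequence)},
        )
        for row in reads.itertuples(index=False)
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(records, fh, "fastq")
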