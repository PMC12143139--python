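"""RNA-AMP-seq: UMI extraction, molecule deduplication, allelic counting.

Read 1 carries an 8-nt unique molecular identifier (UMI) followed by the
amplicon template; reads are assigned to amplicons by exact primer-prefix
match, the base at the panel's SNP offset is called against REF/ALT, and
PCR duplicates are collapsed on the UMI. Exact mode counts distinct
(UMI, allele) pairs; directional mode additionally merges a UMI u into a
more abundant neighbor v when Hamming(u, v) = 1 and count_v >= 2*count_u - 1
(connected components, one molecule each, allele by read majority).
Molecule-scale MAF then reuses the allelic-state machinery.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .ase import classify_allelic_state, compute_maf

log = logging.getLogger(__name__)

UMI_LENGTH = 8

PANEL_COLUMNS = ["amplicon_id", "primer_prefix", "snp_offset", "ref", "alt", "gene_id"]


@dataclass(frozen=True)
class AmpliconRecord:
    amplicon_id: str
    umi: str
    snp_base: str
    template: str

    @property
    def umi_has_n(self) -> bool:
        return "N" in self.umi


@dataclass
class ProcessCounters:
    """Filter accounting: the audit trail of the amplicon pipeline."""

    total: int = 0
    too_short: int = 0
    unassigned: int = 0
    offset_out_of_range: int = 0
    umi_with_n: int = 0
    other_allele: int = 0


def extract_umi(sequence: str, umi_length: int = UMI_LENGTH) -> tuple[str, str]:
    """Split a read into (UMI, template); the read must extend past the UMI."""
    if len(sequence) <= umi_length:
        raise ValueError(f"read shorter than UMI + 1 ({len(sequence)} <= {umi_length})")
    return sequence[:umi_length], sequence[umi_length:]


def call_allele(template: str, amplicon: pd.Series) -> str:
    """Compare the base at the SNP offset to REF/ALT; anything else is 'other'."""
    offset = int(amplicon["snp_offset"])
    if offset >= len(template):
        raise ValueError(f"SNP offset {offset} beyond template of {len(template)} bp")
    base = template[offset]
    if base == amplicon["ref"]:
        return "ref"
    if base == amplicon["alt"]:
        return "alt"
    return "other"


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype={"snp_offset": int})
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"{path}: panel missing columns {sorted(missing)}")
    return panel


def process_reads(
    sequences: Iterable[tuple[str, str]],
    panel: pd.DataFrame,
    umi_length: int = UMI_LENGTH,
) -> tuple[pd.DataFrame, ProcessCounters]:
    """Assign (read_id, sequence) pairs to amplicons and call alleles.

    Returns a record table (amplicon_id, umi, allele, umi_has_n) and the
    filter counters. Reads failing UMI extraction, primer matching or the
    offset bound are counted and dropped; 'other' alleles are retained in
    the table but excluded from MAF downstream.
    """
    by_prefix = {row.primer_prefix: row for row in panel.itertuples(index=False)}
    prefixes = sorted(by_prefix, key=len, reverse=True)
    counters = ProcessCounters()
    rows = []
    for read_id, seq in sequences:
        counters.total += 1
        try:
            umi, template = extract_umi(seq, umi_length)
        except ValueError:
            counters.too_short += 1
            continue
        amp = next((by_prefix[p] for p in prefixes if template.startswith(p)), None)
        if amp is None:
            counters.unassigned += 1
            continue
        amp_row = pd.Series(amp._asdict())
        try:
            allele = call_allele(template, amp_row)
        except ValueError:
            counters.offset_out_of_range += 1
            continue
        if "N" in umi:
            counters.umi_with_n += 1
        if allele == "other":
            counters.other_allele += 1
        rows.append((amp.amplicon_id, umi, allele, "N" in umi))
    records = pd.DataFrame(
        rows, columns=["amplicon_id", "umi", "allele", "umi_has_n"]
    )
    return records, counters


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTQ file (Biopython)."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def _hamming1(u: str, v: str) -> bool:
    if len(u) != len(v):
        return False
    diff = 0
    for a, b in zip(u, v):
        if a != b:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def _directional_components(umi_counts: Counter) -> list[list[str]]:
    """Connected components under the directional merge rule.

    Edge v -> u when Hamming(v, u) = 1 and count_v >= 2*count_u - 1; the
    resulting undirected components each collapse to one molecule.
    """
    umis = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    parent = {u: u for u in umis}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def union(u: str, v: str) -> None:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru

    for i, v in enumerate(umis):
        for u in umis[i + 1:]:
            if umi_counts[v] >= 2 * umi_counts[u] - 1 and _hamming1(u, v):
                union(v, u)
    comps: dict[str, list[str]] = defaultdict(list)
    for u in umis:
        comps[find(u)].append(u)
    return list(comps.values())


def dedup_molecules(
    records: pd.DataFrame,
    mode: Literal["exact", "directional"] = "exact",
) -> pd.DataFrame:
    """Collapse reads to molecules per (amplicon, allele).

    Exact mode: molecules = distinct (UMI, allele) pairs. Directional mode:
    UMIs are clustered per amplicon under the merge rule; each component is
    one molecule whose allele is the read-majority within the component
    (tie -> the component root's allele, the most-read UMI's majority).
    'other' alleles are carried through so callers can report them.
    Returns amplicon_id, allele, molecules, raw_reads.
    """
    if mode not in ("exact", "directional"):
        raise ValueError(f"unknown dedup mode {mode!r}")
    out = []
    for amp, sub in records.groupby("amplicon_id", sort=True):
        raw = sub["allele"].value_counts()
        if mode == "exact":
            mol = sub.drop_duplicates(["umi", "allele"])["allele"].value_counts()
        else:
            umi_counts = Counter(sub["umi"])
            # reads per (umi, allele) for majority voting
            ua = sub.groupby(["umi", "allele"]).size()
            mol_counter: Counter = Counter()
            for comp in _directional_components(umi_counts):
                votes: Counter = Counter()
                for u in comp:
                    for allele, n in ua[u].items():
                        votes[allele] += n
                best = votes.most_common()
                if len(best) > 1 and best[0][1] == best[1][1]:
                    root = max(comp, key=lambda u: (umi_counts[u], u))
                    allele = ua[root].idxmax()
                else:
                    allele = best[0][0]
                mol_counter[allele] += 1
            mol = pd.Series(mol_counter, dtype=int)
        for allele in sorted(set(raw.index) | set(mol.index)):
            out.append(
                {
                    "amplicon_id": amp,
                    "allele": allele,
                    "molecules": int(mol.get(allele, 0)),
                    "raw_reads": int(raw.get(allele, 0)),
                }
            )
    return pd.DataFrame(out, columns=["amplicon_id", "allele", "molecules", "raw_reads"])


def amplicon_maf(
    molecule_counts: pd.DataFrame,
    min_molecules: int = 10,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Molecule-scale MAF and allelic class per amplicon.

    Only ref/alt molecules enter the MAF; 'other' molecules are reported
    separately. Amplicons with zero ref+alt molecules are undetermined.
    """
    rows = []
    for amp, sub in molecule_counts.groupby("amplicon_id", sort=True):
        lookup = sub.set_index("allele")["molecules"]
        n_ref = int(lookup.get("ref", 0))
        n_alt = int(lookup.get("alt", 0))
        n_other = int(lookup.get("other", 0))
        total = n_ref + n_alt
        maf = compute_maf(n_ref, n_alt) if total > 0 else np.nan
        cls = classify_allelic_state(
            None if total == 0 else maf, total, min_depth=min_molecules,
            inclusive=inclusive,
        )
        rows.append(
            {
                "amplicon_id": amp,
                "molecules_ref": n_ref,
                "molecules_alt": n_alt,
                "molecules_other": n_other,
                "maf": maf,
                "allelic_class": cls,
            }
        )
    return pd.DataFrame(rows)


def compare_states(
    maf_state1: pd.DataFrame,
    maf_state2: pd.DataFrame,
    stability_tolerance: float = 0.10,
) -> pd.DataFrame:
    """Pair per-amplicon MAFs across two states (e.g. hiPSC vs derivative).

    The stability flag mirrors the eroded-gene threshold: |delta| below the
    tolerance counts as stable allelic expression.
    """
    merged = maf_state1.merge(
        maf_state2, on="amplicon_id", suffixes=("_1", "_2"), how="inner"
    )
    if merged.empty:
        log.warning("no shared amplicons between the two states")
    out = pd.DataFrame(
        {
            "amplicon_id": merged["amplicon_id"],
            "maf_1": merged["maf_1"],
            "maf_2": merged["maf_2"],
            "class_1": merged["allelic_class_1"],
            "class_2": merged["allelic_class_2"],
        }
    )
    out["delta"] = out["maf_2"] - out["maf_1"]
    out["stable"] = out["delta"].abs() < stability_tolerance
    return out
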