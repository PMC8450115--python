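"""Footprint alignments -> codon occupancy, TPM/ribosome density, and RCDT.

All CDS coordinates are 0-based nucleotide offsets within the CDS; the codon
index of an A-site is ``(five_prime_pos + offset(read_length)) // 3``. The
relative codon decoding time (RCDT) of a codon is the mean, over CDS
positions carrying that codon, of per-gene mean-normalized ribosome
occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .codon_metrics.genetic_code import GeneticCode, standard_code
from .errors import EmptyResultError, InputError, UndefinedIndexError

logger = logging.getLogger(__name__)

#: Community-standard A-site offset: +15 nt from the 5' end for typical RPFs.
DEFAULT_OFFSETS: dict[int, int] = {n: 15 for n in range(27, 32)}

#: Head/tail codons excluded from RCDT statistics (initiation/termination ramp).
DEFAULT_TRIM: tuple[int, int] = (15, 5)


class AlignedFootprint(NamedTuple):
    gene_id: str
    five_prime_pos: int
    read_length: int


@dataclass
class CodonOccupancyProfile:
    """Per-gene A-site-assigned footprint counts, one per codon."""

    gene_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or (self.counts < 0).any():
            raise InputError(f"{self.gene_id}: counts must be a nonnegative 1-D vector")

    @property
    def n_codons(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _footprint_frame(footprints) -> pd.DataFrame:
    if isinstance(footprints, pd.DataFrame):
        missing = {"gene_id", "five_prime_pos", "read_length"} - set(footprints.columns)
        if missing:
            raise InputError(f"footprint frame missing columns: {sorted(missing)}")
        return footprints
    rows = list(footprints)
    return pd.DataFrame(rows, columns=["gene_id", "five_prime_pos", "read_length"])


def assign_a_sites(
    footprints: pd.DataFrame | Iterable[tuple],
    cds_lengths_nt: dict[str, int],
    offsets: dict[int, int] | None = None,
) -> tuple[dict[str, CodonOccupancyProfile], dict[str, int]]:
    """Assign footprints to A-site codons and tally per-gene count vectors.

    Reads whose length has no configured offset, whose gene is unknown, or
    whose A-site codon falls outside ``[0, n_codons)`` are dropped and
    counted in the returned stats. Every gene in ``cds_lengths_nt`` gets a
    profile (possibly all-zero).
    """
    offsets = DEFAULT_OFFSETS if offsets is None else offsets
    df = _footprint_frame(footprints)
    stats = {
        "n_input": int(len(df)),
        "n_assigned": 0,
        "n_dropped_length": 0,
        "n_dropped_unknown_gene": 0,
        "n_dropped_out_of_range": 0,
    }
    profiles = {
        g: CodonOccupancyProfile(g, np.zeros(length // 3, dtype=np.int64))
        for g, length in cds_lengths_nt.items()
    }
    if df.empty:
        logger.warning("assign_a_sites: empty footprint input")
        return profiles, stats

    known = df["gene_id"].map(lambda g: g in profiles).to_numpy()
    stats["n_dropped_unknown_gene"] = int((~known).sum())
    df = df[known]

    offset = df["read_length"].map(offsets).to_numpy(dtype=float)
    has_offset = ~np.isnan(offset)
    stats["n_dropped_length"] = int((~has_offset).sum())
    df = df[has_offset]
    offset = offset[has_offset]

    codon_idx = (df["five_prime_pos"].to_numpy(dtype=np.int64) + offset.astype(np.int64)) // 3
    n_codons = df["gene_id"].map(lambda g: profiles[g].n_codons).to_numpy(dtype=np.int64)
    in_range = (codon_idx >= 0) & (codon_idx < n_codons)
    stats["n_dropped_out_of_range"] = int((~in_range).sum())

    kept = df[in_range]
    codon_idx = codon_idx[in_range]
    stats["n_assigned"] = int(len(kept))
    for gene, idx in pd.Series(codon_idx).groupby(kept["gene_id"].to_numpy()):
        np.add.at(profiles[gene].counts, idx.to_numpy(), 1)
    if stats["n_assigned"] == 0:
        logger.warning("assign_a_sites: all %d reads dropped", stats["n_input"])
    return profiles, stats


def compute_tpm(counts: dict[str, float] | pd.Series, lengths_nt: dict[str, int] | pd.Series) -> pd.Series:
    """Transcripts per kilobase million; the result sums to 1e6."""
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths_nt, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:3]
        raise InputError(f"missing CDS lengths for genes, e.g. {missing}")
    if (lengths <= 0).any():
        raise InputError("CDS lengths must be positive")
    if (counts < 0).any():
        raise InputError("counts must be nonnegative")
    rate = counts / (lengths / 1000.0)
    total = rate.sum()
    if total <= 0:
        raise UndefinedIndexError("TPM undefined: all counts are zero")
    return 1e6 * rate / total


def compute_ribosome_density(
    rpf_tpm: pd.Series,
    mrna_tpm: pd.Series,
    min_mrna_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene ribosome density = RPF TPM / mRNA TPM.

    Genes with mRNA TPM below the floor get NaN density and are meant to be
    excluded downstream. The two inputs must cover the same gene universe.
    """
    if set(rpf_tpm.index).isdisjoint(mrna_tpm.index):
        raise InputError("RPF and mRNA quantifications share no genes")
    genes = rpf_tpm.index.intersection(mrna_tpm.index)
    dropped = len(rpf_tpm.index.symmetric_difference(mrna_tpm.index))
    if dropped:
        logger.warning("compute_ribosome_density: %d genes present in only one input", dropped)
    out = pd.DataFrame(
        {"rpf_tpm": rpf_tpm.reindex(genes), "mrna_tpm": mrna_tpm.reindex(genes)}
    )
    ok = out["mrna_tpm"] >= min_mrna_tpm
    out["ribosome_density"] = np.where(ok, out["rpf_tpm"] / out["mrna_tpm"], np.nan)
    return out


@dataclass
class RCDTTable:
    """Relative codon decoding times for one condition and length stratum."""

    condition_label: str
    stratum: str
    rcdt: dict[str, float]
    n_occurrences: dict[str, int]
    n_genes_used: int
    coverage_filter: dict[str, float] = field(default_factory=dict)

    def to_frame(self, code: GeneticCode | None = None) -> pd.DataFrame:
        code = code or standard_code()
        rows = [
            {
                "codon": c,
                "amino_acid": code.codon_to_aa[c],
                "rcdt": self.rcdt[c],
                "n_occurrences": self.n_occurrences[c],
            }
            for c in sorted(self.rcdt)
        ]
        return pd.DataFrame(rows)


def _codon_index_arrays(
    cds_seqs: dict[str, str], code: GeneticCode
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Encode each CDS as an int array over sense codons (-1 = not a sense codon)."""
    sense = code.sense_codons
    lookup = {c: i for i, c in enumerate(sense)}
    encoded = {}
    for gene, seq in cds_seqs.items():
        seq = seq.upper()
        n = len(seq) // 3
        arr = np.full(n, -1, dtype=np.int64)
        for i in range(n):
            arr[i] = lookup.get(seq[3 * i : 3 * i + 3], -1)
        encoded[gene] = arr
    return encoded, sense


def compute_rcdt(
    profiles: dict[str, CodonOccupancyProfile] | Sequence[CodonOccupancyProfile],
    cds_seqs: dict[str, str],
    *,
    min_mean_reads: float = 0.5,
    min_total_reads: int = 64,
    trim: tuple[int, int] = DEFAULT_TRIM,
    min_occurrences: int = 1,
    aggregate: str = "pooled",
    condition_label: str = "",
    stratum: str = "all",
    code: GeneticCode | None = None,
) -> RCDTTable:
    """Relative codon decoding time per sense codon.

    For each retained gene, relative occupancy r_i = counts_i / mean(counts)
    over non-trimmed positions (so the per-gene mean of r is exactly 1).
    ``aggregate='pooled'`` averages r over all positions of a codon across
    genes; ``'gene_mean'`` first averages within genes, then across genes.
    """
    if aggregate not in {"pooled", "gene_mean"}:
        raise InputError(f"unknown aggregate mode {aggregate!r}")
    if not isinstance(profiles, dict):
        profiles = {p.gene_id: p for p in profiles}
    code = code or standard_code()
    head, tail = trim
    encoded, sense = _codon_index_arrays(cds_seqs, code)

    sums = np.zeros(len(sense))
    occs = np.zeros(len(sense), dtype=np.int64)
    gm_sums = np.zeros(len(sense))
    gm_genes = np.zeros(len(sense), dtype=np.int64)
    n_used = 0
    for gene, prof in profiles.items():
        if gene not in encoded:
            logger.debug("compute_rcdt: no CDS sequence for %s; skipped", gene)
            continue
        codes_arr = encoded[gene]
        if codes_arr.size != prof.n_codons:
            raise InputError(
                f"{gene}: profile has {prof.n_codons} codons but CDS has {codes_arr.size}"
            )
        if prof.n_codons <= head + tail + 1:
            continue
        counts = prof.counts[head : prof.n_codons - tail].astype(float)
        codes_win = codes_arr[head : prof.n_codons - tail]
        total = counts.sum()
        mean = counts.mean()
        if total < min_total_reads or mean < min_mean_reads or mean == 0:
            continue
        n_used += 1
        r = counts / mean
        valid = codes_win >= 0
        np.add.at(sums, codes_win[valid], r[valid])
        np.add.at(occs, codes_win[valid], 1)
        if aggregate == "gene_mean":
            g_sum = np.zeros(len(sense))
            g_occ = np.zeros(len(sense), dtype=np.int64)
            np.add.at(g_sum, codes_win[valid], r[valid])
            np.add.at(g_occ, codes_win[valid], 1)
            has = g_occ > 0
            gm_sums[has] += g_sum[has] / g_occ[has]
            gm_genes[has] += 1

    if n_used == 0:
        raise EmptyResultError("compute_rcdt: no gene passed the coverage filter")

    rcdt: dict[str, float] = {}
    n_occ: dict[str, int] = {}
    for i, codon in enumerate(sense):
        if occs[i] < min_occurrences or occs[i] == 0:
            continue
        if aggregate == "pooled":
            rcdt[codon] = float(sums[i] / occs[i])
        else:
            rcdt[codon] = float(gm_sums[i] / gm_genes[i])
        n_occ[codon] = int(occs[i])
    missing = set(sense) - set(rcdt)
    if missing:
        logger.warning("compute_rcdt: %d codons never observed; omitted", len(missing))
    return RCDTTable(
        condition_label=condition_label,
        stratum=stratum,
        rcdt=rcdt,
        n_occurrences=n_occ,
        n_genes_used=n_used,
        coverage_filter={
            "min_mean_reads": min_mean_reads,
            "min_total_reads": min_total_reads,
            "trim_head": head,
            "trim_tail": tail,
        },
    )


def compute_rcdt_stratified(
    profiles: dict[str, CodonOccupancyProfile],
    cds_seqs: dict[str, str],
    strata: Sequence[tuple[float, float]],
    *,
    condition_label: str = "",
    **kwargs,
) -> list[RCDTTable]:
    """``compute_rcdt`` applied independently to CDS-length strata.

    Each stratum is a half-open amino-acid length interval ``[lo, hi)``
    measured as codons excluding the terminal stop. Empty strata produce a
    warning and no table.
    """
    if not isinstance(profiles, dict):
        profiles = {p.gene_id: p for p in profiles}
    tables = []
    for lo, hi in strata:
        genes = {
            g
            for g, seq in cds_seqs.items()
            if lo <= _length_aa(seq) < hi and g in profiles
        }
        label = f"{lo:g}-{hi:g}aa"
        if not genes:
            logger.warning("stratum %s is empty; omitted", label)
            continue
        try:
            tables.append(
                compute_rcdt(
                    {g: profiles[g] for g in genes},
                    {g: cds_seqs[g] for g in genes},
                    condition_label=condition_label,
                    stratum=label,
                    **kwargs,
                )
            )
        except EmptyResultError:
            logger.warning("stratum %s: no gene passed the coverage filter; omitted", label)
    return tables


def _length_aa(seq: str) -> int:
    """CDS length in amino acids, excluding a terminal stop codon."""
    code = standard_code()
    n = len(seq) // 3
    if n and code.is_stop(seq[3 * (n - 1) : 3 * n].upper()):
        n -= 1
    return n


def delta_rcdt(a: RCDTTable, b: RCDTTable) -> dict[str, float]:
    """Per-codon RCDT difference a - b over the shared codon set."""
    shared = set(a.rcdt) & set(b.rcdt)
    if not shared:
        raise InputError("RCDT tables share no codons")
    return {c: a.rcdt[c] - b.rcdt[c] for c in sorted(shared)}
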