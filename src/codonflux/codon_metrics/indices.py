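"""Gene-level codon usage indices: CAI, CBI, optimal-codon sets, optimization.

CAI is the Sharp & Li geometric mean of relative adaptiveness over codons of
amino acids with two or more synonyms. CBI is the Bennetzen & Hall excess of
optimal-codon use over the random synonymous expectation. Single-codon
families (Met, Trp in the standard code) are excluded from both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from ..errors import ConfigurationError, InputError, UndefinedIndexError
from .genetic_code import GeneticCode, standard_code
from .usage import CodonUsageTable

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


def split_codons(seq: str, *, strict: bool = False, gene_id: str = "?") -> list[str]:
    """Split a CDS into uppercase codons.

    A trailing partial codon is trimmed (strict mode raises instead).
    Codons containing ``N`` are kept here and skipped downstream; any other
    letter is an input error.
    """
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise InputError(f"{gene_id}: invalid characters in sequence: {sorted(bad)}")
    rem = len(seq) % 3
    if rem:
        if strict:
            raise InputError(f"{gene_id}: CDS length {len(seq)} not divisible by 3")
        logger.warning("%s: trimming %d trailing nt (length not divisible by 3)", gene_id, rem)
        seq = seq[: len(seq) - rem]
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _sense_codons(
    seq: str, code: GeneticCode, *, strict: bool = False, gene_id: str = "?"
) -> list[str]:
    """Sense codons of a CDS: stops and N-containing codons are skipped."""
    out = []
    n_skipped = 0
    for codon in split_codons(seq, strict=strict, gene_id=gene_id):
        if "N" in codon:
            n_skipped += 1
            continue
        if codon not in code.codon_to_aa:
            raise InputError(f"{gene_id}: unknown codon {codon!r}")
        if code.is_stop(codon):
            continue
        out.append(codon)
    if n_skipped:
        logger.warning("%s: skipped %d codons containing N", gene_id, n_skipped)
    return out


def compute_cai(
    seq: str,
    table: CodonUsageTable,
    *,
    code: GeneticCode | None = None,
    strict: bool = False,
    gene_id: str = "?",
) -> float:
    """Codon adaptation index: geometric mean of w_c over eligible codons.

    Eligible codons are sense codons of amino acids with >= 2 synonyms.
    """
    code = code or table.code
    w = table.relative_adaptiveness()
    log_sum = 0.0
    n = 0
    for codon in _sense_codons(seq, code, strict=strict, gene_id=gene_id):
        if code.family_size(codon) < 2:
            continue
        wc = w[codon]
        if wc <= 0:
            # zero-frequency codon observed: conventionally floored to avoid -inf
            wc = 0.5 / 1000.0
        log_sum += math.log(wc)
        n += 1
    if n == 0:
        raise UndefinedIndexError(f"{gene_id}: no CAI-eligible codons")
    return math.exp(log_sum / n)


def derive_optimal_set(table: CodonUsageTable, code: GeneticCode | None = None) -> set[str]:
    """One optimal codon per multi-codon family: the most frequent synonym.

    Ties break to the lexicographically smallest codon, so the result is
    deterministic for any table.
    """
    code = code or table.code
    optimal: set[str] = set()
    for aa, fam in code.synonymous_families.items():
        if len(fam) < 2:
            continue
        fmax = max(table.codon_freq[c] for c in fam)
        if fmax <= 0:
            raise ConfigurationError(f"family of {aa} has all-zero frequencies: {fam}")
        optimal.add(min(c for c in fam if table.codon_freq[c] == fmax))
    return optimal


def compute_cbi(
    seq: str,
    optimal_set: set[str],
    code: GeneticCode | None = None,
    *,
    strict: bool = False,
    gene_id: str = "?",
) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran).

    N_tot counts codons of multi-codon families, N_opt those in
    ``optimal_set``, and N_ran the random-usage expectation
    sum_aa n_aa * k_opt,aa / k_syn,aa.
    """
    code = code or standard_code()
    for aa, fam in code.synonymous_families.items():
        if len(fam) >= 2 and not optimal_set.intersection(fam):
            raise ConfigurationError(f"optimal_set lacks a codon for family of {aa}")
    n_opt = 0
    n_tot = 0
    n_ran = 0.0
    for codon in _sense_codons(seq, code, strict=strict, gene_id=gene_id):
        fam = code.family_of(codon)
        k = len(fam)
        if k < 2:
            continue
        n_tot += 1
        if codon in optimal_set:
            n_opt += 1
        n_ran += len(optimal_set.intersection(fam)) / k
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        raise UndefinedIndexError(f"{gene_id}: CBI undefined (N_tot={n_tot}, N_ran={n_ran})")
    return (n_opt - n_ran) / (n_tot - n_ran)


def optimize_sequence(
    seq: str,
    optimal_set: set[str],
    code: GeneticCode | None = None,
    *,
    internal_stop: str = "error",
    gene_id: str = "?",
) -> str:
    """Replace every sense codon with its family's optimal codon.

    Single-codon families and stop codons are left unchanged, so the encoded
    protein is preserved and the operation is idempotent. An internal stop
    codon raises unless ``internal_stop='warn'``.
    """
    code = code or standard_code()
    by_family: dict[str, str] = {}
    for aa, fam in code.synonymous_families.items():
        chosen = sorted(optimal_set.intersection(fam))
        if len(fam) >= 2:
            if not chosen:
                raise ConfigurationError(f"optimal_set lacks a codon for family of {aa}")
            by_family[aa] = chosen[0]
        else:
            by_family[aa] = fam[0]
    codons = split_codons(seq, gene_id=gene_id)
    out = []
    for i, codon in enumerate(codons):
        if "N" in codon or codon not in code.codon_to_aa:
            out.append(codon)
            continue
        if code.is_stop(codon):
            if i != len(codons) - 1:
                msg = f"{gene_id}: internal stop codon {codon} at codon {i}"
                if internal_stop == "error":
                    raise InputError(msg)
                logger.warning(msg)
            out.append(codon)
            continue
        out.append(by_family[code.codon_to_aa[codon]])
    return "".join(out)


@dataclass
class CodonIndexRecord:
    """Per-gene codon usage indices; an index is None when undefined."""

    gene_id: str
    length_aa: int
    cai: float | None
    cbi: float | None
    tai: float | None


def compute_index_table(
    sequences: dict[str, str],
    table: CodonUsageTable,
    tai_weights: dict[str, float] | None = None,
    *,
    code: GeneticCode | None = None,
    optimal_set: set[str] | None = None,
) -> list[CodonIndexRecord]:
    """CAI/CBI/(optionally tAI) for a set of CDS sequences.

    ``length_aa`` counts sense codons (terminal stop excluded). Genes where
    an index is undefined get None there, with a logged warning.
    """
    from .tai import compute_gene_tai

    code = code or table.code
    optimal_set = optimal_set if optimal_set is not None else derive_optimal_set(table, code)
    records = []
    for gene_id, seq in sequences.items():
        sense = _sense_codons(seq, code, gene_id=gene_id)
        rec = CodonIndexRecord(gene_id=gene_id, length_aa=len(sense), cai=None, cbi=None, tai=None)
        try:
            rec.cai = compute_cai(seq, table, code=code, gene_id=gene_id)
            rec.cbi = compute_cbi(seq, optimal_set, code, gene_id=gene_id)
        except UndefinedIndexError as exc:
            logger.warning("%s", exc)
        if tai_weights is not None:
            try:
                rec.tai = compute_gene_tai(seq, tai_weights, code=code, gene_id=gene_id)
            except UndefinedIndexError as exc:
                logger.warning("%s", exc)
        records.append(rec)
    return records
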