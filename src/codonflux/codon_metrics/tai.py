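"""tRNA adaptation index weights from tRNA gene copy numbers.

For each sense codon the raw weight is the sum over recognizing anticodons
of ``(1 - s_pair) * tGCN``, where the Watson-Crick anticodon carries s = 0
and a single wobble anticodon carries the pair-specific penalty:

    codon 3rd base   wobble anticodon 1st base   pair     default s
    T                G                           G:U      0.41
    C                A (inosine)                 I:C      0.28
    A                A (inosine)                 I:A      0.9999
    G                T                           U:G      0.68

A wobble term is only included when the wobble anticodon's Watson-Crick
codon encodes the same amino acid, which excludes cross-family reading
(e.g. an Ile anticodon decoding AUG, or a stop-cognate anticodon decoding
UGG). The bacterial lysidine pair (``L-A:I``) is accepted in ``s_values``
for completeness but unused under this eukaryotic rule set.

Weights are normalized by their maximum; codons with zero raw weight are
assigned the geometric mean of the nonzero normalized weights, as in the
standard tAI formulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from ..errors import ConfigurationError, InputError, UndefinedIndexError
from .genetic_code import GeneticCode, reverse_complement, standard_code

logger = logging.getLogger(__name__)

DEFAULT_S_VALUES: dict[str, float] = {
    "G:U": 0.41,
    "I:C": 0.28,
    "I:A": 0.9999,
    "U:G": 0.68,
    "L-A:I": 0.89,
}

# codon third base -> (wobble anticodon first base, wobble pair label)
_WOBBLE = {
    "T": ("G", "G:U"),
    "C": ("A", "I:C"),
    "A": ("A", "I:A"),
    "G": ("T", "U:G"),
}


def _normalize(s: str) -> str:
    return s.upper().replace("U", "T")


@dataclass
class TAIParams:
    """Anticodon tRNA gene copy numbers plus wobble penalty constants."""

    anticodon_counts: dict[str, int]
    s_values: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_S_VALUES))

    def __post_init__(self) -> None:
        self.anticodon_counts = {
            _normalize(a): int(n) for a, n in self.anticodon_counts.items()
        }
        if any(n < 0 for n in self.anticodon_counts.values()):
            raise ConfigurationError("anticodon copy numbers must be nonnegative")
        if not any(n > 0 for n in self.anticodon_counts.values()):
            raise ConfigurationError("all anticodon copy numbers are zero")
        merged = dict(DEFAULT_S_VALUES)
        merged.update(self.s_values)
        self.s_values = merged
        for pair, s in self.s_values.items():
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(f"s value for {pair} outside [0,1]: {s}")


def read_trna_tsv(path: str | Path) -> TAIParams:
    """Read a two-column ``anticodon<TAB>count`` TSV (optional header)."""
    counts: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
        if lineno == 1 and parts[0].lower() == "anticodon":
            continue
        try:
            counts[_normalize(parts[0])] = counts.get(_normalize(parts[0]), 0) + int(parts[1])
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: bad count {parts[1]!r}") from exc
    return TAIParams(anticodon_counts=counts)


def recognizing_anticodons(codon: str, code: GeneticCode) -> list[tuple[str, str]]:
    """(anticodon, pair label) pairs that may decode ``codon``.

    The Watson-Crick anticodon is always listed (label ``WC``); the wobble
    anticodon is included only when its cognate codon is a same-family sense
    codon.
    """
    pairs = [(reverse_complement(codon), "WC")]
    wobble_base, label = _WOBBLE[codon[2]]
    wobble_anticodon = wobble_base + reverse_complement(codon[:2])
    cognate = reverse_complement(wobble_anticodon)
    if not code.is_stop(cognate) and code.codon_to_aa[cognate] == code.codon_to_aa[codon]:
        pairs.append((wobble_anticodon, label))
    return pairs


def compute_tai_weights(
    params: TAIParams, code: GeneticCode | None = None
) -> dict[str, float]:
    """Normalized tAI weight W in (0, 1] for every sense codon."""
    code = code or standard_code()
    raw: dict[str, float] = {}
    for codon in code.sense_codons:
        w = 0.0
        for anticodon, label in recognizing_anticodons(codon, code):
            s = 0.0 if label == "WC" else params.s_values[label]
            w += (1.0 - s) * params.anticodon_counts.get(anticodon, 0)
        raw[codon] = w
    wmax = max(raw.values())
    if wmax <= 0:
        raise ConfigurationError("all tAI raw weights are zero; check anticodon counts")
    weights = {c: w / wmax for c, w in raw.items()}
    nonzero = [w for w in weights.values() if w > 0]
    gmean = math.exp(sum(math.log(w) for w in nonzero) / len(nonzero))
    n_zero = 0
    for c, w in weights.items():
        if w == 0:
            weights[c] = gmean
            n_zero += 1
    if n_zero:
        logger.warning(
            "%d codons had no recognizing anticodon; assigned geometric-mean weight %.4g",
            n_zero,
            gmean,
        )
    return weights


def compute_gene_tai(
    seq: str,
    weights: dict[str, float],
    *,
    code: GeneticCode | None = None,
    gene_id: str = "?",
) -> float:
    """Gene tAI: geometric mean of W over all sense codons (stops excluded)."""
    from .indices import _sense_codons

    code = code or standard_code()
    log_sum = 0.0
    n = 0
    for codon in _sense_codons(seq, code, gene_id=gene_id):
        log_sum += math.log(weights[codon])
        n += 1
    if n == 0:
        raise UndefinedIndexError(f"{gene_id}: no sense codons for tAI")
    return math.exp(log_sum / n)
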