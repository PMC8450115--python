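"""Genetic code tables: codon -> amino acid and synonymous families.

Codons are DNA trinucleotides (uppercase ACGT). The standard code is built
from Biopython's NCBI table 1 and cached at import time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from ..errors import ConfigurationError

STOP = "*"

_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: 64 codons mapped to amino acids or ``*`` for stop.

    ``synonymous_families`` maps each amino-acid symbol to its codons in
    lexicographic order; stop codons are excluded from families.
    """

    codon_to_aa: dict[str, str]
    synonymous_families: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ConfigurationError(
                f"genetic code must define 64 codons, got {len(self.codon_to_aa)}"
            )
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.codon_to_aa):
            aa = self.codon_to_aa[codon]
            if aa != STOP:
                fams.setdefault(aa, []).append(codon)
        object.__setattr__(self, "synonymous_families", fams)

    @property
    def sense_codons(self) -> list[str]:
        return sorted(c for c, a in self.codon_to_aa.items() if a != STOP)

    @property
    def stop_codons(self) -> list[str]:
        return sorted(c for c, a in self.codon_to_aa.items() if a == STOP)

    def family_of(self, codon: str) -> list[str]:
        return self.synonymous_families[self.codon_to_aa[codon]]

    def family_size(self, codon: str) -> int:
        return len(self.family_of(codon))

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP

    def translate(self, seq: str) -> str:
        """Translate a CDS (length multiple of 3) to amino acids, stop as '*'."""
        return "".join(
            self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3)
        )


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI translation table 1): 61 sense codons."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(codon_to_aa=mapping)
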