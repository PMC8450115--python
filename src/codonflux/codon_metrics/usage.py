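"""Codon usage frequency tables and their parsers.

Two dialects are supported:

* the Kazusa Codon Usage Database flat format, where each codon appears as
  ``UUU 26.1(  1000)`` (RNA letters, frequency per thousand, raw count in
  parentheses), several codons per line;
* a minimal two-column TSV ``codon<TAB>frequency`` with an optional header.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from ..errors import ConfigurationError, InputError
from .genetic_code import GeneticCode, standard_code

_KAZUSA_ENTRY = re.compile(r"([ACGTUacgtu]{3})\s+([0-9.]+)\s*\(\s*([0-9]+)\s*\)")


def _normalize_codon(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass
class CodonUsageTable:
    """Per-codon usage frequencies over the 61 sense codons.

    ``codon_freq`` holds one nonnegative value per sense codon; ``unit``
    records whether values are per-thousand frequencies or raw counts
    (the indices below only use ratios, so the unit does not affect them).
    """

    codon_freq: dict[str, float]
    source_label: str = ""
    unit: str = "per_thousand"
    code: GeneticCode = field(default_factory=standard_code)

    def __post_init__(self) -> None:
        self.codon_freq = {_normalize_codon(c): float(f) for c, f in self.codon_freq.items()}
        sense = set(self.code.sense_codons)
        missing = sense - set(self.codon_freq)
        if missing:
            raise InputError(
                f"usage table '{self.source_label}' missing {len(missing)} sense codons, "
                f"e.g. {sorted(missing)[:3]}"
            )
        bad = {c: f for c, f in self.codon_freq.items() if c in sense and f < 0}
        if bad:
            raise InputError(f"negative codon frequencies: {bad}")
        # keep only sense codons; stop-codon usage is irrelevant to the indices
        self.codon_freq = {c: self.codon_freq[c] for c in sorted(sense)}

    def relative_adaptiveness(self) -> dict[str, float]:
        """w_c = freq(c) / max synonymous freq, per sense codon.

        Families whose codons all have zero frequency raise, since w is
        undefined there.
        """
        w: dict[str, float] = {}
        for aa, fam in self.code.synonymous_families.items():
            fmax = max(self.codon_freq[c] for c in fam)
            if fmax <= 0:
                raise ConfigurationError(f"all-zero usage for family of {aa}: {fam}")
            for c in fam:
                w[c] = self.codon_freq[c] / fmax
        return w


def read_kazusa(path: str | Path, source_label: str | None = None) -> CodonUsageTable:
    """Parse a Kazusa-style codon usage file (frequency per thousand)."""
    text = Path(path).read_text()
    entries = _KAZUSA_ENTRY.findall(text)
    if not entries:
        raise InputError(f"no Kazusa-style codon entries found in {path}")
    freqs = {_normalize_codon(c): float(per_k) for c, per_k, _count in entries}
    return CodonUsageTable(
        codon_freq=freqs,
        source_label=source_label or str(path),
        unit="per_thousand",
    )


def read_usage_tsv(path: str | Path, source_label: str | None = None) -> CodonUsageTable:
    """Parse the two-column ``codon<TAB>frequency`` dialect."""
    freqs: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
        codon, freq = parts
        if lineno == 1 and codon.lower() in {"codon"}:
            continue
        try:
            freqs[_normalize_codon(codon)] = float(freq)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: bad frequency {freq!r}") from exc
    return CodonUsageTable(codon_freq=freqs, source_label=source_label or str(path))


def write_usage_tsv(table: CodonUsageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tfrequency\n")
        for codon in sorted(table.codon_freq):
            fh.write(f"{codon}\t{table.codon_freq[codon]:.6g}\n")
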