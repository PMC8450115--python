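"""Shared fixtures: toy usage tables, tRNA params, random gene factories."""

from __future__ import annotations

import numpy as np
import pytest

from codonflux.codon_metrics import (
    CodonUsageTable,
    TAIParams,
    standard_code,
)
from codonflux.synthetic_data import default_usage_table


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def usage(code):
    """Deterministic ladder usage table: lexicographically first codon optimal."""
    return default_usage_table(code)


@pytest.fixture(scope="session")
def flat_usage(code):
    """All synonyms equally frequent (every w_c = 1)."""
    return CodonUsageTable(
        codon_freq={c: 10.0 for c in code.sense_codons}, source_label="flat"
    )


@pytest.fixture(scope="session")
def trna_params(code):
    """Every sense codon's Watson-Crick anticodon present with equal counts."""
    from codonflux.codon_metrics import reverse_complement

    return TAIParams(
        anticodon_counts={reverse_complement(c): 4 for c in code.sense_codons},
        s_values={"G:U": 1.0, "I:C": 1.0, "I:A": 1.0, "U:G": 1.0},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_genes(code):
    """Factory: n random CDSs built from uniform sense codons plus a stop."""

    def make(n: int, min_codons: int = 30, max_codons: int = 300, seed: int = 0):
        gen = np.random.default_rng(seed)
        sense = code.sense_codons
        out = {}
        for i in range(n):
            m = int(gen.integers(min_codons, max_codons + 1))
            idx = gen.integers(0, len(sense), size=m)
            out[f"t{i:04d}"] = "".join(sense[j] for j in idx) + "TAA"
        return out

    return make
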