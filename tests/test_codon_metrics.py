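"""codon_metrics unit tests against independent naive-loop oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonflux.codon_metrics import (
    CodonUsageTable,
    TAIParams,
    compute_cai,
    compute_cbi,
    compute_gene_tai,
    compute_tai_weights,
    derive_optimal_set,
    optimize_sequence,
    split_codons,
    standard_code,
)
from codonflux.errors import ConfigurationError, InputError, UndefinedIndexError

# ---------------------------------------------------------------- oracles


def naive_cai(seq, table, code):
    """Per-codon loop, dict lookups recomputed each time."""
    logs = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon or code.is_stop(codon):
            continue
        fam = code.family_of(codon)
        if len(fam) < 2:
            continue
        w = table.codon_freq[codon] / max(table.codon_freq[c] for c in fam)
        logs.append(math.log(w if w > 0 else 0.0005))
    assert logs
    return math.exp(sum(logs) / len(logs))


def naive_cbi(seq, optimal, code):
    n_opt = n_tot = 0
    n_ran = 0.0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon or code.is_stop(codon):
            continue
        fam = code.family_of(codon)
        if len(fam) < 2:
            continue
        n_tot += 1
        n_opt += codon in optimal
        n_ran += sum(c in optimal for c in fam) / len(fam)
    return (n_opt - n_ran) / (n_tot - n_ran)


def naive_gene_tai(seq, weights, code):
    logs = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon or code.is_stop(codon):
            continue
        logs.append(math.log(weights[codon]))
    return math.exp(sum(logs) / len(logs))


# ---------------------------------------------------------------- CAI


class TestCAI:
    def test_all_optimal_is_one(self, usage, code):
        optimal = derive_optimal_set(usage, code)
        seq = "".join(sorted(optimal)) + "TAA"
        assert compute_cai(seq, usage) == pytest.approx(1.0)

    def test_two_codon_family_hand_value(self, code):
        # one family with 75:25 usage; gene = (optimal, rare) from that family
        freqs = {c: 10.0 for c in code.sense_codons}
        freqs["AAA"], freqs["AAG"] = 75.0, 25.0
        table = CodonUsageTable(codon_freq=freqs, source_label="toy")
        assert compute_cai("AAAAAG", table) == pytest.approx(math.sqrt(1.0 / 3.0), abs=1e-12)
        assert compute_cai("AAAAAG", table) == pytest.approx(0.57735, abs=1e-5)

    def test_single_codon_families_undefined(self, usage):
        with pytest.raises(UndefinedIndexError):
            compute_cai("ATGTGGATG", usage)  # Met/Trp only

    def test_unknown_characters_rejected(self, usage):
        with pytest.raises(InputError):
            compute_cai("AXGGCT", usage)

    def test_n_codons_skipped(self, usage):
        with_n = compute_cai("GCANNNGCC", usage)
        without = compute_cai("GCAGCC", usage)
        assert with_n == pytest.approx(without)

    def test_trailing_partial_codon_trimmed(self, usage):
        assert compute_cai("GCAGCCAG", usage) == pytest.approx(compute_cai("GCAGCC", usage))
        with pytest.raises(InputError):
            compute_cai("GCAGCCAG", usage, strict=True)

    def test_matches_oracle_on_random_genes(self, usage, code, random_genes):
        for gid, seq in random_genes(100, seed=11).items():
            assert compute_cai(seq, usage, gene_id=gid) == pytest.approx(
                naive_cai(seq, usage, code), abs=1e-12
            )


# ---------------------------------------------------------------- CBI


class TestCBI:
    def test_all_optimal_is_one(self, usage, code):
        optimal = derive_optimal_set(usage, code)
        seq = "".join(sorted(optimal))
        assert compute_cbi(seq, optimal, code) == pytest.approx(1.0)

    def test_hand_value_two_families(self, code, flat_usage):
        # Lys: AAA x3 + AAG; Asn: AAC + AAT; optimal = {AAA, AAC, ...}
        optimal = derive_optimal_set(flat_usage, code)  # lexicographic under ties
        assert {"AAA", "AAC"} <= optimal
        seq = "AAA" * 3 + "AAG" + "AAC" + "AAT"
        # N_opt=4, N_tot=6, N_ran=3 -> 1/3
        assert compute_cbi(seq, optimal, code) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_random_expectation_is_zero(self, code):
        # codon counts exactly at the uniform-synonym expectation
        fam = code.synonymous_families["A"]  # 4 codons
        seq = "".join(fam)  # one of each: N_opt=1, N_ran=4*(1/4)=1
        optimal = {min(fam)} | {
            min(f) for aa, f in code.synonymous_families.items() if len(f) >= 2
        }
        assert compute_cbi(seq, optimal, code) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_raises(self, code, usage):
        optimal = derive_optimal_set(usage, code)
        with pytest.raises(UndefinedIndexError):
            compute_cbi("ATGTGG", optimal, code)  # no multi-family codons

    def test_incomplete_optimal_set_rejected(self, code):
        with pytest.raises(ConfigurationError):
            compute_cbi("AAAAAG", {"AAA"}, code)

    def test_matches_oracle_on_random_genes(self, usage, code, random_genes):
        optimal = derive_optimal_set(usage, code)
        for gid, seq in random_genes(100, seed=13).items():
            assert compute_cbi(seq, optimal, code, gene_id=gid) == pytest.approx(
                naive_cbi(seq, optimal, code), abs=1e-12
            )

    def test_uniform_sampling_converges_to_zero(self, code, rng):
        """CBI -> 0 when synonyms are drawn uniformly within families."""
        optimal = {min(f) for f in code.synonymous_families.values() if len(f) >= 2}
        fams = [f for f in code.synonymous_families.values()]
        vals = []
        for _ in range(5):
            codons = []
            for _ in range(10_000):
                fam = fams[rng.integers(len(fams))]
                codons.append(fam[rng.integers(len(fam))])
            vals.append(compute_cbi("".join(codons), optimal, code))
        assert abs(np.mean(vals)) < 0.05


# ---------------------------------------------------------------- optimal set


class TestDeriveOptimalSet:
    def test_argmax(self, code):
        freqs = {c: 10.0 for c in code.sense_codons}
        freqs["AAA"], freqs["AAG"] = 60.0, 40.0
        table = CodonUsageTable(codon_freq=freqs)
        assert "AAA" in derive_optimal_set(table, code)

    def test_tie_breaks_lexicographic(self, flat_usage, code):
        optimal = derive_optimal_set(flat_usage, code)
        for aa, fam in code.synonymous_families.items():
            if len(fam) >= 2:
                assert optimal.intersection(fam) == {min(fam)}

    def test_zero_family_is_config_error(self, code):
        freqs = {c: 10.0 for c in code.sense_codons}
        for c in code.synonymous_families["K"]:
            freqs[c] = 0.0
        with pytest.raises(ConfigurationError):
            derive_optimal_set(CodonUsageTable(codon_freq=freqs), code)

    def test_one_codon_per_multi_family(self, usage, code):
        optimal = derive_optimal_set(usage, code)
        n_multi = sum(1 for f in code.synonymous_families.values() if len(f) >= 2)
        assert len(optimal) == n_multi


# ---------------------------------------------------------------- tAI


class TestTAI:
    def test_equal_counts_watson_crick_all_one(self, trna_params, code):
        weights = compute_tai_weights(trna_params, code)
        assert all(w == pytest.approx(1.0) for w in weights.values())

    def test_wobble_ratio_059(self, code):
        # TTT decoded only through G:U wobble by GAA (tGCN 10); TTC is GAA's
        # Watson-Crick codon -> ratio 1 - 0.41 = 0.59
        params = TAIParams(anticodon_counts={"GAA": 10})
        weights = compute_tai_weights(params, code)
        assert weights["TTT"] / weights["TTC"] == pytest.approx(0.59)

    def test_unrecognized_codon_gets_geometric_mean(self, code):
        params = TAIParams(anticodon_counts={"GAA": 10})
        weights = compute_tai_weights(params, code)
        decoded = {"TTC": weights["TTC"], "TTT": weights["TTT"]}
        others = [w for c, w in weights.items() if c not in decoded]
        nonzero = list(decoded.values())
        expected = math.exp(sum(math.log(w) for w in nonzero) / len(nonzero))
        assert all(w == pytest.approx(expected) for w in others)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            TAIParams(anticodon_counts={"GAA": 0})

    def test_s_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            TAIParams(anticodon_counts={"GAA": 1}, s_values={"G:U": 1.5})

    def test_gene_tai_trivial_values(self, trna_params, code):
        weights = compute_tai_weights(trna_params, code)
        assert compute_gene_tai("AAAGCT", weights) == pytest.approx(1.0)
        w2 = dict(weights)
        w2["AAA"], w2["GCT"] = 0.25, 1.0
        assert compute_gene_tai("AAAGCT", w2) == pytest.approx(0.5)

    def test_gene_tai_empty_raises(self, trna_params):
        weights = compute_tai_weights(trna_params)
        with pytest.raises(UndefinedIndexError):
            compute_gene_tai("TAA", weights)

    def test_matches_oracle_on_random_genes(self, code, random_genes):
        from codonflux.io_cli.pipeline import trna_params_from_usage
        from codonflux.synthetic_data import default_usage_table

        weights = compute_tai_weights(trna_params_from_usage(default_usage_table()), code)
        for gid, seq in random_genes(100, seed=17).items():
            assert compute_gene_tai(seq, weights, gene_id=gid) == pytest.approx(
                naive_gene_tai(seq, weights, code), abs=1e-12
            )


# ---------------------------------------------------------------- optimization


def _codon_strategy():
    sense = standard_code().sense_codons
    return st.lists(st.sampled_from(sense), min_size=1, max_size=120)


class TestOptimizeSequence:
    @given(codons=_codon_strategy())
    @settings(max_examples=50, deadline=None)
    def test_protein_preserved_and_idempotent(self, codons):
        code = standard_code()
        from codonflux.synthetic_data import default_usage_table

        usage = default_usage_table(code)
        optimal = derive_optimal_set(usage, code)
        seq = "".join(codons) + "TAA"
        out = optimize_sequence(seq, optimal, code)
        assert code.translate(out) == code.translate(seq)
        assert optimize_sequence(out, optimal, code) == out

    def test_direct_substitution(self, code):
        freqs = {c: 10.0 for c in code.sense_codons}
        freqs["AAA"], freqs["AAG"] = 60.0, 40.0
        table = CodonUsageTable(codon_freq=freqs)
        optimal = derive_optimal_set(table, code)
        out = optimize_sequence("AAGAAA", optimal, code)
        assert out == "AAAAAA"

    def test_internal_stop_rejected(self, usage, code):
        optimal = derive_optimal_set(usage, code)
        with pytest.raises(InputError):
            optimize_sequence("AAATAAGCT", optimal, code)
        # warn mode passes through
        out = optimize_sequence("AAATAAGCT", optimal, code, internal_stop="warn")
        assert out[3:6] == "TAA"

    def test_never_decreases_indices(self, usage, code, random_genes):
        """Weak monotonicity of CAI/CBI/tAI under optimization (1000 genes)."""
        from codonflux.io_cli.pipeline import trna_params_from_usage

        optimal = derive_optimal_set(usage, code)
        weights = compute_tai_weights(trna_params_from_usage(usage), code)
        for gid, seq in random_genes(1000, min_codons=20, max_codons=120, seed=19).items():
            opt = optimize_sequence(seq, optimal, code, gene_id=gid)
            assert compute_cai(opt, usage) >= compute_cai(seq, usage) - 1e-12
            assert compute_cbi(opt, optimal, code) >= compute_cbi(seq, optimal, code) - 1e-12
            assert compute_gene_tai(opt, weights) >= compute_gene_tai(seq, weights) - 1e-12


# ---------------------------------------------------------------- bounds


@given(codons=_codon_strategy())
@settings(max_examples=50, deadline=None)
def test_index_bounds(codons):
    code = standard_code()
    from codonflux.synthetic_data import default_usage_table

    usage = default_usage_table(code)
    optimal = derive_optimal_set(usage, code)
    seq = "".join(codons)
    try:
        cai = compute_cai(seq, usage)
        assert 0.0 < cai <= 1.0
    except UndefinedIndexError:
        pass
    try:
        cbi = compute_cbi(seq, optimal, code)
        assert -1.0 - 1e-9 <= cbi <= 1.0 + 1e-9
    except UndefinedIndexError:
        pass


def test_split_codons_rejects_bad_letters():
    with pytest.raises(InputError):
        split_codons("AAU")  # RNA letters are not accepted in CDS input
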