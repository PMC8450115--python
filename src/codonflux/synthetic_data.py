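"""Synthetic transcriptomes, proteomes, and two-condition footprint studies.

Every generator plants explicit, recoverable structure:

* per-gene synonymous-codon bias (``p_opt``) and a broad CDS-length spread;
* protein abundance whose log declines with length at a rate that weakens
  as codon optimality rises;
* footprints sampled multinomially from per-codon dwell times, with
  condition modifiers (global/exponent dwell scaling, initiation scaling,
  a long-gene dwell factor) and A-site 5' positions chosen so that
  ``assign_a_sites`` inverts the generator exactly.

All randomness flows from one ``numpy`` seed; replicate streams are spawned
deterministically from it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon_metrics.genetic_code import GeneticCode, standard_code
from .codon_metrics.usage import CodonUsageTable
from .errors import ConfigurationError
from .ribo_quant import DEFAULT_OFFSETS, _codon_index_arrays

DEFAULT_READ_LENGTH_DIST: dict[int, float] = {27: 0.15, 28: 0.5, 29: 0.25, 30: 0.1}


@dataclass
class ConditionModifiers:
    """How a condition reshapes the baseline dwell/initiation model.

    Effective dwell is ``dwell_scale * d ** dwell_exponent`` (an exponent
    below 1 compresses dwell spread, accelerating rare codons the most);
    genes at or above the long-CDS threshold get an extra multiplicative
    ``long_dwell_factor``; per-gene initiation is scaled by ``init_scale``.
    """

    dwell_exponent: float = 1.0
    dwell_scale: float = 1.0
    init_scale: float = 1.0
    long_dwell_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dwell_exponent", "dwell_scale", "init_scale", "long_dwell_factor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    def effective_dwell(self, dwell: np.ndarray) -> np.ndarray:
        return self.dwell_scale * np.power(dwell, self.dwell_exponent)


def default_conditions() -> dict[str, ConditionModifiers]:
    """Baseline vs. globally accelerated elongation with elevated initiation.

    The accelerated condition compresses dwell spread (rare codons sped up
    preferentially), scales dwells down globally, raises initiation, and
    weakens the long-gene slowdown.
    """
    return {
        "baseline": ConditionModifiers(long_dwell_factor=2.5),
        "fast": ConditionModifiers(
            dwell_exponent=0.5, dwell_scale=0.45, init_scale=1.25, long_dwell_factor=1.0
        ),
    }


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    # lognormal CDS length in aa, truncated
    length_median_aa: float = 400.0
    length_log_sigma: float = 0.6
    length_min_aa: int = 60
    length_max_aa: int = 3000
    # per-gene optimality p_opt ~ Beta(alpha, beta); None fixes p_opt = popt_fixed
    popt_alpha: float = 2.0
    popt_beta: float = 2.0
    popt_fixed: float | None = None
    # abundance model: log10 A = a - (b0 - b1 * optimality) * length + N(0, sigma)
    abund_a: float = 6.0
    abund_b0: float = 2.0e-3
    abund_b1: float = 1.6e-3
    abund_sigma: float = 0.2
    missing_rate: float = 0.0
    # expression/initiation spread (lognormal sigmas)
    init_sigma: float = 0.4
    mrna_sigma: float = 0.5
    # sequencing depth: mean RPF (mRNA) reads per codon at baseline
    depth: float = 10.0
    mrna_depth: float = 10.0
    read_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_READ_LENGTH_DIST)
    )
    offsets: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    dwell_min: float = 0.5
    dwell_max: float = 3.0
    long_threshold_aa: float = 600.0
    replicates: int = 4
    rep_cv: float = 0.1
    conditions: dict[str, ConditionModifiers] = field(default_factory=default_conditions)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.length_min_aa < 1 or self.length_max_aa < self.length_min_aa:
            raise ConfigurationError("invalid CDS length bounds")
        if self.abund_sigma < 0 or self.rep_cv < 0:
            raise ConfigurationError("sigmas must be nonnegative")
        if not self.abund_b0 > self.abund_b1 >= 0:
            raise ConfigurationError(
                "need b0 > b1 >= 0 so the planted length effect stays negative"
            )
        if self.depth <= 0 or self.mrna_depth <= 0:
            raise ConfigurationError("depths must be positive")
        if not 0 < self.dwell_min <= self.dwell_max:
            raise ConfigurationError("invalid dwell bounds")
        if self.replicates < 2:
            raise ConfigurationError("need at least 2 replicates per condition")
        total = sum(self.read_length_dist.values())
        if total <= 0 or any(p < 0 for p in self.read_length_dist.values()):
            raise ConfigurationError("invalid read-length distribution")
        self.read_length_dist = {k: v / total for k, v in self.read_length_dist.items()}
        missing = set(self.read_length_dist) - set(self.offsets)
        if missing:
            raise ConfigurationError(f"no A-site offset for read lengths {sorted(missing)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = {k: dataclasses.asdict(v) for k, v in self.conditions.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = {
                k: ConditionModifiers(**v) for k, v in d["conditions"].items()
            }
        for key in ("read_length_dist", "offsets"):
            if key in d:
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)


def default_usage_table(code: GeneticCode | None = None) -> CodonUsageTable:
    """Deterministic synthetic usage table with a geometric preference ladder.

    Within each family, codons in lexicographic order get weights
    1, 1/2, 1/4, ..., so the lexicographically first codon is optimal and
    there are no ties.
    """
    code = code or standard_code()
    freqs: dict[str, float] = {}
    for fam in code.synonymous_families.values():
        for j, codon in enumerate(fam):
            freqs[codon] = 0.5**j
    total = sum(freqs.values())
    return CodonUsageTable(
        codon_freq={c: 1000.0 * f / total for c, f in freqs.items()},
        source_label="codonflux-synthetic",
        code=code,
    )


def dwell_from_usage(
    usage: CodonUsageTable, dwell_min: float = 0.5, dwell_max: float = 3.0
) -> dict[str, float]:
    """Per-codon dwell inversely monotone with within-family preference.

    The most preferred synonym gets ``dwell_min``; dwell rises linearly as
    relative adaptiveness falls.
    """
    w = usage.relative_adaptiveness()
    return {c: dwell_min + (dwell_max - dwell_min) * (1.0 - wc) for c, wc in w.items()}


def null_popt(code: GeneticCode | None = None) -> float:
    """p_opt at which optimal-codon use matches the uniform-synonym null.

    Equals the mean of 1/family_size over multi-codon families under a
    uniform amino-acid composition, so the expected CBI is 0.
    """
    code = code or standard_code()
    ks = [len(f) for f in code.synonymous_families.values() if len(f) >= 2]
    return float(np.mean([1.0 / k for k in ks]))


@dataclass
class GroundTruth:
    """Planted parameters sufficient to score recovery at every stage."""

    genes: pd.DataFrame
    dwell: dict[str, float]
    usage_label: str = ""
    config: dict = field(default_factory=dict)
    footprint_totals: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "dwell": self.dwell,
            "usage_label": self.usage_label,
            "config": self.config,
            "footprint_totals": self.footprint_totals,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        genes = pd.DataFrame(payload["genes"]).set_index("gene_id")
        return cls(
            genes=genes,
            dwell=payload["dwell"],
            usage_label=payload.get("usage_label", ""),
            config=payload.get("config", {}),
            footprint_totals=payload.get("footprint_totals", {}),
        )


def _sample_lengths(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(cfg.n_genes, dtype=np.int64)
    filled = 0
    attempts = 0
    while filled < cfg.n_genes:
        draw = np.floor(
            rng.lognormal(
                mean=np.log(cfg.length_median_aa),
                sigma=cfg.length_log_sigma,
                size=max(cfg.n_genes, 1024),
            )
        ).astype(np.int64)
        draw = draw[(draw >= cfg.length_min_aa) & (draw <= cfg.length_max_aa)]
        take = min(len(draw), cfg.n_genes - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
        attempts += 1
        if attempts > 10_000:
            raise ConfigurationError(
                "length distribution rarely hits the truncation bounds "
                f"[{cfg.length_min_aa}, {cfg.length_max_aa}]"
            )
    return out


def simulate_transcriptome(
    cfg: SimulationConfig,
    usage: CodonUsageTable | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Draw CDS sequences with planted per-gene codon bias.

    Amino acids are uniform over the 20 standard residues; within each
    multi-codon family the optimal codon is used with probability ``p_opt``
    and otherwise a uniform non-optimal synonym. A TAA stop terminates each
    CDS. Ground truth records length, p_opt, and a per-gene optimality score
    (geometric mean of relative adaptiveness over sense codons).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    usage = usage or default_usage_table()
    code = usage.code
    w = usage.relative_adaptiveness()

    aas = sorted(code.synonymous_families)
    fam_codons = []  # per aa: optimal first, then the other synonyms
    for aa in aas:
        fam = code.synonymous_families[aa]
        fmax = max(usage.codon_freq[c] for c in fam)
        optimal = min(c for c in fam if usage.codon_freq[c] == fmax)
        fam_codons.append([optimal] + [c for c in fam if c != optimal])
    fam_sizes = np.array([len(f) for f in fam_codons])
    pad = np.full((len(aas), fam_sizes.max()), "", dtype="<U3")
    logw = np.zeros_like(pad, dtype=float)
    for i, fams in enumerate(fam_codons):
        for j, codon in enumerate(fams):
            pad[i, j] = codon
            logw[i, j] = np.log(w[codon])

    lengths = _sample_lengths(cfg, rng)
    if cfg.popt_fixed is not None:
        popt = np.full(cfg.n_genes, float(cfg.popt_fixed))
    else:
        popt = rng.beta(cfg.popt_alpha, cfg.popt_beta, size=cfg.n_genes)

    width = len(str(cfg.n_genes))
    seqs: dict[str, str] = {}
    optimality = np.empty(cfg.n_genes)
    for g in range(cfg.n_genes):
        n = int(lengths[g])
        aa_idx = rng.integers(0, len(aas), size=n)
        k = fam_sizes[aa_idx]
        use_opt = (rng.random(n) < popt[g]) | (k == 1)
        syn_idx = np.where(use_opt, 0, 1 + (rng.integers(0, 1 << 30, size=n) % np.maximum(k - 1, 1)))
        codons = pad[aa_idx, syn_idx]
        seqs[f"g{g:0{width}d}"] = "".join(codons) + "TAA"
        optimality[g] = float(np.exp(logw[aa_idx, syn_idx].mean()))

    genes = pd.DataFrame(
        {
            "gene_id": list(seqs),
            "length_aa": lengths,
            "p_opt": popt,
            "optimality": optimality,
        }
    ).set_index("gene_id")
    gt = GroundTruth(
        genes=genes,
        dwell=dwell_from_usage(usage, cfg.dwell_min, cfg.dwell_max),
        usage_label=usage.source_label,
        config=cfg.to_dict(),
    )
    return seqs, gt


def simulate_proteome(
    cfg: SimulationConfig, gt: GroundTruth, rng: np.random.Generator | None = None
) -> pd.Series:
    """Protein abundances from the planted length x optimality model.

    log10(abundance) = a - (b0 - b1 * optimality) * length + N(0, sigma);
    a fraction ``missing_rate`` of genes is masked missing at random. The
    drawn abundances are stored in ``gt.genes['abundance']``.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    lengths = gt.genes["length_aa"].to_numpy(dtype=float)
    opt = gt.genes["optimality"].to_numpy(dtype=float)
    slope = cfg.abund_b0 - cfg.abund_b1 * opt
    log10_abund = cfg.abund_a - slope * lengths + rng.normal(0.0, cfg.abund_sigma, len(lengths))
    abund = np.power(10.0, log10_abund)
    if cfg.missing_rate > 0:
        abund[rng.random(len(abund)) < cfg.missing_rate] = np.nan
    gt.genes["abundance"] = abund
    return pd.Series(abund, index=gt.genes.index, name="abundance")


def _ensure_expression(cfg: SimulationConfig, gt: GroundTruth, rng: np.random.Generator) -> None:
    if "init_rate" not in gt.genes.columns:
        n = len(gt.genes)
        gt.genes["init_rate"] = rng.lognormal(0.0, cfg.init_sigma, n)
        gt.genes["mrna_level"] = rng.lognormal(0.0, cfg.mrna_sigma, n)


def _position_weights(
    cfg: SimulationConfig,
    encoded: np.ndarray,
    dwell_vec: np.ndarray,
    is_long: bool,
    mods: ConditionModifiers,
) -> np.ndarray:
    """Sampling weight per codon position (0 where no A-site read can land)."""
    w = np.where(encoded >= 0, dwell_vec[np.maximum(encoded, 0)], 0.0)
    if is_long:
        w = w * mods.long_dwell_factor
    min_codon = int(np.ceil(max(cfg.offsets.values()) / 3.0))
    w[:min_codon] = 0.0
    return w


def depth_calibration(
    cfg: SimulationConfig, seqs: dict[str, str], gt: GroundTruth
) -> float:
    """Scale factor giving ~cfg.depth mean reads/codon under baseline dwells."""
    code = standard_code()
    encoded, sense = _codon_index_arrays(seqs, code)
    dwell_vec = np.array([gt.dwell[c] for c in sense])
    expected = 0.0
    total_codons = 0
    for gene, arr in encoded.items():
        w = np.where(arr >= 0, dwell_vec[np.maximum(arr, 0)], 0.0)
        expected += (
            gt.genes.at[gene, "mrna_level"] * gt.genes.at[gene, "init_rate"] * w.sum()
        )
        total_codons += arr.size
    return cfg.depth * total_codons / expected


def simulate_footprints(
    cfg: SimulationConfig,
    seqs: dict[str, str],
    gt: GroundTruth,
    condition: str,
    rng: np.random.Generator | None = None,
    calibration: float | None = None,
    dataset_label: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """One footprint library plus paired mRNA-seq counts for a condition.

    Per-gene footprint totals are Poisson with mean proportional to
    mRNA level x initiation rate x summed effective dwell; positions are
    multinomial over per-codon weights; 5' positions are back-computed from
    the A-site offsets so assignment inverts the generator exactly.
    """
    if condition not in cfg.conditions:
        raise ConfigurationError(f"unknown condition {condition!r}")
    mods = cfg.conditions[condition]
    rng = rng or np.random.default_rng(cfg.seed + 2)
    _ensure_expression(cfg, gt, rng)
    if calibration is None:
        calibration = depth_calibration(cfg, seqs, gt)

    code = standard_code()
    encoded, sense = _codon_index_arrays(seqs, code)
    dwell_vec = mods.effective_dwell(np.array([gt.dwell[c] for c in sense]))

    read_lengths = np.array(sorted(cfg.read_length_dist), dtype=np.int64)
    read_probs = np.array([cfg.read_length_dist[int(l)] for l in read_lengths])
    offset_by_len = {int(l): int(cfg.offsets[int(l)]) for l in read_lengths}

    jitter_rpf = rng.lognormal(-0.5 * cfg.rep_cv**2, cfg.rep_cv, len(gt.genes))
    jitter_mrna = rng.lognormal(-0.5 * cfg.rep_cv**2, cfg.rep_cv, len(gt.genes))

    frames = []
    mrna_counts = {}
    totals: dict[str, int] = {}
    total_codons = sum(a.size for a in encoded.values())
    mrna_scale = (
        cfg.mrna_depth
        * total_codons
        / float((gt.genes["mrna_level"] * (gt.genes["length_aa"] + 1)).sum())
    )
    for gi, (gene, arr) in enumerate(encoded.items()):
        row = gt.genes.loc[gene]
        is_long = row["length_aa"] >= cfg.long_threshold_aa
        w = _position_weights(cfg, arr, dwell_vec, is_long, mods)
        wsum = w.sum()
        mean_reads = (
            calibration * mods.init_scale * row["mrna_level"] * row["init_rate"] * wsum
        ) * jitter_rpf[gi]
        n_reads = int(rng.poisson(mean_reads)) if mean_reads > 0 else 0
        totals[gene] = n_reads
        mrna_counts[gene] = int(
            rng.poisson(mrna_scale * row["mrna_level"] * arr.size * jitter_mrna[gi])
        )
        if n_reads == 0:
            continue
        pos_counts = rng.multinomial(n_reads, w / wsum)
        codon_idx = np.repeat(np.arange(arr.size), pos_counts)
        lens = read_lengths[rng.choice(len(read_lengths), size=n_reads, p=read_probs)]
        offs = np.array([offset_by_len[int(l)] for l in read_lengths])[
            np.searchsorted(read_lengths, lens)
        ]
        five_prime = 3 * codon_idx - offs
        frames.append(
            pd.DataFrame(
                {"gene_id": gene, "five_prime_pos": five_prime, "read_length": lens}
            )
        )
    if frames:
        footprints = pd.concat(frames, ignore_index=True)
    else:
        footprints = pd.DataFrame(columns=["gene_id", "five_prime_pos", "read_length"])
    if footprints.empty:
        raise ConfigurationError("simulated library has zero total depth")
    gt.footprint_totals[dataset_label or condition] = totals
    return footprints, pd.Series(mrna_counts, name="count")


@dataclass
class Replicate:
    condition: str
    replicate: int
    footprints: pd.DataFrame
    mrna_counts: pd.Series


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    sequences: dict[str, str]
    ground_truth: GroundTruth
    abundance: pd.Series
    usage: CodonUsageTable
    replicates: dict[str, list[Replicate]]


def simulate_two_condition_study(
    cfg: SimulationConfig, usage: CodonUsageTable | None = None
) -> SimulatedStudy:
    """Full paired study: transcriptome, proteome, replicated footprint sets.

    Replicate seeds are spawned deterministically from ``cfg.seed`` via
    ``numpy.random.SeedSequence``; the library-size calibration is computed
    once from the baseline dwell model so initiation/dwell scaling between
    conditions stays visible in read totals.
    """
    master = np.random.SeedSequence(cfg.seed)
    n_datasets = len(cfg.conditions) * cfg.replicates
    children = master.spawn(2 + 1 + n_datasets)
    rng_tx = np.random.default_rng(children[0])
    rng_prot = np.random.default_rng(children[1])
    rng_expr = np.random.default_rng(children[2])

    usage = usage or default_usage_table()
    seqs, gt = simulate_transcriptome(cfg, usage=usage, rng=rng_tx)
    abundance = simulate_proteome(cfg, gt, rng=rng_prot)
    _ensure_expression(cfg, gt, rng_expr)
    calib = depth_calibration(cfg, seqs, gt)

    replicates: dict[str, list[Replicate]] = {}
    child_i = 3
    for condition in cfg.conditions:
        replicates[condition] = []
        for rep in range(cfg.replicates):
            rng = np.random.default_rng(children[child_i])
            child_i += 1
            fp, mrna = simulate_footprints(
                cfg,
                seqs,
                gt,
                condition,
                rng=rng,
                calibration=calib,
                dataset_label=f"{condition}/rep{rep}",
            )
            replicates[condition].append(Replicate(condition, rep, fp, mrna))
    return SimulatedStudy(
        config=cfg,
        sequences=seqs,
        ground_truth=gt,
        abundance=abundance,
        usage=usage,
        replicates=replicates,
    )
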