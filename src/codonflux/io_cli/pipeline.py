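"""Workflow composition: simulate/write run directories and analyze them.

A *run directory* is the on-disk exchange format between the simulator and
the analysis workflows::

    rundir/
      config.yaml            resolved simulation config
      transcriptome.fasta    CDS sequences
      usage_table.tsv        codon usage (two-column dialect)
      trna.tsv               anticodon copy numbers (derived, monotone with usage)
      abundance.tsv          gene_id, abundance
      ground_truth.json      planted parameters
      ribo/<cond>_rep<k>.tsv footprint TSVs
      rna/<cond>_rep<k>.tsv  mRNA count TSVs

``run_pipeline`` executes a named workflow against such a directory and
writes TSV outputs plus a checksum manifest into ``config.out_dir``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .. import genome_scan, ribo_quant
from ..codon_metrics import (
    TAIParams,
    compute_index_table,
    compute_tai_weights,
    read_trna_tsv,
    read_usage_tsv,
    reverse_complement,
    write_usage_tsv,
)
from ..errors import ConfigurationError
from ..synthetic_data import SimulatedStudy, SimulationConfig, simulate_two_condition_study
from .config import RunConfig
from .io import (
    read_fasta,
    read_footprints,
    write_fasta,
    write_footprints,
    write_manifest,
    write_tsv,
)

logger = logging.getLogger(__name__)

WORKFLOWS = ("indices", "density", "rcdt", "windows", "diffdensity", "groups", "full")


@dataclass
class ResultBundle:
    out_dir: Path
    manifest: Path
    files: list[Path]


def trna_params_from_usage(usage) -> TAIParams:
    """Synthetic anticodon copy numbers monotone with codon usage.

    Each sense codon's Watson-Crick anticodon gets a copy number that grows
    with the codon's within-family relative adaptiveness, so derived tAI
    weights rank synonyms like the usage table does.
    """
    w = usage.relative_adaptiveness()
    counts = {
        reverse_complement(c): max(1, int(round(10 * wc))) for c, wc in w.items()
    }
    return TAIParams(anticodon_counts=counts)


def write_study_dir(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Serialize a simulated study to a run directory (text formats only)."""
    out = Path(out_dir)
    (out / "ribo").mkdir(parents=True, exist_ok=True)
    (out / "rna").mkdir(exist_ok=True)
    write_fasta(study.sequences, out / "transcriptome.fasta")
    write_usage_tsv(study.usage, out / "usage_table.tsv")
    params = trna_params_from_usage(study.usage)
    with open(out / "trna.tsv", "w") as fh:
        fh.write("anticodon\tcount\n")
        for ac in sorted(params.anticodon_counts):
            fh.write(f"{ac}\t{params.anticodon_counts[ac]}\n")
    write_tsv(study.abundance.to_frame("abundance"), out / "abundance.tsv")
    for condition, reps in study.replicates.items():
        for rep in reps:
            write_footprints(rep.footprints, out / "ribo" / f"{condition}_rep{rep.replicate}.tsv")
            write_tsv(rep.mrna_counts.to_frame("count"), out / "rna" / f"{condition}_rep{rep.replicate}.tsv")
    study.ground_truth.to_json(out / "ground_truth.json")
    (out / "config.yaml").write_text(yaml.safe_dump(study.config.to_dict(), sort_keys=True))
    files = [p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"]
    write_manifest(out, files)
    return out


def simulate_run(config_path: str | Path | None, out_dir: str | Path, seed: int | None = None) -> Path:
    """CLI backend: simulate a two-condition study and write its run dir."""
    if config_path is None:
        cfg = SimulationConfig()
    else:
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        cfg = SimulationConfig.from_dict(raw)
    if seed is not None:
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "seed": seed})
    study = simulate_two_condition_study(cfg)
    return write_study_dir(study, out_dir)


class _RunInputs:
    """Lazy accessors over a run directory's files."""

    def __init__(self, run_dir: str | Path, cfg: RunConfig):
        self.root = Path(run_dir)
        self.cfg = cfg
        if not self.root.is_dir():
            raise ConfigurationError(f"run directory {self.root} does not exist")
        self._seqs = None

    def require(self, rel: str) -> Path:
        path = self.root / rel
        if not path.exists():
            raise ConfigurationError(f"required input {path} is missing")
        return path

    @property
    def sequences(self) -> dict[str, str]:
        if self._seqs is None:
            self._seqs = read_fasta(self.require("transcriptome.fasta"))
        return self._seqs

    @property
    def lengths_nt(self) -> dict[str, int]:
        return {g: len(s) - len(s) % 3 for g, s in self.sequences.items()}

    @property
    def lengths_aa(self) -> pd.Series:
        return pd.Series(
            {g: ribo_quant._length_aa(s) for g, s in self.sequences.items()}, name="length_aa"
        )

    def conditions(self) -> list[str]:
        ribo = self.require("ribo")
        conds = sorted({p.stem.rsplit("_rep", 1)[0] for p in ribo.glob("*_rep*.tsv")})
        if not conds:
            raise ConfigurationError(f"no footprint files under {ribo}")
        raw = yaml.safe_load((self.root / "config.yaml").read_text()) if (self.root / "config.yaml").exists() else None
        if raw and "conditions" in raw:  # keep the declared condition order
            declared = [c for c in raw["conditions"] if c in conds]
            if set(declared) == set(conds):
                return declared
        return conds

    def replicate_paths(self, condition: str) -> list[tuple[Path, Path]]:
        ribo = sorted(self.require("ribo").glob(f"{condition}_rep*.tsv"))
        pairs = []
        for r in ribo:
            rna = self.root / "rna" / r.name
            if not rna.exists():
                raise ConfigurationError(f"missing mRNA counts {rna}")
            pairs.append((r, rna))
        return pairs


def _stage_indices(inputs: _RunInputs, out: Path) -> pd.DataFrame:
    usage = read_usage_tsv(inputs.require("usage_table.tsv"))
    trna_path = inputs.root / "trna.tsv"
    weights = None
    if trna_path.exists():
        weights = compute_tai_weights(read_trna_tsv(trna_path))
    records = compute_index_table(inputs.sequences, usage, tai_weights=weights)
    df = pd.DataFrame([vars(r) for r in records]).set_index("gene_id")
    write_tsv(df, out / "indices.tsv")
    return df


def _stage_density(inputs: _RunInputs, out: Path) -> dict[str, pd.DataFrame]:
    """Per condition: per-replicate expression tables (TPM + density)."""
    cfg = inputs.cfg
    lengths = inputs.lengths_nt
    result: dict[str, pd.DataFrame] = {}
    for condition in inputs.conditions():
        per_rep = []
        for ribo_path, rna_path in inputs.replicate_paths(condition):
            fp = read_footprints(ribo_path)
            profiles, stats = ribo_quant.assign_a_sites(fp, lengths, cfg.offsets)
            logger.info("%s: %s", ribo_path.name, stats)
            rpf_counts = pd.Series({g: p.total for g, p in profiles.items()})
            rpf_tpm = ribo_quant.compute_tpm(rpf_counts, lengths)
            mrna = pd.read_csv(rna_path, sep="\t", index_col="gene_id")["count"]
            mrna_tpm = ribo_quant.compute_tpm(mrna.reindex(rpf_tpm.index, fill_value=0), lengths)
            dens = ribo_quant.compute_ribosome_density(rpf_tpm, mrna_tpm, cfg.min_mrna_tpm)
            rep_name = ribo_path.stem
            write_tsv(dens, out / f"expression_{rep_name}.tsv")
            per_rep.append(dens["ribosome_density"].rename(rep_name))
        result[condition] = pd.concat(per_rep, axis=1)
    return result


def _stage_rcdt(inputs: _RunInputs, out: Path) -> dict[str, ribo_quant.RCDTTable]:
    """Pooled-replicate RCDT per condition, plus long/short strata and deltas."""
    cfg = inputs.cfg
    lengths = inputs.lengths_nt
    seqs = inputs.sequences
    tables: dict[str, ribo_quant.RCDTTable] = {}
    strata_tables: dict[str, list[ribo_quant.RCDTTable]] = {}
    kwargs = dict(
        min_mean_reads=cfg.min_mean_reads,
        min_total_reads=cfg.min_total_reads,
        trim=cfg.trim,
    )
    for condition in inputs.conditions():
        pooled = pd.concat(
            [read_footprints(r) for r, _ in inputs.replicate_paths(condition)],
            ignore_index=True,
        )
        profiles, _ = ribo_quant.assign_a_sites(pooled, lengths, cfg.offsets)
        table = ribo_quant.compute_rcdt(profiles, seqs, condition_label=condition, **kwargs)
        tables[condition] = table
        write_tsv(table.to_frame(), out / f"rcdt_{condition}.tsv", index_label=None)
        strata = [(cfg.strata_long_aa, float("inf")), (0.0, cfg.strata_short_aa)]
        per_stratum = ribo_quant.compute_rcdt_stratified(
            profiles, seqs, strata, condition_label=condition, **kwargs
        )
        strata_tables[condition] = per_stratum
        for st in per_stratum:
            write_tsv(st.to_frame(), out / f"rcdt_{condition}_{st.stratum}.tsv", index_label=None)
    conds = list(tables)
    if len(conds) >= 2:
        delta = ribo_quant.delta_rcdt(tables[conds[1]], tables[conds[0]])
        write_tsv(
            pd.DataFrame({"codon": list(delta), "delta_rcdt": list(delta.values())}),
            out / f"delta_rcdt_{conds[1]}_minus_{conds[0]}.tsv",
            index_label=None,
        )
    for condition, per_stratum in strata_tables.items():
        if len(per_stratum) == 2:
            d = ribo_quant.delta_rcdt(per_stratum[0], per_stratum[1])
            write_tsv(
                pd.DataFrame({"codon": list(d), "delta_rcdt": list(d.values())}),
                out / f"delta_rcdt_{condition}_long_minus_short.tsv",
                index_label=None,
            )
    return tables


def _stage_differential(
    inputs: _RunInputs, out: Path, density: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    cfg = inputs.cfg
    conds = inputs.conditions()
    if len(conds) < 2:
        raise ConfigurationError("differential workflow needs two conditions")
    a, b = conds[0], conds[1]
    diff = genome_scan.differential_density(
        density[a], density[b], fc_threshold=cfg.fc_threshold, alpha=cfg.alpha
    )
    write_tsv(diff, out / "differential.tsv")
    shares = genome_scan.call_shares(diff)
    logger.info("differential %s vs %s: %s", b, a, shares)
    return diff


def _feature_table(inputs: _RunInputs, indices: pd.DataFrame) -> pd.DataFrame:
    table = indices.copy()
    abund_path = inputs.root / "abundance.tsv"
    if abund_path.exists():
        abund = pd.read_csv(abund_path, sep="\t", index_col="gene_id")["abundance"]
        table = table.join(abund, how="left")
    return table


def _stage_windows(inputs: _RunInputs, out: Path, indices: pd.DataFrame) -> None:
    cfg = inputs.cfg
    table = _feature_table(inputs, indices)
    usable = table.dropna(subset=["tai", "length_aa", "abundance"])
    if len(usable) < cfg.window:
        raise ConfigurationError(
            f"windows: only {len(usable)} genes with tai/length/abundance "
            f"(window={cfg.window})"
        )
    stats = genome_scan.scanning_window_correlation(
        usable,
        rank_by="tai",
        x="length_aa",
        y="abundance",
        window=cfg.window,
        step=cfg.step,
        y_transform="log10",
    )
    write_tsv(genome_scan.window_stats_frame(stats), out / "windows_abundance.tsv", index_label=None)


def _stage_proportions(
    inputs: _RunInputs, out: Path, diff: pd.DataFrame, indices: pd.DataFrame
) -> None:
    cfg = inputs.cfg
    table = diff.join(indices["length_aa"], how="inner")
    table["log2_fold_change"] = np.log2(table["fold_change"])
    window = min(cfg.window, max(3, len(table)))
    dec, inc = genome_scan.proportion_curves(
        table, window=window, step=cfg.step, lo=1.0 / cfg.fc_threshold, hi=cfg.fc_threshold
    )
    write_tsv(genome_scan.window_stats_frame(dec), out / "proportion_decreased.tsv", index_label=None)
    write_tsv(genome_scan.window_stats_frame(inc), out / "proportion_increased.tsv", index_label=None)
    ml = genome_scan.ranked_mean_length(table, window=window, step=cfg.step)
    write_tsv(genome_scan.window_stats_frame(ml), out / "ranked_mean_length.tsv", index_label=None)


def _stage_groups(inputs: _RunInputs, out: Path, indices: pd.DataFrame) -> None:
    cfg = inputs.cfg
    usable = indices.dropna(subset=["cbi", "length_aa"])
    n_hi = int((usable["cbi"] >= cfg.cbi_high).sum())
    n_lo = int((usable["cbi"] <= cfg.cbi_low).sum())
    size = min(cfg.group_size, n_hi, n_lo)
    if size < 1:
        raise ConfigurationError("groups: a CBI stratum is empty")
    if size < cfg.group_size:
        logger.warning("groups: shrinking group_size %d -> %d to fit strata", cfg.group_size, size)
    groups = genome_scan.group_genes_by_cbi_length(
        usable, cbi_high=cfg.cbi_high, cbi_low=cfg.cbi_low, group_size=size
    )
    gdir = out / "groups"
    gdir.mkdir(exist_ok=True)
    for name, ids in groups.items():
        (gdir / f"{name}.txt").write_text("\n".join(ids) + "\n")


def run_pipeline(config: RunConfig, workflow: str) -> ResultBundle:
    """Execute one named workflow; stages abort with stage-labelled errors."""
    if workflow not in WORKFLOWS:
        raise ConfigurationError(f"unknown workflow {workflow!r}; choose from {WORKFLOWS}")
    if config.run_dir is None:
        raise ConfigurationError("config.run_dir is required")
    inputs = _RunInputs(config.run_dir, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # fail fast on missing stage inputs before any computation
    if workflow in {"density", "rcdt", "diffdensity", "full"}:
        inputs.require("ribo")
    if workflow in {"indices", "windows", "groups", "full"}:
        inputs.require("usage_table.tsv")

    stage = workflow
    try:
        indices = None
        density = None
        diff = None
        if workflow in {"indices", "windows", "groups", "full"}:
            stage = "indices"
            indices = _stage_indices(inputs, out)
        if workflow in {"density", "diffdensity", "full"}:
            stage = "density"
            density = _stage_density(inputs, out)
        if workflow in {"rcdt", "full"}:
            stage = "rcdt"
            _stage_rcdt(inputs, out)
        if workflow in {"diffdensity", "full"}:
            stage = "diffdensity"
            diff = _stage_differential(inputs, out, density)
        if workflow in {"windows", "full"}:
            stage = "windows"
            _stage_windows(inputs, out, indices)
        if workflow == "full":
            stage = "proportions"
            _stage_proportions(inputs, out, diff, indices)
        if workflow in {"groups", "full"}:
            stage = "groups"
            _stage_groups(inputs, out, indices)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    config.to_yaml(out / "config_resolved.yaml")
    files = [p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"]
    manifest = write_manifest(out, files, extra={"workflow": workflow})
    return ResultBundle(out_dir=out, manifest=manifest, files=files)
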