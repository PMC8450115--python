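"""Genome-scale analytics over joined per-gene feature tables.

Scanning-window statistics rank genes by one field and slide a fixed-size
window over the ranking, computing a Pearson correlation, a threshold
proportion, or a mean per window. Differential ribosome-density testing
classifies genes by fold change and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

logger = logging.getLogger(__name__)


class WindowStat(NamedTuple):
    window_index: int
    window_size: int
    center_metric: float
    statistic: float
    n_effective: int


def _sorted_table(table: pd.DataFrame, rank_by: str) -> pd.DataFrame:
    """Sort ascending by ``rank_by`` with deterministic gene_id tie-breaks."""
    df = table.dropna(subset=[rank_by])
    order = np.lexsort((df.index.to_numpy(), df[rank_by].to_numpy()))
    return df.iloc[order]


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return values.astype(float)
    if transform == "log10":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log10(values.astype(float))
        out[~np.isfinite(out)] = np.nan
        return out
    if transform == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(values.astype(float))
        out[~np.isfinite(out)] = np.nan
        return out
    raise InputError(f"unknown transform {transform!r}")


def _window_starts(n: int, window: int, step: int) -> np.ndarray:
    return np.arange(0, n - window + 1, step)


def _rolling_sums(values: np.ndarray, window: int, starts: np.ndarray) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(values)])
    return cs[starts + window] - cs[starts]


def scanning_window_correlation(
    table: pd.DataFrame,
    rank_by: str,
    x: str,
    y: str,
    window: int = 500,
    step: int = 1,
    x_transform: str = "identity",
    y_transform: str = "identity",
) -> list[WindowStat]:
    """Pearson r between x and y in fixed-size windows of the rank_by ordering.

    Genes missing ``rank_by`` are dropped before ranking; within a window the
    correlation uses pairs where both (transformed) x and y are finite.
    Windows with fewer than 3 such pairs are skipped; zero-variance windows
    yield NaN statistics.
    """
    if window < 3:
        raise InputError("window must be >= 3")
    df = _sorted_table(table, rank_by)
    n = len(df)
    if n < window:
        raise InputError(f"window {window} exceeds the {n} rankable genes")
    rank_vals = df[rank_by].to_numpy(dtype=float)
    xv = _apply_transform(df[x].to_numpy(), x_transform)
    yv = _apply_transform(df[y].to_numpy(), y_transform)
    mask = np.isfinite(xv) & np.isfinite(yv)
    x0 = np.where(mask, xv, 0.0)
    y0 = np.where(mask, yv, 0.0)

    starts = _window_starts(n, window, step)
    m = _rolling_sums(mask.astype(float), window, starts)
    sx = _rolling_sums(x0, window, starts)
    sy = _rolling_sums(y0, window, starts)
    sxx = _rolling_sums(x0 * x0, window, starts)
    syy = _rolling_sums(y0 * y0, window, starts)
    sxy = _rolling_sums(x0 * y0, window, starts)
    center = _rolling_sums(rank_vals, window, starts) / window

    out: list[WindowStat] = []
    for k, s0 in enumerate(starts):
        ne = int(m[k])
        if ne < 3:
            continue
        cov = ne * sxy[k] - sx[k] * sy[k]
        varx = ne * sxx[k] - sx[k] ** 2
        vary = ne * syy[k] - sy[k] ** 2
        if varx <= 0 or vary <= 0:
            r = float("nan")
        else:
            r = float(cov / np.sqrt(varx * vary))
        out.append(WindowStat(k, window, float(center[k]), r, ne))
    return out


def subset_correlation(
    table: pd.DataFrame,
    filter_expr: str,
    x: str,
    y: str,
    x_transform: str = "identity",
    y_transform: str = "identity",
) -> tuple[float, int]:
    """Pearson r and n on the genes selected by a pandas query expression."""
    df = table.query(filter_expr) if filter_expr else table
    xv = _apply_transform(df[x].to_numpy(), x_transform)
    yv = _apply_transform(df[y].to_numpy(), y_transform)
    mask = np.isfinite(xv) & np.isfinite(yv)
    n = int(mask.sum())
    if n < 3:
        raise InputError(f"filter {filter_expr!r} left {n} usable genes (< 3)")
    r = float(np.corrcoef(xv[mask], yv[mask])[0, 1])
    return r, n


def group_genes_by_cbi_length(
    table: pd.DataFrame,
    cbi_high: float = 0.3,
    cbi_low: float = 0.15,
    group_size: int = 1000,
) -> dict[str, list[str]]:
    """Four gene groups: {long, short} x {high-CBI, low-CBI}.

    Within the high-CBI stratum (cbi >= cbi_high) and the low-CBI stratum
    (cbi <= cbi_low), select the ``group_size`` longest and shortest genes
    by length_aa, ties broken by gene_id.
    """
    df = table.dropna(subset=["cbi", "length_aa"])
    strata = {
        "high_cbi": df[df["cbi"] >= cbi_high],
        "low_cbi": df[df["cbi"] <= cbi_low],
    }
    groups: dict[str, list[str]] = {}
    for name, sub in strata.items():
        if len(sub) < group_size:
            raise InputError(
                f"stratum {name} has {len(sub)} genes; group_size {group_size} required"
            )
        if len(sub) < 2 * group_size:
            logger.warning(
                "stratum %s has %d genes (< 2*group_size); long/short groups overlap",
                name,
                len(sub),
            )
        ids = sub.index.to_numpy()
        lengths = sub["length_aa"].to_numpy(dtype=float)
        asc = np.lexsort((ids, lengths))
        desc = np.lexsort((ids, -lengths))
        groups[f"long_{name}"] = sorted(ids[desc][:group_size].tolist())
        groups[f"short_{name}"] = sorted(ids[asc][:group_size].tolist())
    return groups


def differential_density(
    a_reps: pd.DataFrame,
    b_reps: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-gene differential ribosome density between two replicate matrices.

    Returns a frame indexed by gene with mean_density_a/b, fold_change
    (b/a), p_value, fdr (Benjamini-Hochberg), and call in {up, down, ns}.
    Genes with NaN in any replicate, or zero mean in condition a, are
    excluded (logged). ``test`` is 'welch' or 'student'.
    """
    genes = a_reps.index.intersection(b_reps.index)
    if len(genes) == 0:
        raise InputError("replicate matrices share no genes")
    if a_reps.shape[1] < 2 or b_reps.shape[1] < 2:
        raise InputError("need >= 2 replicates per condition")
    a = a_reps.loc[genes].to_numpy(dtype=float)
    b = b_reps.loc[genes].to_numpy(dtype=float)
    finite = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
    mean_a = a.mean(axis=1)
    usable = finite & (mean_a != 0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("differential_density: excluded %d genes (NaN or zero baseline)", n_excluded)
    a, b = a[usable], b[usable]
    genes = genes[usable]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fc = mean_b / mean_a

    res = sps.ttest_ind(b, a, axis=1, equal_var=(test == "student"))
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> p = 1 by convention,
    # different means -> p = 0
    degenerate = ~np.isfinite(pvals)
    pvals[degenerate & np.isclose(mean_a, mean_b)] = 1.0
    pvals[degenerate & ~np.isclose(mean_a, mean_b)] = 0.0

    fdr = benjamini_hochberg(pvals)
    call = np.full(len(genes), "ns", dtype=object)
    call[(fc > fc_threshold) & (fdr < alpha)] = "up"
    call[(fc < 1.0 / fc_threshold) & (fdr < alpha)] = "down"
    return pd.DataFrame(
        {
            "mean_density_a": mean_a,
            "mean_density_b": mean_b,
            "fold_change": fc,
            "p_value": pvals,
            "fdr": fdr,
            "call": call,
        },
        index=genes,
    )


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values, monotone and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_shares(differential: pd.DataFrame) -> dict[str, float]:
    """Down/up shares among significant calls, as fractions in [0, 1]."""
    sig = differential[differential["call"] != "ns"]
    n = len(sig)
    if n == 0:
        return {"down_share": float("nan"), "up_share": float("nan"), "n_significant": 0}
    return {
        "down_share": float((sig["call"] == "down").mean()),
        "up_share": float((sig["call"] == "up").mean()),
        "n_significant": n,
    }


def proportion_curves(
    table: pd.DataFrame,
    window: int = 500,
    step: int = 1,
    rank_by: str = "length_aa",
    lo: float = 0.5,
    hi: float = 2.0,
    fold_change: str = "fold_change",
) -> tuple[list[WindowStat], list[WindowStat]]:
    """Per-window fractions of genes with fold_change < lo and > hi.

    Genes are ranked ascending by ``rank_by`` (default CDS length).
    """
    df = _sorted_table(table.dropna(subset=[fold_change]), rank_by)
    n = len(df)
    if n < window:
        raise InputError(f"window {window} exceeds the {n} usable genes")
    fc = df[fold_change].to_numpy(dtype=float)
    rank_vals = df[rank_by].to_numpy(dtype=float)
    starts = _window_starts(n, window, step)
    center = _rolling_sums(rank_vals, window, starts) / window
    down = _rolling_sums((fc < lo).astype(float), window, starts) / window
    up = _rolling_sums((fc > hi).astype(float), window, starts) / window
    decreased = [
        WindowStat(k, window, float(center[k]), float(down[k]), window)
        for k in range(len(starts))
    ]
    increased = [
        WindowStat(k, window, float(center[k]), float(up[k]), window)
        for k in range(len(starts))
    ]
    return decreased, increased


def ranked_mean_length(
    table: pd.DataFrame,
    window: int = 500,
    step: int = 1,
    rank_by: str = "log2_fold_change",
    length: str = "length_aa",
) -> list[WindowStat]:
    """Mean CDS length per window of genes ranked by (log2) fold change."""
    df = _sorted_table(table.dropna(subset=[length]), rank_by)
    n = len(df)
    if n < window:
        raise InputError(f"window {window} exceeds the {n} usable genes")
    lengths = df[length].to_numpy(dtype=float)
    rank_vals = df[rank_by].to_numpy(dtype=float)
    starts = _window_starts(n, window, step)
    center = _rolling_sums(rank_vals, window, starts) / window
    mean_len = _rolling_sums(lengths, window, starts) / window
    return [
        WindowStat(k, window, float(center[k]), float(mean_len[k]), window)
        for k in range(len(starts))
    ]


def window_stats_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(stats, columns=WindowStat._fields)
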