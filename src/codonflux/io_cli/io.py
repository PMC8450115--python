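"""Readers and writers for FASTA, footprint SAM/TSV, and result tables."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ..errors import InputError

logger = logging.getLogger(__name__)

FOOTPRINT_COLUMNS = ["gene_id", "five_prime_pos", "read_length"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> {id: uppercase sequence}.

    The record id is the first whitespace-delimited header token; duplicate
    ids are an error. An empty file yields an empty dict with a warning.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InputError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        logger.warning("read_fasta: no records in %s", path)
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_footprints(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Footprints from SAM or the three-column TSV fallback.

    The dialect is sniffed from the extension when not given. SAM reading
    keeps only mapped primary alignments; positions are 0-based offsets on
    the reference (gene/CDS) sequence.
    """
    path = Path(path)
    if dialect is None:
        dialect = "sam" if path.suffix.lower() in {".sam", ".bam"} else "tsv"
    if dialect == "tsv":
        return _read_footprint_tsv(path)
    if dialect == "sam":
        return _read_footprint_sam(path)
    raise InputError(f"unknown footprint dialect {dialect!r}")


def _read_footprint_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # propagate with file context
        raise InputError(f"cannot parse footprint TSV {path}: {exc}") from exc
    missing = set(FOOTPRINT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing footprint columns {sorted(missing)}")
    df = df[FOOTPRINT_COLUMNS]
    for col in ("five_prime_pos", "read_length"):
        if not pd.api.types.is_integer_dtype(df[col]):
            try:
                df[col] = df[col].astype(int)
            except (TypeError, ValueError) as exc:
                raise InputError(f"{path}: non-integer values in {col}") from exc
    return df


def _read_footprint_sam(path: Path) -> pd.DataFrame:
    import pysam

    genes, positions, lengths = [], [], []
    n_skipped = 0
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                n_skipped += 1
                continue
            genes.append(aln.reference_name)
            positions.append(aln.reference_start)
            lengths.append(aln.query_length or aln.infer_read_length() or 0)
    if n_skipped:
        logger.info("%s: skipped %d unmapped/secondary/supplementary records", path, n_skipped)
    return pd.DataFrame(
        {"gene_id": genes, "five_prime_pos": positions, "read_length": lengths}
    )


def write_footprints(df: pd.DataFrame, path: str | Path) -> None:
    df[FOOTPRINT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = "gene_id") -> None:
    """TSV with NA for missing values and a newline-terminated final line."""
    df.to_csv(path, sep="\t", na_rep="NA", index=index_label is not None, index_label=index_label)


def sha256sum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, files: list[Path], extra: dict | None = None) -> Path:
    """Manifest of produced tables with checksums, for reproducibility checks."""
    from .. import __version__

    out_dir = Path(out_dir)
    entries = {
        str(f.relative_to(out_dir)): sha256sum(f) for f in sorted(files)
    }
    payload = {"tool": "codonflux", "version": __version__, "files": entries}
    if extra:
        payload.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path
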