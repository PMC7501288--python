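"""Strict tab-separated table and FASTA readers/writers.

Every file the pipeline touches is plain text: TSV with a header row
(UTF-8, "." decimal, optional leading ``#`` comment lines carrying
provenance metadata) or FASTA.  Readers validate the schema up front and
fail with the offending column or line rather than propagating NaNs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__

# Column name -> pandas dtype for every table schema in the pipeline.
SCHEMAS: dict[str, dict[str, str]] = {
    "orf_catalog": {
        "orf_id": "string",
        "mag_id": "string",
        "orfg_id_mt": "string",
        "orfg_id_mp": "string",
        "length_nt": "int64",
        "mw_g_per_mol": "float64",
        "ko_terms": "string",
    },
    "mt_reads": {
        "orfg_id": "string",
        "sample_id": "string",
        "reads": "float64",  # float: expectation-mode simulation yields fractional reads
        "unique_hits": "float64",
    },
    "spikein": {
        "sample_id": "string",
        "i_m": "float64",
        "i_nt": "float64",
        "i_r": "float64",
    },
    "mp_lfq": {
        "orfg_id": "string",
        "sample_id": "string",
        "lfq": "float64",
        "unique_peptides": "int64",
    },
    "peaks": {
        "sample_id": "string",
        "peak_id": "string",
        "base_peak_intensity": "float64",
        "mass_da": "float64",
        "identified": "int64",
    },
    "bradford": {
        "sample_id": "string",
        "conc_g_per_l": "float64",
        "volume_l": "float64",
    },
    "samples": {
        "sample_id": "string",
        "time_h": "float64",
        "replicate": "string",
    },
    "mt_absolute": {
        "orfg_id": "string",
        "sample_id": "string",
        "rpkm": "float64",
        "molecules_sample": "float64",
        "unique_hits": "float64",
    },
    "mt_sample_summary": {
        "sample_id": "string",
        "total_reads": "float64",
        "spike_reads": "float64",
        "transcriptome_nt": "float64",
        "total_molecules": "float64",
    },
    "mp_absolute": {
        "orfg_id": "string",
        "sample_id": "string",
        "copy_number": "float64",
        "unique_peptides": "int64",
    },
    "mp_sample_summary": {
        "sample_id": "string",
        "total_mass_g": "float64",
        "detected_mass_g": "float64",
        "total_copies": "float64",
    },
    "paired_expression": {
        "orf_id": "string",
        "mag_id": "string",
        "time_h": "float64",
        "rna_molecules": "float64",
        "protein_molecules": "float64",
    },
    "filter_report": {
        "stage": "string",
        "rows_in": "int64",
        "rows_out": "int64",
    },
    "truth_expression": {
        "orf_id": "string",
        "sample_id": "string",
        "molecules": "float64",
    },
    "truth_params": {
        "mag_id": "string",
        "time_h": "float64",
        "true_k": "float64",
        "true_a_log10": "float64",
    },
    "truth_transcriptome": {
        "sample_id": "string",
        "transcriptome_nt": "float64",
    },
}


class SchemaError(ValueError):
    """A table file does not match its declared schema."""


def _meta_header(meta: Mapping[str, object] | None) -> str:
    fields = {"tool": f"omicounts {__version__}"}
    if meta:
        fields.update({k: str(v) for k, v in meta.items()})
    return "# " + " ".join(f"{k}={v}" for k, v in fields.items()) + "\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    schema: str | None = None,
    meta: Mapping[str, object] | None = None,
) -> Path:
    """Write *df* as TSV with a provenance comment header.

    Floats are written with 17 significant digits so a read round-trip is
    loss-free.  If *schema* is given, the column set is validated first.
    """
    path = Path(path)
    if schema is not None:
        _check_columns(df.columns, SCHEMAS[schema], str(path))
        df = df[list(SCHEMAS[schema])]
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def _check_columns(found: Iterable[str], schema: Mapping[str, str], where: str) -> None:
    found = list(found)
    missing = [c for c in schema if c not in found]
    extra = [c for c in found if c not in schema]
    if missing:
        raise SchemaError(f"{where}: missing required column(s) {missing}")
    if extra:
        raise SchemaError(f"{where}: unexpected column(s) {extra}")


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, enforcing *schema*.

    Comment lines starting with ``#`` are skipped.  A cell that cannot be
    parsed to its declared type raises :class:`SchemaError` naming the
    column and (1-based, data) row.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"table not found: {path}")
    spec = SCHEMAS[schema]
    raw = pd.read_csv(path, sep="\t", comment="#", dtype="string")
    _check_columns(raw.columns, spec, str(path))
    out = pd.DataFrame(index=raw.index)
    for col, dtype in spec.items():
        if dtype == "string":
            # empty fields are empty strings, not missing values
            out[col] = raw[col].astype("string").fillna("")
            continue
        try:
            out[col] = pd.to_numeric(raw[col], errors="raise").astype(dtype)
        except (ValueError, TypeError):
            numeric = pd.to_numeric(raw[col], errors="coerce")
            bad = numeric.isna() & raw[col].notna()
            row = int(bad.idxmax()) + 1 if bad.any() else "?"
            raise SchemaError(
                f"{path}: column '{col}' has an unparseable value at data row {row}"
            ) from None
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ``{id: sequence}`` dict.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased.  Duplicate ids and empty records are errors.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise SchemaError(f"{path}: duplicate sequence id '{rec.id}'")
        seq = str(rec.seq).upper()
        if not seq:
            raise SchemaError(f"{path}: empty sequence for id '{rec.id}'")
        seqs[rec.id] = seq
    if not seqs:
        raise SchemaError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(obj: object) -> str:
    """Stable hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
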