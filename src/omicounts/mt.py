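"""Absolute metatranscriptomics via an RNA spike-in internal standard.

A known quantity of an in vitro transcript (I_M molecules, I_Nt
nucleotides long) is added to the RNA extraction, so the reads it draws
(I_R) calibrate reads per nucleotide of starting material.  The total
transcriptome size in nucleotides is then::

    sum(T_Nt) = I_M * I_Nt * sum(T_R) / I_R

with sum(T_R) the transcriptome-mapped reads (spike-in and rRNA
excluded), and per-gene molecule counts follow from RPKM::

    T_M = T_RPKM / 1e9 * sum(T_Nt)

Counts refer to the measured aliquot and are scaled to the whole sample
by the aliquot factor (10 for a 6 ml aliquot of a 60 ml sample).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def estimate_transcriptome_size(
    i_m: float, i_nt: float, i_r: float, total_transcript_reads: float
) -> float:
    """Total transcriptome size in nucleotides from the spike-in.

    ``I_M * I_Nt * sum(T_R) / I_R``; requires at least one spike-in read.
    """
    if i_m <= 0 or i_nt <= 0:
        raise ValueError("spike-in molecules and length must be > 0")
    if i_r <= 0:
        raise ValueError("no spike-in reads detected (I_R = 0): cannot calibrate")
    if total_transcript_reads < 0:
        raise ValueError("total transcript reads must be >= 0")
    return i_m * i_nt * total_transcript_reads / i_r


def compute_rpkm(
    reads: pd.Series | np.ndarray,
    lengths_nt: pd.Series | np.ndarray,
    total_transcript_reads: float,
) -> pd.Series:
    """Reads per kilobase per million transcriptome-mapped reads.

    ``RPKM_i = reads_i * 1e9 / (length_i * total)``; the denominator is
    transcriptome-mapped reads only (spike-in excluded upstream).
    """
    reads = pd.Series(reads, dtype=float)
    lengths = pd.Series(lengths_nt, dtype=float).reindex(reads.index)
    if total_transcript_reads <= 0:
        raise ValueError("total transcript reads must be > 0 for RPKM")
    if (reads < 0).any():
        raise ValueError("negative read count")
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every feature needs a positive length")
    return reads * 1e9 / (lengths * total_transcript_reads)


def molecules_per_orfg(rpkm: pd.Series, transcriptome_nt: float) -> pd.Series:
    """Absolute transcript molecules at aliquot scale: RPKM/1e9 * sum(T_Nt)."""
    rpkm = pd.Series(rpkm, dtype=float)
    if transcriptome_nt < 0:
        raise ValueError("transcriptome size must be >= 0 nt")
    if (rpkm < 0).any():
        raise ValueError("negative RPKM")
    return rpkm / 1e9 * transcriptome_nt


def scale_to_sample(molecules_aliquot: pd.Series | float, aliquot_factor: float):
    """Rescale aliquot counts to the whole sample (factor >= 1)."""
    if aliquot_factor < 1:
        raise ValueError(f"aliquot factor must be >= 1, got {aliquot_factor}")
    return molecules_aliquot * aliquot_factor


def orfg_lengths(catalog: pd.DataFrame) -> pd.Series:
    """Per-ORFG length: mean of member ORF lengths (members share length)."""
    return catalog.groupby("orfg_id_mt")["length_nt"].mean()


def quantify_mt(
    reads: pd.DataFrame,
    spikein: pd.DataFrame,
    catalog: pd.DataFrame,
    aliquot_factor: float = 10.0,
    rpkm_column: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spike-in calibrated absolute transcript counts per ORFG and sample.

    Parameters
    ----------
    reads : long table with orfg_id, sample_id, reads, unique_hits (and
        optionally a precomputed abundance column named by *rpkm_column*,
        for externally estimated abundances).
    spikein : per-sample i_m, i_nt, i_r.
    catalog : ORF catalog with orfg_id_mt and length_nt columns.
    aliquot_factor : sample volume over aliquot volume.

    Returns
    -------
    (mt_absolute, mt_sample_summary) tables; molecule counts are per
    whole sample.
    """
    lengths = orfg_lengths(catalog)
    spike = spikein.set_index("sample_id")
    out_rows, summary_rows = [], []
    for sample, grp in reads.groupby("sample_id", sort=True):
        if sample not in spike.index:
            raise ValueError(f"no spike-in record for sample {sample}")
        grp = grp.set_index("orfg_id")
        total_reads = float(grp["reads"].sum())
        nt = estimate_transcriptome_size(
            float(spike.loc[sample, "i_m"]),
            float(spike.loc[sample, "i_nt"]),
            float(spike.loc[sample, "i_r"]),
            total_reads,
        )
        if rpkm_column is not None:
            rpkm = grp[rpkm_column].astype(float)
        else:
            glen = lengths.reindex(grp.index)
            if glen.isna().any():
                missing = list(grp.index[glen.isna()])[:5]
                raise ValueError(f"ORFGs absent from catalog: {missing}")
            rpkm = compute_rpkm(grp["reads"], glen, total_reads)
        mol = scale_to_sample(molecules_per_orfg(rpkm, nt), aliquot_factor)
        for gid in grp.index:
            out_rows.append(
                {"orfg_id": gid, "sample_id": sample, "rpkm": float(rpkm[gid]),
                 "molecules_sample": float(mol[gid]),
                 "unique_hits": float(grp.loc[gid, "unique_hits"])}
            )
        summary_rows.append(
            {"sample_id": sample, "total_reads": total_reads,
             "spike_reads": float(spike.loc[sample, "i_r"]),
             "transcriptome_nt": nt, "total_molecules": float(mol.sum())}
        )
    return pd.DataFrame(out_rows), pd.DataFrame(summary_rows)
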