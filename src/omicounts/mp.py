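"""Absolute metaproteomics via the total protein approach (TPA).

Label-free quantification (LFQ) intensities are relative: within a
sample, LFQ_i is proportional to the mass of protein i injected.  The
TPA anchors them to absolute copy numbers with two sample-level
measurements: the total protein mass (Bradford assay x sample volume)
and the *detected* protein mass — the share of that total explained by
MS peaks that were actually identified, estimated from the raw peak
list as an intensity-times-mass ratio.  The chain is::

    total_protein_i = LFQ_i / sum(LFQ)                      [mass fraction]
    molar_fraction_i = total_protein_i / MW_i               [mol/g]
    copy_number_i = molar_fraction_i * detected_mass * N_A  [molecules]

Per-cell normalisation is deliberately omitted: in a heterogeneous
community there is no single cell count to divide by.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23  # 1/mol

WATER_G_PER_MOL = 18.01528

# Average (not monoisotopic) residue masses, g/mol: monomer minus one water.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

# Ambiguity policy: mean of candidate residues; X is a generic residue.
_AMBIGUOUS_MASS = {
    "B": (AVERAGE_RESIDUE_MASS["N"] + AVERAGE_RESIDUE_MASS["D"]) / 2.0,
    "Z": (AVERAGE_RESIDUE_MASS["Q"] + AVERAGE_RESIDUE_MASS["E"]) / 2.0,
    "X": 110.0,
}


def compute_mw(aa_sequence: str, ambiguous: str = "average") -> float:
    """Average molecular weight of a protein, g/mol.

    Sum of average residue masses plus one water.  Ambiguous residues
    (B, Z, X) use the mean of their candidate masses when
    ``ambiguous='average'``; ``ambiguous='strict'`` rejects them.
    """
    if not aa_sequence:
        raise ValueError("empty amino-acid sequence")
    if ambiguous not in ("average", "strict"):
        raise ValueError(f"unknown ambiguity policy '{ambiguous}'")
    total = WATER_G_PER_MOL
    for pos, aa in enumerate(aa_sequence.upper()):
        mass = AVERAGE_RESIDUE_MASS.get(aa)
        if mass is None and ambiguous == "average":
            mass = _AMBIGUOUS_MASS.get(aa)
        if mass is None:
            raise ValueError(
                f"unknown amino-acid character '{aa}' at position {pos + 1}"
            )
        total += mass
    return total


def bradford_total_mass(conc_g_per_l: float, volume_l: float) -> float:
    """Total protein mass in the sample, grams (Bradford conc x volume)."""
    if volume_l <= 0:
        raise ValueError(f"volume must be > 0 l, got {volume_l}")
    if conc_g_per_l < 0:
        raise ValueError(f"concentration must be >= 0 g/l, got {conc_g_per_l}")
    return conc_g_per_l * volume_l


def total_protein_fractions(lfq: pd.Series | np.ndarray) -> pd.Series:
    """LFQ intensities -> per-protein mass fractions (sum to 1).

    Undetected entries (LFQ 0) get fraction 0; an all-zero sample is an
    error because nothing can be normalised.
    """
    lfq = pd.Series(lfq, dtype=float) if not isinstance(lfq, pd.Series) else lfq.astype(float)
    if (lfq < 0).any():
        raise ValueError("negative LFQ intensity")
    total = lfq.sum()
    if total <= 0:
        raise ValueError("all LFQ intensities are zero in this sample")
    return lfq / total


def molar_fractions(fractions: pd.Series, mw_g_per_mol: pd.Series) -> pd.Series:
    """Mass fractions -> molar fractions, mol per gram of protein."""
    fractions = pd.Series(fractions, dtype=float)
    mw = pd.Series(mw_g_per_mol, dtype=float).reindex(fractions.index)
    bad = mw.isna() | (mw <= 0)
    if bad.any():
        raise ValueError(
            f"non-positive or missing molecular weight for: {list(fractions.index[bad])[:5]}"
        )
    return fractions / mw


def detected_protein_mass(total_mass_g: float, peaks: pd.DataFrame) -> float:
    """Detected protein mass, grams.

    ``total_mass x sum(BPI_i x Mass_i over identified peaks) /
    sum(BPI_j x Mass_j over all peaks)``: the fraction of injected mass
    the identified MS peaks account for.
    """
    if total_mass_g < 0:
        raise ValueError("total mass must be >= 0")
    if peaks.empty:
        raise ValueError("empty peak table")
    weight = peaks["base_peak_intensity"].to_numpy(float) * peaks["mass_da"].to_numpy(float)
    denom = weight.sum()
    if denom <= 0:
        raise ValueError("peak intensity-mass sum is zero")
    ident = peaks["identified"].to_numpy().astype(bool)
    return total_mass_g * float(weight[ident].sum() / denom)


def copy_numbers(molar_fraction: pd.Series, detected_mass_g: float) -> pd.Series:
    """Molar fractions (mol/g) x detected mass (g) x N_A -> molecules."""
    molar_fraction = pd.Series(molar_fraction, dtype=float)
    if detected_mass_g < 0:
        raise ValueError("detected mass must be >= 0")
    if (molar_fraction < 0).any():
        raise ValueError("negative molar fraction")
    return molar_fraction * detected_mass_g * AVOGADRO


def orfg_molecular_weights(catalog: pd.DataFrame) -> pd.Series:
    """Per-ORFG MW: mean of member ORF MWs (members are near-identical)."""
    return catalog.groupby("orfg_id_mp")["mw_g_per_mol"].mean()


def quantify_mp(
    lfq: pd.DataFrame,
    peaks: pd.DataFrame,
    bradford: pd.DataFrame,
    catalog: pd.DataFrame,
    aliquot_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full TPA per sample over a long-format LFQ table.

    Parameters
    ----------
    lfq : columns orfg_id, sample_id, lfq, unique_peptides.
    peaks : columns sample_id, peak_id, base_peak_intensity, mass_da, identified.
    bradford : columns sample_id, conc_g_per_l, volume_l.
    catalog : ORF catalog with orfg_id_mp and mw_g_per_mol columns.
    aliquot_scale : factor reconciling the Bradford aliquot to the whole
        sample (1 when the concentration already refers to the full
        sample volume).

    Returns
    -------
    (mp_absolute, mp_sample_summary) tables.
    """
    if aliquot_scale <= 0:
        raise ValueError("aliquot_scale must be > 0")
    mw = orfg_molecular_weights(catalog)
    brad = bradford.set_index("sample_id")
    out_rows, summary_rows = [], []
    for sample, grp in lfq.groupby("sample_id", sort=True):
        if sample not in brad.index:
            raise ValueError(f"no Bradford measurement for sample {sample}")
        total_mass = aliquot_scale * bradford_total_mass(
            float(brad.loc[sample, "conc_g_per_l"]), float(brad.loc[sample, "volume_l"])
        )
        sample_peaks = peaks[peaks["sample_id"] == sample]
        detected_mass = detected_protein_mass(total_mass, sample_peaks)

        grp = grp.set_index("orfg_id")
        detected = grp["lfq"] > 0
        fractions = pd.Series(0.0, index=grp.index)
        fractions[detected] = total_protein_fractions(grp.loc[detected, "lfq"])
        copies = pd.Series(0.0, index=grp.index)
        if detected.any():
            molar = molar_fractions(fractions[detected], mw)
            copies[detected] = copy_numbers(molar, detected_mass)
        for gid in grp.index:
            out_rows.append(
                {"orfg_id": gid, "sample_id": sample,
                 "copy_number": float(copies[gid]),
                 "unique_peptides": int(grp.loc[gid, "unique_peptides"])}
            )
        summary_rows.append(
            {"sample_id": sample, "total_mass_g": total_mass,
             "detected_mass_g": detected_mass, "total_copies": float(copies.sum())}
        )
    return pd.DataFrame(out_rows), pd.DataFrame(summary_rows)
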