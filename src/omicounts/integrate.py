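"""Harmonise the absolute MT and MP layers into paired per-ORF series.

Filtering pipeline (in order): drop entries without unique hits, log10
transform with pseudocount 1, apply layer-specific minimum expression
thresholds (log10 >= 5 for MT, >= 8 for MP, boundary inclusive), screen
outlier samples by PCA, restrict to ORF-groups that are singletons in
both layers, and average replicates per time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

MT_LOG10_THRESHOLD = 5.0
MP_LOG10_THRESHOLD = 8.0


@dataclass
class FilterConfig:
    """Knobs of the integration filter pipeline."""

    pseudocount: float = 1.0
    mt_log10_threshold: float = MT_LOG10_THRESHOLD
    mp_log10_threshold: float = MP_LOG10_THRESHOLD
    min_unique_hits: float = 1.0
    manual_outliers: tuple[str, ...] = ()
    pc_sd_cutoff: float = 3.0
    use_pca_screen: bool = False  # manual list is the default policy
    average_log: bool = False

    def __post_init__(self) -> None:
        for name in ("pseudocount", "mt_log10_threshold", "mp_log10_threshold",
                     "min_unique_hits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pc_sd_cutoff <= 0:
            raise ValueError("pc_sd_cutoff must be > 0")


def collapse_identical_orfs(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
) -> dict[str, str]:
    """Group ORFs with byte-identical sequences into ORF-groups.

    Returns ``{orf_id: orfg_id}`` where the group id is the
    lexicographically smallest member id — deterministic and invariant
    to input order.  Duplicate ORF ids are an error.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    seen: set[str] = set()
    groups: dict[str, list[str]] = {}
    for orf_id, seq in items:
        if orf_id in seen:
            raise ValueError(f"duplicate orf_id '{orf_id}'")
        seen.add(orf_id)
        groups.setdefault(seq, []).append(orf_id)
    mapping: dict[str, str] = {}
    for members in groups.values():
        gid = min(members)
        for m in members:
            mapping[m] = gid
    return mapping


def filter_unique_hits(
    table: pd.DataFrame, min_unique_hits: float = 1.0, column: str | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose unique-hit support is below the minimum.

    The unique-hit column is auto-detected (``unique_hits`` or
    ``unique_peptides``) unless named.  Returns the filtered table and
    the number of rows removed.
    """
    if column is None:
        for cand in ("unique_hits", "unique_peptides"):
            if cand in table.columns:
                column = cand
                break
    if column is None or column not in table.columns:
        raise ValueError("no unique-hit column found in table")
    keep = table[column] >= min_unique_hits
    return table[keep].copy(), int((~keep).sum())


def log_transform(values, pseudocount: float = 1.0):
    """log10(value + pseudocount); rejects negative inputs."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = np.log10(arr + pseudocount)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out


def threshold_filter(
    log_values: pd.Series,
    layer: str,
    mt_threshold: float = MT_LOG10_THRESHOLD,
    mp_threshold: float = MP_LOG10_THRESHOLD,
) -> pd.Series:
    """Boolean mask keeping entries at or above the layer's minimum
    expression threshold (inclusive)."""
    layer = layer.upper()
    if layer == "MT":
        threshold = mt_threshold
    elif layer == "MP":
        threshold = mp_threshold
    else:
        raise ValueError(f"unknown layer '{layer}' (expected 'MT' or 'MP')")
    return pd.Series(log_values, dtype=float) >= threshold


def screen_outlier_samples(
    matrix: pd.DataFrame,
    pc_sd_cutoff: float = 3.0,
    manual: Sequence[str] = (),
) -> list[str]:
    """Flag outlier samples by distance in the first two principal components.

    *matrix* is samples x features (log-scale profiles).  Features are
    standardised, PCA projects to two components, and a sample is
    flagged when its Euclidean distance from the robust centre (median,
    MAD-scaled per component) exceeds ``pc_sd_cutoff``.  Samples in
    *manual* are always flagged.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples to screen for outliers")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(2, min(z.shape) - 1) or 1
    scores = PCA(n_components=n_comp, random_state=0).fit_transform(z)
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * 1.4826
    mad[mad == 0] = 1.0
    dist = np.sqrt((((scores - med) / mad) ** 2).sum(axis=1))
    flagged = set(matrix.index[dist > pc_sd_cutoff])
    flagged.update(manual)  # manual overrides always honoured
    return sorted(flagged)


def _singleton_orfgs(catalog: pd.DataFrame, column: str) -> pd.Series:
    """Map singleton orfg_id -> its single member orf_id."""
    sizes = catalog.groupby(column)["orf_id"].agg(["size", "first"])
    single = sizes[sizes["size"] == 1]["first"]
    single.index.name = column
    return single


def match_singletons(
    mt_table: pd.DataFrame,
    mp_table: pd.DataFrame,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
    average_log: bool = False,
) -> pd.DataFrame:
    """Pair absolute RNA and protein levels for dual-layer singleton ORFs.

    Inner join restricted to ORFs whose group is a singleton in both
    the MT and MP layer, then replicate-averaged per time point
    (linear scale by default).  Returns the paired_expression table
    (orf_id, mag_id, time_h, rna_molecules, protein_molecules).
    """
    mt_single = _singleton_orfgs(catalog, "orfg_id_mt")
    mp_single = _singleton_orfgs(catalog, "orfg_id_mp")

    mt = mt_table[mt_table["orfg_id"].isin(mt_single.index)].copy()
    mt["orf_id"] = mt["orfg_id"].map(mt_single)
    mp = mp_table[mp_table["orfg_id"].isin(mp_single.index)].copy()
    mp["orf_id"] = mp["orfg_id"].map(mp_single)

    merged = pd.merge(
        mt[["orf_id", "sample_id", "molecules_sample"]],
        mp[["orf_id", "sample_id", "copy_number"]],
        on=["orf_id", "sample_id"],
        how="inner",
    )
    if merged.empty:
        warnings.warn("no ORFs shared between the MT and MP singleton sets")
        return pd.DataFrame(
            columns=["orf_id", "mag_id", "time_h", "rna_molecules", "protein_molecules"]
        )
    merged = merged.merge(samples[["sample_id", "time_h"]], on="sample_id")

    def _mean(s: pd.Series) -> float:
        if average_log:
            return float(10.0 ** np.log10(s).mean())
        return float(s.mean())

    paired = (
        merged.groupby(["orf_id", "time_h"])
        .agg(
            rna_molecules=("molecules_sample", _mean),
            protein_molecules=("copy_number", _mean),
        )
        .reset_index()
    )
    mags = catalog.set_index("orf_id")["mag_id"]
    paired["mag_id"] = paired["orf_id"].map(mags)
    return paired[["orf_id", "mag_id", "time_h", "rna_molecules", "protein_molecules"]]


def integrate_layers(
    mt_absolute: pd.DataFrame,
    mp_absolute: pd.DataFrame,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Full integration pipeline: filters, screening, singleton pairing.

    Returns ``(paired_expression, filter_report, dropped_samples)``.
    The report logs rows in/out at every stage.
    """
    cfg = config or FilterConfig()
    report: list[dict] = []

    def stage(name: str, n_in: int, n_out: int) -> None:
        report.append({"stage": name, "rows_in": int(n_in), "rows_out": int(n_out)})

    mt, removed = filter_unique_hits(mt_absolute, cfg.min_unique_hits)
    stage("mt_unique_hits", len(mt_absolute), len(mt))
    mp, removed = filter_unique_hits(mp_absolute, cfg.min_unique_hits)
    stage("mp_unique_hits", len(mp_absolute), len(mp))

    mt_log = log_transform(mt["molecules_sample"], cfg.pseudocount)
    keep = threshold_filter(mt_log, "MT", cfg.mt_log10_threshold, cfg.mp_log10_threshold)
    mt2 = mt[keep.to_numpy()]
    stage("mt_threshold", len(mt), len(mt2))
    mp_log = log_transform(mp["copy_number"], cfg.pseudocount)
    keep = threshold_filter(mp_log, "MP", cfg.mt_log10_threshold, cfg.mp_log10_threshold)
    mp2 = mp[keep.to_numpy()]
    stage("mp_threshold", len(mp), len(mp2))

    dropped = set(cfg.manual_outliers)
    if cfg.use_pca_screen:
        for tbl, value_col in ((mt2, "molecules_sample"), (mp2, "copy_number")):
            mat = (
                tbl.assign(logv=log_transform(tbl[value_col], cfg.pseudocount))
                .pivot_table(index="sample_id", columns="orfg_id", values="logv",
                             fill_value=0.0)
            )
            if mat.shape[0] >= 3:
                dropped.update(
                    screen_outlier_samples(mat, cfg.pc_sd_cutoff, cfg.manual_outliers)
                )
    n_samples = samples["sample_id"].nunique()
    dropped = sorted(dropped)
    mt3 = mt2[~mt2["sample_id"].isin(dropped)]
    mp3 = mp2[~mp2["sample_id"].isin(dropped)]
    stage("outlier_samples", n_samples, n_samples - len(dropped))

    paired = match_singletons(mt3, mp3, catalog, samples, cfg.average_log)
    stage("singleton_match", len(mt3) + len(mp3), len(paired))
    return paired, pd.DataFrame(report), dropped
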