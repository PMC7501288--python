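"""Protein/RNA dynamics: ratios, correlations, monomial fits, rank preservation.

The headline statistics of the integrated dataset:

* per-population (MAG) protein-to-RNA ratio distributions at a time point;
* gene-wise Pearson correlation of RNA and protein across time;
* the monomial relationship ``protein = a * RNA**k`` fitted per MAG and
  time point as ``log10(protein) = a_log10 + k * log10(RNA)``, with the
  linearity k tracked over time by a cubic polynomial;
* tie-corrected Kendall tau-b rank agreement of functional-category
  abundances between omic layers;
* marker-gene pathway profiles (summed transcripts with cubic smoothing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MonomialFit:
    """OLS fit of log10(protein) on log10(RNA) at one MAG x time."""

    mag_id: str
    time_h: float
    a_log10: float  # intercept; the scale constant is a = 10**a_log10
    k: float        # slope; linearity of the protein response to RNA
    n_points: int
    r_squared: float
    residual_sd: float

    @property
    def a(self) -> float:
        return 10.0 ** self.a_log10


@dataclass
class KTrajectory:
    """Cubic least-squares trend of the linearity k over time."""

    mag_id: str
    coefficients: tuple[float, float, float, float]  # c0 + c1 t + c2 t^2 + c3 t^3
    residuals: np.ndarray
    time_range: tuple[float, float]

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        lo, hi = self.time_range
        if (t < lo).any() or (t > hi).any():
            raise ValueError(
                f"refusing to extrapolate outside the fitted range [{lo}, {hi}] h"
            )
        c0, c1, c2, c3 = self.coefficients
        return c0 + c1 * t + c2 * t**2 + c3 * t**3


@dataclass
class RankAgreement:
    """Kendall tau-b between two layers' category rankings."""

    layer_pair: tuple[str, str]
    kendall_tau: float
    p_value: float
    n_categories: int


def protein_rna_ratios(
    paired: pd.DataFrame,
    time_h: float,
    domains: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-MAG protein-to-RNA ratio summary at one time point.

    Ratios are protein_molecules / rna_molecules per ORF on
    replicate-mean counts.  Returns one row per MAG (median, quartiles,
    n_genes) plus, when *domains* maps MAG ids to 'bacterial'/'archaeal',
    a pooled ``all_bacteria`` row.
    """
    sub = paired[paired["time_h"] == time_h]
    if sub.empty:
        raise ValueError(f"no paired observations at time {time_h} h")
    if (sub["rna_molecules"] <= 0).any():
        raise ValueError("non-positive RNA counts present; filter upstream")
    ratios = sub["protein_molecules"] / sub["rna_molecules"]
    sub = sub.assign(ratio=ratios)

    def summarise(grp: pd.DataFrame, label: str) -> dict:
        r = grp["ratio"]
        return {
            "mag_id": label, "time_h": time_h,
            "median": float(r.median()),
            "q25": float(r.quantile(0.25)), "q75": float(r.quantile(0.75)),
            "min": float(r.min()), "max": float(r.max()),
            "n_genes": int(len(r)),
        }

    rows = [summarise(grp, mag) for mag, grp in sub.groupby("mag_id", sort=True)]
    if domains is not None:
        bact = sub[sub["mag_id"].map(domains).eq("bacterial")]
        if not bact.empty:
            rows.append(summarise(bact, "all_bacteria"))
    return pd.DataFrame(rows)


def genewise_pcc(
    paired: pd.DataFrame, min_timepoints: int = 3, log_scale: bool = True
) -> tuple[pd.DataFrame, float]:
    """Per-gene Pearson correlation of RNA and protein across time.

    Computed on log10 replicate means by default.  Genes with fewer
    than *min_timepoints* shared time points are skipped and counted;
    zero-variance series give a missing (NaN) coefficient, never +/-1.
    Returns (records, median PCC over defined values).
    """
    records = []
    for orf, grp in paired.groupby("orf_id", sort=True):
        n = len(grp)
        if n < min_timepoints:
            records.append({"orf_id": orf, "pcc": np.nan, "n_timepoints": n,
                            "skipped": True})
            continue
        x = grp["rna_molecules"].to_numpy(float)
        y = grp["protein_molecules"].to_numpy(float)
        if log_scale:
            x, y = np.log10(x), np.log10(y)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pcc = np.nan
        else:
            pcc = float(stats.pearsonr(x, y).statistic)
        records.append({"orf_id": orf, "pcc": pcc, "n_timepoints": n,
                        "skipped": False})
    df = pd.DataFrame(records)
    median = float(df.loc[~df["skipped"], "pcc"].median())
    return df, median


def fit_monomial(
    rna_molecules, protein_molecules, mag_id: str = "", time_h: float = np.nan
) -> MonomialFit:
    """Fit ``protein = a * RNA**k`` by OLS on the log10 scale.

    Needs >= 3 strictly positive pairs with RNA variance > 0.
    """
    x = np.log10(np.asarray(rna_molecules, dtype=float))
    y = np.log10(np.asarray(protein_molecules, dtype=float))
    if x.size != y.size:
        raise ValueError("RNA and protein vectors differ in length")
    if x.size < 3:
        raise ValueError(f"need >= 3 points to fit, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-positive or non-finite expression values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in RNA levels; slope undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    dof = max(x.size - 2, 1)
    return MonomialFit(
        mag_id=mag_id,
        time_h=float(time_h),
        a_log10=float(res.intercept),
        k=float(res.slope),
        n_points=int(x.size),
        r_squared=float(res.rvalue**2),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def fit_mag_timepoints(
    paired: pd.DataFrame, min_points: int = 30, mags: Sequence[str] | None = None
) -> pd.DataFrame:
    """Monomial fits for every eligible MAG x time cell of a paired table.

    Cells with fewer than *min_points* gene pairs are skipped; *mags*
    optionally restricts the populations considered (a data-quality
    call, as MAG reconstructions differ in reliability).
    """
    rows = []
    for (mag, t), grp in paired.groupby(["mag_id", "time_h"], sort=True):
        if mags is not None and mag not in mags:
            continue
        if len(grp) < min_points:
            continue
        fit = fit_monomial(grp["rna_molecules"], grp["protein_molecules"], mag, t)
        rows.append(
            {"mag_id": fit.mag_id, "time_h": fit.time_h, "a_log10": fit.a_log10,
             "k": fit.k, "n_points": fit.n_points, "r_squared": fit.r_squared,
             "residual_sd": fit.residual_sd}
        )
    columns = ["mag_id", "time_h", "a_log10", "k", "n_points", "r_squared",
               "residual_sd"]
    return pd.DataFrame(rows, columns=columns)


def predict_protein_change(k: float, rna_fold_change: float) -> float:
    """Protein fold change implied by an RNA fold change under the
    monomial model: ``FC_protein = FC_RNA ** k``."""
    if rna_fold_change <= 0:
        raise ValueError("RNA fold change must be > 0")
    return float(rna_fold_change**k)


def fit_k_trajectory(times_h, k_values, mag_id: str = "") -> KTrajectory:
    """Degree-3 polynomial least squares of k on time (hours).

    Four points interpolate exactly; fewer are an error.  The fit is
    only valid inside the observed time range (``predict`` refuses to
    extrapolate).
    """
    t = np.asarray(times_h, dtype=float)
    k = np.asarray(k_values, dtype=float)
    if t.size != k.size:
        raise ValueError("times and k values differ in length")
    if t.size < 4:
        raise ValueError(f"need >= 4 time points for a cubic fit, got {t.size}")
    coeffs = np.polynomial.polynomial.polyfit(t, k, deg=3)
    fitted = np.polynomial.polynomial.polyval(t, coeffs)
    return KTrajectory(
        mag_id=mag_id,
        coefficients=tuple(float(c) for c in coeffs),
        residuals=k - fitted,
        time_range=(float(t.min()), float(t.max())),
    )


def kendall_rank_preservation(
    layer_a: pd.Series,
    layer_b: pd.Series,
    layer_pair: tuple[str, str] = ("MT", "MP"),
) -> RankAgreement:
    """Tie-corrected Kendall tau-b between two category-abundance rankings.

    Both series must be indexed by the same category set (e.g. KO
    functional categories; genomic layers rank by gene counts,
    expression layers by summed absolute molecules).
    """
    a_idx, b_idx = set(layer_a.index), set(layer_b.index)
    if a_idx != b_idx:
        only_a, only_b = sorted(a_idx - b_idx), sorted(b_idx - a_idx)
        raise ValueError(
            f"category sets differ: only in {layer_pair[0]}: {only_a}; "
            f"only in {layer_pair[1]}: {only_b}"
        )
    if len(layer_a) < 2:
        raise ValueError("need >= 2 categories")
    b = layer_b.reindex(layer_a.index)
    res = stats.kendalltau(layer_a.to_numpy(float), b.to_numpy(float))
    return RankAgreement(
        layer_pair=layer_pair,
        kendall_tau=float(res.statistic),
        p_value=float(res.pvalue),
        n_categories=int(len(layer_a)),
    )


def aggregate_pathway_markers(
    mt_absolute: pd.DataFrame,
    samples: pd.DataFrame,
    markers: Mapping[str, Sequence[str]],
    catalog: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pathway profiles: summed transcript molecules over marker genes.

    *markers* maps a pathway label to ORFG (or singleton ORF) ids.
    Unknown ids raise a warning and are skipped.  Per pathway and time
    point the member molecules are summed (replicate-averaged first),
    and a cubic polynomial smooths the log10 sums when >= 4 time points
    are available (points already lying on a cubic are reproduced
    exactly; with fewer than 4 points the smoothed column is NaN).
    """
    table = mt_absolute.merge(samples[["sample_id", "time_h"]], on="sample_id")
    known = set(table["orfg_id"])
    if catalog is not None:
        orf_to_orfg = catalog.set_index("orf_id")["orfg_id_mt"].to_dict()
    else:
        orf_to_orfg = {}
    rows = []
    for pathway, ids in markers.items():
        resolved, unknown = [], []
        for mid in ids:
            if mid in known:
                resolved.append(mid)
            elif mid in orf_to_orfg and orf_to_orfg[mid] in known:
                resolved.append(orf_to_orfg[mid])
            else:
                unknown.append(mid)
        if unknown:
            warnings.warn(
                f"pathway '{pathway}': {len(unknown)} unknown marker id(s) skipped: "
                f"{unknown[:5]}"
            )
        if not resolved:
            continue
        sub = table[table["orfg_id"].isin(resolved)]
        per_time = (
            sub.groupby(["orfg_id", "time_h"])["molecules_sample"].mean()
            .groupby("time_h").sum()
        )
        t = per_time.index.to_numpy(float)
        logv = np.log10(per_time.to_numpy(float))
        if t.size >= 4:
            coeffs = np.polynomial.polynomial.polyfit(t, logv, deg=3)
            smooth = np.polynomial.polynomial.polyval(t, coeffs)
        else:
            smooth = np.full(t.size, np.nan)
        for ti, raw, sm in zip(t, per_time.to_numpy(float), smooth):
            rows.append(
                {"pathway": pathway, "time_h": float(ti),
                 "total_molecules": float(raw), "smoothed_log10": float(sm),
                 "n_markers": len(resolved)}
            )
    return pd.DataFrame(rows)
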