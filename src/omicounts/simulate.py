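"""Ground-truthed synthetic multi-omics community generator.

Emulates the statistical structure of a time-resolved mixed
bacterial/archaeal consortium experiment: per-MAG open reading frames
(ORFs) with lognormal transcript copy numbers, protein copies tied to
RNA through the monomial law ``protein = a * RNA**k`` with log10 noise,
sequencing reads allocated over nucleotide mass alongside an RNA
spike-in internal standard, label-free protein intensities proportional
to protein mass fractions, a raw-peak table with a controlled identified
fraction, and a Bradford total-protein anchor.  All randomness flows
from a single integer seed, so identical configurations reproduce
identical datasets bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .mp import AVOGADRO, compute_mw

_AA20 = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")
_NT4 = np.frombuffer(b"ACGT", dtype="S1")

# Small KO vocabulary grouped into functional categories, enough to
# exercise annotation-driven ranking analyses.
_KO_CATEGORIES = {
    "Carbohydrate metabolism": ["K00001", "K00002", "K00003"],
    "Energy metabolism": ["K00100", "K00101", "K00102"],
    "Translation": ["K00200", "K00201"],
    "Amino acid metabolism": ["K00300", "K00301"],
    "Membrane transport": ["K00400", "K00401"],
    "Replication and repair": ["K00500"],
}


@dataclass
class MagSpec:
    """Parameters of one simulated population (MAG).

    ``median_ratio_target`` is the intended median protein-to-RNA ratio
    (molecules per molecule); typical regimes are ~1e3 for bacteria and
    ~1e4 for an archaeon.  When set, the scale constant ``a`` of the
    monomial law is derived per time point so the median ratio stays at
    the target regardless of ``k``; an explicit ``true_a_log10``
    overrides that derivation with a constant intercept.
    """

    mag_id: str
    domain_tag: str = "bacterial"
    n_orfs: int = 500
    true_k_per_timepoint: Sequence[float] | None = None
    true_a_log10: float | None = None
    rna_abundance_log10_mean: float = 8.0
    rna_abundance_log10_sd: float = 0.8
    median_ratio_target: float | None = 1e3

    def __post_init__(self) -> None:
        if self.domain_tag not in ("bacterial", "archaeal"):
            raise ValueError(f"{self.mag_id}: unknown domain_tag '{self.domain_tag}'")
        if self.n_orfs < 2:
            raise ValueError(f"{self.mag_id}: n_orfs must be >= 2, got {self.n_orfs}")
        if self.true_k_per_timepoint is not None:
            ks = np.asarray(self.true_k_per_timepoint, dtype=float)
            if ks.size and (ks.min() < 0.0 or ks.max() > 1.0):
                raise ValueError(f"{self.mag_id}: k values must lie in [0, 1]")
        if self.median_ratio_target is not None and self.median_ratio_target <= 0:
            raise ValueError(f"{self.mag_id}: median_ratio_target must be > 0")
        if self.rna_abundance_log10_sd < 0:
            raise ValueError(f"{self.mag_id}: rna_abundance_log10_sd must be >= 0")

    def k_values(self, n_timepoints: int) -> np.ndarray:
        if self.true_k_per_timepoint is None:
            # gentle default decline from 0.8 to 0.5
            return np.linspace(0.8, 0.5, n_timepoints)
        ks = np.asarray(self.true_k_per_timepoint, dtype=float)
        if ks.size != n_timepoints:
            raise ValueError(
                f"{self.mag_id}: true_k_per_timepoint has {ks.size} entries, "
                f"expected {n_timepoints}"
            )
        return ks


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic experiment.

    Defaults mirror the emulated design: 7 time points at 13-43 h in
    5 h steps (t2..t8), triplicates, a 60 ml sample of which 1/10 is
    used for the transcriptome aliquot, and a single in vitro
    transcript spike-in.
    """

    mags: list[MagSpec] = field(default_factory=lambda: default_community())
    n_timepoints: int = 7
    t_start_h: float = 13.0
    t_step_h: float = 5.0
    n_replicates: int = 3
    seq_depth: int = 1_000_000
    spike_molecules: float = 1e10
    spike_length_nt: float = 994.0
    spike_mass_fraction: float | None = None
    lfq_noise_sd: float = 0.2
    mt_noise_sd: float = 0.1
    mp_noise_sd: float = 0.2
    replicate_sd: float = 0.3
    temporal_sd: float = 0.3
    detect_fraction_mp: float = 0.8
    identified_peak_fraction: float = 0.6
    duplicate_fraction: float = 0.04
    aliquot_factor_mt: float = 10.0
    sample_volume_l: float = 0.060
    read_sampling: str = "multinomial"  # or "expected"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mags:
            raise ValueError("at least one MagSpec required")
        for name in ("n_timepoints", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.seq_depth < 0:
            raise ValueError("seq_depth must be >= 0")
        for name in ("detect_fraction_mp", "identified_peak_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.spike_mass_fraction is not None and not (
            0.0 < self.spike_mass_fraction < 1.0
        ):
            raise ValueError("spike_mass_fraction must be in (0, 1)")
        for name in ("lfq_noise_sd", "mt_noise_sd", "mp_noise_sd",
                     "replicate_sd", "temporal_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aliquot_factor_mt < 1:
            raise ValueError("aliquot_factor_mt must be >= 1")
        if self.spike_molecules <= 0 or self.spike_length_nt <= 0:
            raise ValueError("spike_molecules and spike_length_nt must be > 0")
        if self.sample_volume_l <= 0:
            raise ValueError("sample_volume_l must be > 0")
        if self.read_sampling not in ("multinomial", "expected"):
            raise ValueError("read_sampling must be 'multinomial' or 'expected'")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ValueError("duplicate_fraction must be in [0, 1)")

    @property
    def times_h(self) -> np.ndarray:
        return self.t_start_h + self.t_step_h * np.arange(self.n_timepoints)

    @property
    def replicates(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_replicates)]

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for ti, t in enumerate(self.times_h):
            for rep in self.replicates:
                rows.append({"sample_id": f"t{ti + 2}{rep}", "time_h": float(t),
                             "replicate": rep})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return asdict(self)


def default_community(n_orfs: int = 500) -> list[MagSpec]:
    """Seven-population community: six bacteria plus one archaeon.

    k(t) trajectories cover the regimes observed in mixed consortia:
    rapid decline, slow decline, and flat-to-increasing; bacterial MAGs
    target a median protein-to-RNA ratio of 1e3, the archaeon 1e4.
    """
    k = {
        "bac1": [0.85, 0.80, 0.74, 0.69, 0.64, 0.60, 0.56],  # slow decline
        "bac2": [0.80, 0.74, 0.67, 0.61, 0.56, 0.52, 0.49],
        "bac3": [0.78, 0.62, 0.48, 0.38, 0.31, 0.27, 0.24],  # rapid decline
        "bac4": [0.75, 0.58, 0.44, 0.34, 0.28, 0.24, 0.22],
        "bac5": [0.55, 0.56, 0.58, 0.61, 0.64, 0.67, 0.70],  # increasing
        "bac6": [0.40, 0.42, 0.45, 0.48, 0.52, 0.55, 0.58],
        "arch1": [0.82, 0.77, 0.71, 0.66, 0.61, 0.57, 0.54],
    }
    mags = []
    for mag_id, ks in k.items():
        archaeal = mag_id.startswith("arch")
        mags.append(
            MagSpec(
                mag_id=mag_id,
                domain_tag="archaeal" if archaeal else "bacterial",
                n_orfs=n_orfs,
                true_k_per_timepoint=ks,
                median_ratio_target=1e4 if archaeal else 1e3,
            )
        )
    return mags


@dataclass
class OrfCatalog:
    """ORF metadata plus (optionally) the sequences themselves."""

    table: pd.DataFrame  # orf_id, mag_id, orfg_id_mt, orfg_id_mp, length_nt, mw_g_per_mol, ko_terms
    nt_sequences: dict[str, str] | None = None
    aa_sequences: dict[str, str] | None = None


@dataclass
class GroundTruth:
    """True molecule counts and generating parameters.

    ``rna`` / ``protein`` are ORF x sample matrices of molecules per
    whole (60 ml) sample; ``transcriptome_nt`` is the per-sample total
    transcript nucleotide content; ``params`` holds true (a, k) per
    MAG x time.
    """

    rna: pd.DataFrame
    protein: pd.DataFrame
    transcriptome_nt: pd.Series
    params: pd.DataFrame  # mag_id, time_h, true_k, true_a_log10
    samples: pd.DataFrame  # sample_id, time_h, replicate


def _random_seq(rng: np.random.Generator, alphabet: np.ndarray, n: int) -> str:
    return rng.choice(alphabet, size=n).tobytes().decode()


def _draw_ko_terms(rng: np.random.Generator, n: int) -> list[str]:
    """~50% of ORFs annotated, 1-2 KO terms each."""
    all_terms = [t for terms in _KO_CATEGORIES.values() for t in terms]
    out = []
    for _ in range(n):
        if rng.random() < 0.5:
            k = 1 + int(rng.random() < 0.2)
            out.append(";".join(sorted(rng.choice(all_terms, size=k, replace=False))))
        else:
            out.append("")
    return out


def generate_community(
    config: SimulationConfig, make_sequences: bool = True
) -> tuple[OrfCatalog, GroundTruth]:
    """Draw the community: ORF catalog plus true RNA/protein counts.

    ORF lengths are lognormal (median 900 nt, rounded to codons);
    per-ORF RNA copies are lognormal per MAG with a per-time-point
    wander (sd ``temporal_sd``) and replicate noise (``replicate_sd``),
    both on the log10 scale; protein copies follow
    ``a(t) * RNA**k(t) * 10**N(0, mp_noise_sd)`` with RNA the realised
    replicate value.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    samples = config.sample_table()
    sample_ids = samples["sample_id"].tolist()
    times = config.times_h

    cat_rows: list[dict] = []
    nt_seqs: dict[str, str] = {}
    aa_seqs: dict[str, str] = {}
    rna_blocks: list[np.ndarray] = []
    prot_blocks: list[np.ndarray] = []
    orf_ids_all: list[str] = []
    param_rows: list[dict] = []

    for mag in config.mags:
        n = mag.n_orfs
        orf_ids = [f"{mag.mag_id}_orf{i + 1:05d}" for i in range(n)]
        # lengths: lognormal, median 900 nt, rounded to whole codons, >= 150 nt
        lengths = np.exp(rng.normal(math.log(900.0), 0.45, size=n))
        lengths = np.maximum(150, (np.round(lengths / 3.0) * 3).astype(int))

        # plant exact-duplicate ORFs -> multi-member ORFGs
        n_dup = int(round(config.duplicate_fraction * n))
        dup_of = np.full(n, -1)
        if n_dup and n >= 2 * n_dup:
            originals = rng.choice(n, size=2 * n_dup, replace=False)
            for src, dst in zip(originals[:n_dup], originals[n_dup:]):
                dup_of[dst] = src
                lengths[dst] = lengths[src]

        if make_sequences:
            for i, oid in enumerate(orf_ids):
                if dup_of[i] < 0:
                    nt_seqs[oid] = _random_seq(rng, _NT4, int(lengths[i]))
                    aa_seqs[oid] = _random_seq(rng, _AA20, int(lengths[i]) // 3 - 1)
            for i, oid in enumerate(orf_ids):
                if dup_of[i] >= 0:
                    nt_seqs[oid] = nt_seqs[orf_ids[dup_of[i]]]
                    aa_seqs[oid] = aa_seqs[orf_ids[dup_of[i]]]
            mws = np.array([compute_mw(aa_seqs[o]) for o in orf_ids])
        else:
            # mean 20-residue average mass, no explicit sequences
            mws = (lengths // 3 - 1) * 111.1 + 18.01528

        # ORFG ids: duplicates share the lexicographically smallest member id
        orfg = list(orf_ids)
        for i in range(n):
            if dup_of[i] >= 0:
                gid = min(orf_ids[i], orf_ids[dup_of[i]])
                orfg[i] = gid
                orfg[dup_of[i]] = gid

        ko = _draw_ko_terms(rng, n)
        for i, oid in enumerate(orf_ids):
            cat_rows.append(
                {
                    "orf_id": oid,
                    "mag_id": mag.mag_id,
                    "orfg_id_mt": orfg[i],
                    "orfg_id_mp": orfg[i],
                    "length_nt": int(lengths[i]),
                    "mw_g_per_mol": float(mws[i]),
                    "ko_terms": ko[i],
                }
            )

        ks = mag.k_values(config.n_timepoints)
        if mag.true_a_log10 is not None:
            a_log10 = np.full(config.n_timepoints, float(mag.true_a_log10))
        else:
            target = mag.median_ratio_target
            if target is None:
                target = 1e3
            a_log10 = np.log10(target) + (1.0 - ks) * mag.rna_abundance_log10_mean
        for ti, t in enumerate(times):
            param_rows.append(
                {"mag_id": mag.mag_id, "time_h": float(t),
                 "true_k": float(ks[ti]), "true_a_log10": float(a_log10[ti])}
            )

        base = rng.normal(mag.rna_abundance_log10_mean, mag.rna_abundance_log10_sd, size=n)
        wander = rng.normal(0.0, config.temporal_sd, size=(n, config.n_timepoints))
        log_rna = np.empty((n, len(sample_ids)))
        log_prot = np.empty_like(log_rna)
        col = 0
        for ti in range(config.n_timepoints):
            for _rep in config.replicates:
                rep_noise = rng.normal(0.0, config.replicate_sd, size=n)
                lr = base + wander[:, ti] + rep_noise
                mp_noise = rng.normal(0.0, config.mp_noise_sd, size=n)
                log_rna[:, col] = lr
                log_prot[:, col] = a_log10[ti] + ks[ti] * lr + mp_noise
                col += 1
        rna_blocks.append(10.0 ** log_rna)
        prot_blocks.append(10.0 ** log_prot)
        orf_ids_all.extend(orf_ids)

    catalog = OrfCatalog(
        table=pd.DataFrame(cat_rows),
        nt_sequences=nt_seqs if make_sequences else None,
        aa_sequences=aa_seqs if make_sequences else None,
    )
    rna = pd.DataFrame(np.vstack(rna_blocks), index=orf_ids_all, columns=sample_ids)
    protein = pd.DataFrame(np.vstack(prot_blocks), index=orf_ids_all, columns=sample_ids)
    lengths_all = catalog.table.set_index("orf_id")["length_nt"].reindex(rna.index)
    transcriptome_nt = rna.mul(lengths_all.to_numpy(), axis=0).sum(axis=0)
    transcriptome_nt.name = "transcriptome_nt"
    truth = GroundTruth(
        rna=rna,
        protein=protein,
        transcriptome_nt=transcriptome_nt,
        params=pd.DataFrame(param_rows),
        samples=samples,
    )
    return catalog, truth


def simulate_mt_observation(
    truth: GroundTruth, catalog: OrfCatalog, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate sequencing of the transcriptome aliquot plus spike-in.

    Reads are allocated (multinomially, or as exact expectations in
    ``read_sampling='expected'`` mode) across ORFs proportionally to
    nucleotide mass (molecules x length), with the spike-in competing at
    ``spike_molecules x spike_length_nt``.  Only 1/``aliquot_factor_mt``
    of the sample material enters the library; the spike-in is added to
    the aliquot in full.  Returns (mt_reads, spikein) tables; ORF reads
    are aggregated per ORFG.
    """
    if config.seq_depth <= 0:
        raise ValueError("seq_depth must be > 0 to simulate sequencing")
    rng = np.random.default_rng(config.seed + 1)
    cat = catalog.table.set_index("orf_id")
    lengths = cat["length_nt"].reindex(truth.rna.index).to_numpy(dtype=float)
    orfg = cat["orfg_id_mt"].reindex(truth.rna.index)

    i_m = config.spike_molecules
    i_nt = config.spike_length_nt
    if config.spike_mass_fraction is not None:
        aliquot_nt = (truth.transcriptome_nt / config.aliquot_factor_mt).mean()
        f = config.spike_mass_fraction
        i_m = f / (1.0 - f) * aliquot_nt / i_nt
    spike_weight = i_m * i_nt

    reads_rows = []
    spike_rows = []
    for sample in truth.rna.columns:
        w = truth.rna[sample].to_numpy() * lengths / config.aliquot_factor_mt
        if config.mt_noise_sd > 0:
            w = w * 10.0 ** rng.normal(0.0, config.mt_noise_sd, size=w.size)
        total = w.sum() + spike_weight
        p = np.concatenate([w, [spike_weight]]) / total
        if config.read_sampling == "multinomial":
            counts = rng.multinomial(config.seq_depth, p).astype(float)
        else:
            counts = config.seq_depth * p
        i_r = counts[-1]
        if i_r <= 0:
            raise ValueError(
                f"sample {sample}: no spike-in reads drawn "
                "(spike fraction too small for the sequencing depth)"
            )
        per_orfg = (
            pd.Series(counts[:-1], index=truth.rna.index)
            .groupby(orfg)
            .sum()
        )
        for gid, r in per_orfg.items():
            reads_rows.append(
                {"orfg_id": gid, "sample_id": sample, "reads": float(r),
                 "unique_hits": float(r)}
            )
        spike_rows.append(
            {"sample_id": sample, "i_m": float(i_m), "i_nt": float(i_nt),
             "i_r": float(i_r)}
        )
    return pd.DataFrame(reads_rows), pd.DataFrame(spike_rows)


def simulate_mp_observation(
    truth: GroundTruth, catalog: OrfCatalog, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate label-free proteomics: LFQ, raw peaks and Bradford tables.

    Per-ORFG LFQ is proportional to protein mass (molecules x MW) with
    multiplicative log10 noise; each ORFG is detected with probability
    ``detect_fraction_mp`` (undetected -> LFQ 0).  The Bradford table
    anchors the exact total protein mass of the whole sample.  The peak
    table is built so that the identified intensity-mass share equals
    ``identified_peak_fraction x (detected protein mass share)``.
    """
    rng = np.random.default_rng(config.seed + 2)
    cat = catalog.table.set_index("orf_id")
    mw_orf = cat["mw_g_per_mol"].reindex(truth.protein.index)
    orfg = cat["orfg_id_mp"].reindex(truth.protein.index)
    mw_orfg = mw_orf.groupby(orfg).mean()

    lfq_rows, peak_rows, bradford_rows = [], [], []
    for sample in truth.protein.columns:
        mass_orf = truth.protein[sample] * mw_orf  # g/mol-weighted molecule mass
        mass_orfg = mass_orf.groupby(orfg).sum()
        total_mass_g = float(mass_orf.sum() / AVOGADRO)

        detected = rng.random(mass_orfg.size) < config.detect_fraction_mp
        if not detected.any():
            raise ValueError(f"sample {sample}: no protein detected")
        noise = 10.0 ** rng.normal(0.0, config.lfq_noise_sd, size=mass_orfg.size)
        lfq = np.where(detected, mass_orfg.to_numpy() * noise, 0.0)
        n_pep = np.where(detected, rng.poisson(4, size=mass_orfg.size) + 1, 0)
        for gid, v, npep in zip(mass_orfg.index, lfq, n_pep):
            lfq_rows.append(
                {"orfg_id": gid, "sample_id": sample, "lfq": float(v),
                 "unique_peptides": int(npep)}
            )

        bradford_rows.append(
            {"sample_id": sample,
             "conc_g_per_l": total_mass_g / config.sample_volume_l,
             "volume_l": config.sample_volume_l}
        )

        detected_share = float(mass_orfg.to_numpy()[detected].sum() / mass_orfg.sum())
        target_ratio = config.identified_peak_fraction * detected_share
        n_id, n_un = 60, 40
        bpi_id = 10.0 ** rng.normal(6.0, 0.5, size=n_id)
        mass_id = rng.uniform(300.0, 1800.0, size=n_id)
        s_id = float(np.sum(bpi_id * mass_id))
        rows = [
            {"sample_id": sample, "peak_id": f"{sample}_p{i + 1:03d}",
             "base_peak_intensity": float(b), "mass_da": float(m), "identified": 1}
            for i, (b, m) in enumerate(zip(bpi_id, mass_id))
        ]
        if target_ratio < 1.0:
            bpi_un = 10.0 ** rng.normal(6.0, 0.5, size=n_un)
            mass_un = rng.uniform(300.0, 1800.0, size=n_un)
            s_un_needed = s_id * (1.0 - target_ratio) / target_ratio
            bpi_un *= s_un_needed / float(np.sum(bpi_un * mass_un))
            rows.extend(
                {"sample_id": sample, "peak_id": f"{sample}_p{n_id + i + 1:03d}",
                 "base_peak_intensity": float(b), "mass_da": float(m), "identified": 0}
                for i, (b, m) in enumerate(zip(bpi_un, mass_un))
            )
        peak_rows.extend(rows)

    return pd.DataFrame(lfq_rows), pd.DataFrame(peak_rows), pd.DataFrame(bradford_rows)


def write_dataset(
    dir_path: str | Path,
    catalog: OrfCatalog,
    truth: GroundTruth,
    mt_reads: pd.DataFrame,
    spikein: pd.DataFrame,
    mp_lfq: pd.DataFrame,
    peaks: pd.DataFrame,
    bradford: pd.DataFrame,
    seed: int | None = None,
) -> Path:
    """Write the full synthetic dataset as TSV/FASTA under *dir_path*."""
    if not str(dir_path).strip():
        raise ValueError("empty directory path")
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": seed} if seed is not None else None
    io.write_table(catalog.table, out / "orf_catalog.tsv", "orf_catalog", meta)
    io.write_table(mt_reads, out / "mt_reads.tsv", "mt_reads", meta)
    io.write_table(spikein, out / "spikein.tsv", "spikein", meta)
    io.write_table(mp_lfq, out / "mp_lfq.tsv", "mp_lfq", meta)
    io.write_table(peaks, out / "peaks.tsv", "peaks", meta)
    io.write_table(bradford, out / "bradford.tsv", "bradford", meta)
    io.write_table(truth.samples, out / "samples.tsv", "samples", meta)
    if catalog.nt_sequences:
        io.write_fasta(catalog.nt_sequences, out / "orfs.fna")
    if catalog.aa_sequences:
        io.write_fasta(catalog.aa_sequences, out / "orfs.faa")
    tdir = out / "truth"
    io.write_table(
        truth.rna.rename_axis("orf_id").reset_index().melt(
            id_vars="orf_id", var_name="sample_id", value_name="molecules"
        ),
        tdir / "rna_molecules.tsv", "truth_expression", meta,
    )
    io.write_table(
        truth.protein.rename_axis("orf_id").reset_index().melt(
            id_vars="orf_id", var_name="sample_id", value_name="molecules"
        ),
        tdir / "protein_molecules.tsv", "truth_expression", meta,
    )
    io.write_table(truth.params, tdir / "params.tsv", "truth_params", meta)
    io.write_table(
        truth.transcriptome_nt.rename_axis("sample_id").reset_index(),
        tdir / "transcriptome_nt.tsv", "truth_transcriptome", meta,
    )
    return out


def read_dataset(dir_path: str | Path) -> dict[str, pd.DataFrame | dict[str, str]]:
    """Read back a dataset written by :func:`write_dataset`."""
    d = Path(dir_path)
    out: dict[str, pd.DataFrame | dict[str, str]] = {
        "orf_catalog": io.read_table(d / "orf_catalog.tsv", "orf_catalog"),
        "mt_reads": io.read_table(d / "mt_reads.tsv", "mt_reads"),
        "spikein": io.read_table(d / "spikein.tsv", "spikein"),
        "mp_lfq": io.read_table(d / "mp_lfq.tsv", "mp_lfq"),
        "peaks": io.read_table(d / "peaks.tsv", "peaks"),
        "bradford": io.read_table(d / "bradford.tsv", "bradford"),
        "samples": io.read_table(d / "samples.tsv", "samples"),
    }
    if (d / "orfs.fna").exists():
        out["nt_sequences"] = io.read_fasta(d / "orfs.fna")
    if (d / "orfs.faa").exists():
        out["aa_sequences"] = io.read_fasta(d / "orfs.faa")
    tdir = d / "truth"
    if tdir.is_dir():
        out["truth_rna"] = io.read_table(tdir / "rna_molecules.tsv", "truth_expression")
        out["truth_protein"] = io.read_table(
            tdir / "protein_molecules.tsv", "truth_expression"
        )
        out["truth_params"] = io.read_table(tdir / "params.tsv", "truth_params")
        out["truth_transcriptome_nt"] = io.read_table(
            tdir / "transcriptome_nt.tsv", "truth_transcriptome"
        )
    return out
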