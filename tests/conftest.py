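import numpy as np
import pandas as pd
import pytest

import omicounts as oc


@pytest.fixture(scope="session")
def small_config() -> oc.SimulationConfig:
    """Three-MAG desk-scale community: two bacteria + one archaeon."""
    mags = [
        oc.MagSpec("bacA", "bacterial", n_orfs=30,
                   true_k_per_timepoint=[0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5],
                   median_ratio_target=1e3),
        oc.MagSpec("bacB", "bacterial", n_orfs=30,
                   true_k_per_timepoint=[0.7, 0.6, 0.5, 0.45, 0.4, 0.38, 0.35],
                   median_ratio_target=1e3),
        oc.MagSpec("archA", "archaeal", n_orfs=30,
                   true_k_per_timepoint=[0.8, 0.76, 0.72, 0.68, 0.64, 0.6, 0.56],
                   median_ratio_target=1e4),
    ]
    return oc.SimulationConfig(mags=mags, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    catalog, truth = oc.generate_community(small_config)
    mt_reads, spikein = oc.simulate_mt_observation(truth, catalog, small_config)
    mp_lfq, peaks, bradford = oc.simulate_mp_observation(truth, catalog, small_config)
    return {
        "config": small_config, "catalog": catalog, "truth": truth,
        "mt_reads": mt_reads, "spikein": spikein,
        "mp_lfq": mp_lfq, "peaks": peaks, "bradford": bradford,
    }


@pytest.fixture(scope="session")
def noiseless_config() -> oc.SimulationConfig:
    """All noise off, full detection, expectation-mode reads: the
    quantification chain must invert the simulation exactly."""
    mags = [
        oc.MagSpec("bacA", "bacterial", n_orfs=25,
                   true_k_per_timepoint=[0.8] * 7, median_ratio_target=1e3),
        oc.MagSpec("archA", "archaeal", n_orfs=25,
                   true_k_per_timepoint=[0.7] * 7, median_ratio_target=1e4),
    ]
    return oc.SimulationConfig(
        mags=mags, seed=11,
        lfq_noise_sd=0.0, mt_noise_sd=0.0, mp_noise_sd=0.0,
        replicate_sd=0.0, temporal_sd=0.0,
        detect_fraction_mp=1.0, identified_peak_fraction=1.0,
        duplicate_fraction=0.0, read_sampling="expected",
    )


def paired_from_truth(truth, catalog) -> pd.DataFrame:
    """Replicate-mean paired table straight from ground truth (no
    observation layer), for parameter-recovery tests."""
    samples = truth.samples.set_index("sample_id")
    mags = catalog.table.set_index("orf_id")["mag_id"]
    frames = []
    for t, cols in samples.groupby("time_h").groups.items():
        frames.append(pd.DataFrame({
            "orf_id": truth.rna.index,
            "mag_id": mags.reindex(truth.rna.index).to_numpy(),
            "time_h": float(t),
            "rna_molecules": truth.rna[list(cols)].mean(axis=1).to_numpy(),
            "protein_molecules": truth.protein[list(cols)].mean(axis=1).to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
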