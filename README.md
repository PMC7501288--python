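# omicounts

Absolute multi-omics quantification for mixed microbial communities.

Meta-omics layers are usually reported in relative units, which makes
them incomparable between samples and — worse — between layers: an RPKM
cannot be divided by an LFQ intensity.  `omicounts` converts both layers
of a time-resolved metatranscriptome/metaproteome experiment into
**molecules per sample**, so that quantities like the protein-to-RNA
ratio of a population, or how faithfully protein levels track transcript
levels, become well-defined numbers.

The package is aimed at microbiome researchers working with
MAG-resolved expression data (e.g. anaerobic digestion consortia of
cellulolytic bacteria and methanogenic archaea), and at anyone who wants
a fully testable, ground-truthed sandbox for absolute-quantification
workflows.

## What it computes

**Absolute transcripts (RNA spike-in).**  A known number of molecules
`I_M` of an in vitro transcript of length `I_Nt` nt is spiked into the
RNA extraction and draws `I_R` reads.  The transcriptome size follows
from read proportionality,

    ΣT_Nt = I_M · I_Nt · ΣT_R / I_R

and per-gene molecule counts from RPKM:

    T_M = T_RPKM / 10⁹ · ΣT_Nt

**Absolute proteins (total protein approach).**  LFQ intensities are
normalised to mass fractions, divided by molecular weight, and anchored
to the *detected protein mass* — the Bradford-measured total mass times
the intensity×mass share of identified MS peaks:

    copy_numberᵢ = (LFQᵢ / ΣLFQ) / MWᵢ · detected_mass · N_A

**Integration and dynamics.**  The layers are filtered (unique hits,
log10 with pseudocount 1, minimum expression thresholds of 5 for MT and
8 for MP, outlier-sample screening), restricted to ORF-groups that are
singletons in both layers, and paired per gene.  From the paired table
the package computes per-population protein-to-RNA ratio distributions,
gene-wise Pearson correlations over time, the monomial law

    protein = a · RNAᵏ      (fit as log₁₀ protein = a_log10 + k · log₁₀ RNA)

per population and time point with a cubic k(t) trend, Kendall τ-b rank
preservation of functional categories across layers, and marker-gene
pathway profiles.

A synthetic community generator (`omicounts.simulate`) produces all of
the above inputs with known ground truth, so every stage is testable
without external data.

## Worked example

```python
import omicounts as oc

cfg = oc.SimulationConfig(mags=oc.default_community(n_orfs=200), seed=1)
catalog, truth = oc.generate_community(cfg)
mt_reads, spikein = oc.simulate_mt_observation(truth, catalog, cfg)
mp_lfq, peaks, bradford = oc.simulate_mp_observation(truth, catalog, cfg)

mt_abs, _ = oc.quantify_mt(mt_reads, spikein, catalog.table, aliquot_factor=10)
mp_abs, _ = oc.quantify_mp(mp_lfq, peaks, bradford, catalog.table)
paired, report, _ = oc.integrate_layers(mt_abs, mp_abs, catalog.table, truth.samples)

domains = {m.mag_id: m.domain_tag for m in cfg.mags}
ratios = oc.protein_rna_ratios(paired, time_h=18.0, domains=domains)
print(ratios.round(0).to_string(index=False))
```

This prints (seed 1):

```
      mag_id  time_h  median    q25    q75   min     max  n_genes
       arch1    18.0  5539.0 3429.0 9046.0 736.0 42790.0      176
        bac1    18.0   533.0  342.0  776.0 104.0  2639.0      182
        bac2    18.0   552.0  317.0  922.0  57.0  8262.0      183
        bac3    18.0   506.0  297.0  957.0  28.0  6717.0      183
        bac4    18.0   510.0  283.0  987.0  51.0  6128.0      181
        bac5    18.0   543.0  313.0 1020.0  42.0 16184.0      180
        bac6    18.0   482.0  229.0 1046.0  17.0 12333.0      180
all_bacteria    18.0   523.0  295.0  942.0  17.0 16184.0     1089
```

The archaeal population sits roughly an order of magnitude above every
bacterial population — the domain-level signature the generator plants
(bacteria at a median target of 10³ protein molecules per transcript,
the archaeon at 10⁴) and the pipeline recovers.  The bacterial medians
fall below their 10³ target because the expression filters preferentially
retain highly transcribed genes, which at sub-unit linearity k have
lower ratios.

The `examples/` directory contains one short script per capability
(simulation, quantification, integration/ratios, monomial dynamics,
rank preservation); each prints the numbers it computes and a line on
what they mean.  A thin CLI mirrors the stages:

```bash
omicounts simulate --seed 1 --out dataset/
omicounts run-all --seed 1 --out run/
omicounts config            # dump all defaults
```

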