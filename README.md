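# coccoproteome

Analysis pipeline for coccolithophore ocean-acidification experiments:
seawater carbonate-system speciation, batch-culture physiology, and iTRAQ
8-plex quantitative proteomics with homologous-protein-group inference —
plus a synthetic-data generator with recorded ground truth so every stage is
testable end to end without any external downloads.

## Who this is for

Experimentalists analysing CO₂-manipulation cultures of calcifying
phytoplankton (e.g. *Emiliania huxleyi*): you have bottle DIC/total
alkalinity measurements, daily Coulter-counter densities, per-cell elemental
quotas, and reporter-ion PSM tables from an isobaric-tag (iTRAQ 8-plex)
experiment, and you want the standard derived quantities and a defensible
differential-expression call per protein.

## What it computes

**Carbonate chemistry** (`coccoproteome.carbonate`). Given DIC and TA at
known *T*, *S* the solver finds the total-scale pH that closes the
alkalinity balance

TA = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]_F − [HSO₄⁻] − [HF]
(optionally + phosphate/silicate terms),

then reports pCO₂ = [CO₂(aq)]/K₀, the three carbon species, and the calcite
saturation state Ω = [Ca²⁺][CO₃²⁻]/K_sp. Constants: K₀ Weiss (1974), K₁/K₂
Mehrbach et al. (1973) refit by Dickson & Millero (1987) converted to the
total scale, K_B Dickson (1990b), K_W Millero (1995), K_S Dickson (1990a),
calcite solubility Mucci (1983); pressure 0 dbar.

**Physiology** (`coccoproteome.physiology`). µ = ln(C₁/C₀)/Δt,
g = log₂(N₁/N₀), production = quota × µ, CaCO₃ quotas from ICP-OES Ca with a
Na-proxy seawater blank, nutrient-utilization percentages, and unpaired
pooled-variance t-tests runnable directly from (mean, sd, n) summaries.

**iTRAQ quantification** (`coccoproteome.itraq`). Peptide reporter ratios
(high:ambient per replicate pair) are intensity-weighted, median-normalized
within each pair, cleaned by an iterated Grubbs test on log ratios, and
combined into a weighted geometric-mean protein ratio per replicate.
Across the three replicate pairs the geometric mean *G* and its 95% CI
(z = 1.96 on natural-log ratios) decide regulation: **down** iff the whole
interval ≤ 0.67, **up** iff ≥ 1.5, else unchanged; single-peptide
identifications and two-peptide identifications with one erroneous ratio
are not evaluable.

**Protein inference** (`coccoproteome.inference`). Six-frame EST
translation, tryptic digestion, exact peptide-to-database mapping with the
two-distinct-peptide rule, Smith–Waterman/BLOSUM62 pairwise alignment with
a Karlin–Altschul e-value, and single-linkage clustering of identifications
into homologous protein groups (HPGs) at e ≤ 1e−10 and > 5% identity.

**Synthetic data** (`coccoproteome.simulate`) and a one-shot orchestrator
(`coccoproteome.pipeline.run_all`, CLI `coccoproteome run`) that chains
simulate → carbonate → physiology → inference → quantification → report,
byte-identically reproducible from a seed.

## Worked example

```python
from coccoproteome.carbonate import solve_from_dic_ta
from coccoproteome.itraq import replicate_geomean_ci, classify_regulation

s = solve_from_dic_ta(2145.7, 2200.4, temperature=19.0, salinity=35.0)
print(f"pH={s.ph:.3f} pCO2={s.pco2:.1f} omega={s.omega_cal:.2f}")
# pH=7.571 pCO2=1302.3 omega=1.58

G, lo, hi = replicate_geomean_ci((0.28, 0.45, 0.61))
print(f"G={G:.3f} CI=({lo:.2f}, {hi:.2f}) -> {classify_regulation(lo, hi)}")
# G=0.425 CI=(0.27, 0.66) -> down
```

The first call speciates a high-CO₂ culture at harvest: the water is still
supersaturated with respect to calcite (Ω ≈ 1.6) but pCO₂ is ~1300 µatm.
The second takes the three replicate expression ratios of a chloroplastic
30S ribosomal protein: the geometric mean is 0.43 and the entire 95% CI
lies below 0.67, so the protein is called down-regulated under high CO₂.

Full pipeline on synthetic data:

```sh
coccoproteome run --seed 1 --outdir pipeline_out
```

writes the synthetic inputs, a per-bottle speciation table with percent DIC
drawdown, per-replicate growth/quota/production summaries with
between-condition t-tests, the HPG table, per-protein regulation calls, and
a plain-text report.

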