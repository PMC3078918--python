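# pamkin

Kinetic analysis of real-time peptide-microarray kinase assays.

Porous-chip (PamChip®) peptide microarrays read out tyrosine-kinase activity
in real time: each spot carries an immobilised peptide, reaction mix is
pumped through the pores, and phosphorylation is imaged continuously via a
fluorescent anti-phosphotyrosine antibody.  `pamkin` implements the full
analysis chain used to characterise the JAK2 kinase domain (JH1), its
pseudokinase-containing forms (JH1-JH2 wild type and the myeloproliferative-
neoplasm mutant V617F), and JAK3 JH1 on such arrays:

1. **Initial-rate extraction** — each spot's background-subtracted time
   series is fitted to the exponential association
   `y(c) = y0 + ymax(1 − e^(−kc))` and the initial velocity is the tangent
   at the second imaged cycle, `v = ymax · k · e^(−kc) · 2` (signal/min).
2. **Substrate calling** — a peptide is a substrate when its 20-minute
   signal exceeds 2× the background SD, increases with both enzyme and ATP,
   and is absent from all negative controls (no enzyme, no ATP,
   staurosporine, AMP-PNP, kinase-dead enzyme, pre-activated enzyme).
3. **Kinetics** — rates are normalised to the construct's activity on
   1000 µM STA5A_687_699 per pmol enzyme; `Km(ATP)` and apparent `Vmax` come
   from a Michaelis–Menten fit of the ATP titration, and the catalytic
   efficiency `Vmax/Km` per peptide from the slope of v vs [peptide] in the
   low-concentration linear regime (at 400 µM ATP).
4. **Comparison transforms** — fold change with a reference construct set
   to 1, and each efficiency as a percent of its construct's total.
5. **Substrate motifs** — peptides aligned on the central tyrosine (−5..+5),
   weighted by percent-of-total efficiency; stack heights are the relative
   entropy (bits) of each position's weighted residue distribution against a
   uniform background.

A synthetic-data generator emulates the assay end to end (144-peptide
screening arrays, the 24-peptide custom chip with its
{100, 300, 400, 600, 750, 1000} µM concentration series, 60 pump cycles at
2 cycles/min imaged every second cycle, all negative controls, Gaussian
noise) so that every stage can be validated against known ground truth.
The package ships the published screen calls, catalytic-efficiency table
and kinetic constants as versioned fixtures that drive the simulator.

## Worked example

```python
import pamkin as pk
from pamkin.simulate import NoiseModel, custom_chip_design, custom_chip_layout, simulate_experiment
from pamkin.rates import extract_rates
from pamkin.kinetics import normalize_activity, efficiency_table
from pamkin.compare import comparison_table

profiles = pk.load_constructs()
design = custom_chip_design(profiles, ("JAK2_JH1JH2_WT", "JAK2_JH1"))
data, truth = simulate_experiment(design, custom_chip_layout(), profiles,
                                  NoiseModel.noiseless(), master_seed=1)
rates = extract_rates(data)
normalized = normalize_activity(rates, reference_value=truth["reference_values"])
effs = efficiency_table(normalized)
comp = comparison_table(effs, "JAK2_JH1JH2_WT")
row = comp[(comp.construct == "JAK2_JH1") & (comp.peptide_id == "STA5A_687_699")]
print(row[["vmax_km", "fold_change", "fold_change_int"]].to_string(index=False))
```

prints

```
 vmax_km  fold_change  fold_change_int
   2.087    19.688679               20
```

i.e. from a zero-noise simulated chip the pipeline recovers the kinase
domain's catalytic efficiency on the STAT5A peptide (2.087 relative-activity
units · µM⁻¹) and its 20-fold increase over the JH1-JH2 wild type — the
pseudokinase domain's inhibitory effect.

The same stages are available from the shell:

```
pamkin simulate --design custom --seed 1 --out chip.csv --truth-out truth.json
pamkin fit-rates --input chip.csv --out rates.tsv
pamkin kinetics --rates rates.tsv --atp 400 --out kinetics.tsv
pamkin compare --kinetics kinetics.tsv --reference JAK2_JH1JH2_WT --out comparison.tsv
pamkin motif --comparison comparison.tsv --construct JAK2_JH1 --out motif.tsv
pamkin run --out-dir results/   # end-to-end bundle with MANIFEST
```

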