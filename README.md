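# thermadapt

Tools for studying thermal adaptation in closely related ectotherm
populations — built around the comparison of Arctic (Kongsfjord) and
Subarctic (Porsangerfjord) populations of *Strongylocentrotus* sea
urchins, but applicable to any foreground/background population
contrast with aligned orthogroups and enzyme temperature-profile
assays.

The package answers two linked questions:

1. **Which amino acid positions changed convergently?** Given aligned
   orthogroups (one protein alignment per ortholog cluster) and a
   taxon-to-group mapping, it detects **convergent amino acid
   substitutions (CAAS)**: alignment columns where the residues of all
   foreground taxa are mutually exclusive with those of all background
   taxa. Detected substitutions are profiled by the amino-acid flux

   > D = (C − R) / (C + R)

   where C counts the events in which an amino acid was gained
   (created) in the foreground population and R those in which it was
   lost, along with the 20×20 exchange matrix, residue-class tallies
   (hydrophilic N,Q,S,T,Y / hydrophobic A,C,F,G,I,L,M,P,V,W / negative
   D,E / positive H,K,R), the arginine/lysine ratio (a classical
   cold-adaptation signature), and COG functional-category summaries.

2. **Do the enzymes behave differently?** From replicate assay rates
   (or raw 5-minute signal time series) measured across 2–50 °C, it
   builds temperature-activity profiles and estimates the **Arrhenius
   activation energy** from the linearised law

   > ln k = ln A − (Eₐ / R) · (1 / T)

   by regressing ln(rate) on reciprocal absolute temperature over a
   configurable window (default 2–20 °C, below the activity optimum),
   so Eₐ = −slope·R. Populations are compared with Welch t-tests
   (from raw values or from printed mean ± SD summaries) and one-way
   ANOVA with Tukey's HSD.

A synthetic-data module generates orthogroup alignments with *planted*
convergent columns and enzyme assays with known Arrhenius parameters,
so every stage is testable against ground truth without any downloads.

## Worked example

```python
import thermadapt as ta

# synthetic orthogroups: 20 alignments x 100 columns, 10 planted CAAS
spec = ta.OrthogroupSimSpec(n_orthogroups=20, alignment_length=100,
                            n_planted_caas=10, seed=7)
orthogroups, truth = ta.simulate_orthogroups(spec)
roles = {t.taxon_id: t.role for t in spec.taxa}

caas = ta.scan_collection(orthogroups, roles)
print(caas.head(3).to_string(index=False))
print("total CAAS:", len(caas))
```

```
orthogroup_id  column_trimmed  column_original fg_residues bg_residues  scenario  n_missing
       OG0001              12               12           C           F         3          0
       OG0004              50               50           L           Q         3          0
       OG0006               1                1           A           R         3          0
total CAAS: 10
```

The scan recovers exactly the ten planted columns: in each, the
foreground taxa share one residue (`fg_residues`) and the background
taxa a disjoint one (`bg_residues`). Per-amino-acid gain/loss counts
and the flux follow directly:

```python
flux_table, exchange = ta.count_gain_loss(caas)
print(flux_table[flux_table.gains + flux_table.losses > 0].head(4))
```

```
            gains  losses      flux
amino_acid
A               1       1  0.000000
C               1       0  1.000000
F               0       2 -1.000000
H               1       2 -0.333333
```

A flux of +1 means a residue only ever appeared in the foreground
population (pure gain), −1 that it was only ever replaced.

On the kinetics side, simulate two populations with true activation
energies of 50 and 55 kJ·mol⁻¹, 5 replicates, 5 % multiplicative
noise, and fit one of them:

```python
kin = ta.KineticsSimSpec(populations=(("arctic", 50.0, 2.0e9),
                                      ("subarctic", 55.0, 2.0e10)),
                         sigma=0.05, seed=7)
rates, _, _ = ta.simulate_kinetics(kin)
fit = ta.ArrheniusModel.from_dataframe(
    rates[rates.population == "arctic"]).fit()
print(fit.summary())
```

```
Arrhenius fit (ln k ~ 1/T)
  window           : 2-20 C
  Ea               : 48.972 kJ/mol
  ln A             : 20.961
  r^2              : 0.9937
  temperatures used: 5
  observations     : 25
```

The fitted Eₐ of 48.97 kJ·mol⁻¹ sits about 2 % from the generating
value of 50, as expected at this noise level. Comparing two published
per-group summaries (mean ± SD, n = 5 each) takes one call:

```python
cmp_ = ta.welch_from_summary(45.881, 4.725, 5, 60.190, 5.255, 5)
# t = -4.528, df = 7.91, p = 0.002
```

a highly significant difference in activation energy between the two
populations under Welch's unequal-variance t-test.

## Command line

```sh
thermadapt simulate --out-dir demo --seed 7        # synthetic inputs + truth
thermadapt caas --alignments demo/alignments --taxon-map demo/taxon_map.tsv --out-dir demo
thermadapt profile --caas-table demo/caas.tsv --out-dir demo
thermadapt kinetics --rates demo/rates.tsv --out-dir demo
thermadapt stats --arrhenius demo/arrhenius.tsv --profiles demo/profiles.tsv --out-dir demo
```

Every run writes its resolved configuration and seed beside the
outputs.

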