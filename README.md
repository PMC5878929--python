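# sdapower

Power analysis for detecting first-generation dispersers from
microsatellite marker panels, via **Simulated Disperser Analysis (SDA)**.

## The problem

Genetic assignment tests detect first-generation migrants: an individual
sampled in one population whose multilocus genotype is much more likely
under another population's allele frequencies. Whether the test actually
has the power to catch such a migrant depends on the marker panel (how
many loci, how informative), on how differentiated the populations are,
and on the direction of movement — and this power is almost never
quantified before a study is run.

SDA measures it directly from the data at hand: take real (or simulated)
individuals, relabel them into every other population as *simulated
dispersers*, rerun the detection machinery on nested marker panels
(adding loci one at a time, most-informative-first and
least-informative-first), and record whether each simulated disperser is
caught, missed, or assigned to the wrong source. The output is a
treatments × panels grid from which one can read off the smallest panel
that reliably detects dispersal for each population pair, and fit a
logistic power model (correct classification against panel size,
ranking direction and pairwise differentiation).

The package implements the full pipeline:

- `genotype_io` — GENEPOP and CSV genotype tables, subsetting, relabelling
- `popgen_stats` — allele frequencies, PIC, Weir–Cockerham θ, Shannon
  mutual information, Hardy–Weinberg Monte Carlo exact tests, locus
  ranking
- `assignment` — Rannala–Mountain partial-Bayesian genotype likelihoods,
  Lh and Lh/Lmax statistics, Monte Carlo resampling nulls
  (Paetkau-style exclusion test), migrant detection
- `synthetic_data` — Balding–Nichols generators, including a
  hierarchical "starling-like" preset (3 populations, 29 loci, one
  distant population and a close pair), and true-disperser planting
- `sda_engine` — treatment enumeration, nested panels, the SDA grid,
  minimal panel sizes, worst-case quick check, heatmap plotting
- `power_model` — logistic (GLM/GLMM) power models and Nakagawa–Schielzeth
  R², literature-table summaries

## Worked example

```python
import sdapower as sp

# 1. simulate a starling-like study: 3 populations, 29 microsatellites
table, truth = sp.simulate_starling_like(seed=1)
print(table.population_sizes())
diff = sp.pairwise_differentiation(table)
print(diff.round(3).to_string(index=False))
```

```
{'Munglinup': 30, 'Mallala': 32, 'Orange': 32}
    pop_a   pop_b  theta_fst  mutual_information
Munglinup Mallala      0.073               0.147
Munglinup  Orange      0.064               0.143
  Mallala  Orange      0.036               0.074
```

One distant population (Munglinup) and a weakly differentiated close
pair (Mallala–Orange), as configured. Now plant two true dispersers and
run detection:

```python
planted, ptruth = sp.plant_dispersers(
    table, truth, [("Munglinup", "Orange", 2)], seed=1
)
config = sp.AssignmentConfig(alpha=0.01, n_simulated=1000, seed=1)
frame = sp.results_frame(sp.detect_migrants(planted, config))
print(frame[frame["individual"].isin(ptruth.planted)]
      .round(3).to_string(index=False))
```

```
   individual   home  neg_log10_L_Munglinup  neg_log10_L_Mallala  neg_log10_L_Orange  statistic  p_value  flagged_disperser assigned_source
disperser_001 Orange                 36.164               54.853              40.789        0.0    0.001               True       Munglinup
disperser_002 Orange                 42.593               56.431              41.098        1.0    1.000              False          Orange
```

The first planted disperser is flagged (p = 0.001) and assigned to its
true source; the second is missed — exactly the kind of imperfect power
SDA is designed to quantify. Run the SDA itself for the worst-case
movement plan:

```python
cands = sp.select_candidates(table, sp.detect_migrants(table, config), seed=1)
plan, direction = sp.worst_case_plan(table, diff, cands)
stats = sp.locus_statistics(table, n_permutations=200, seed=1)
panels = sp.prefix_series(sp.rank_loci(stats, sp.HIGHEST_FIRST))
grid = sp.run_grid(table, cands, [plan], panels, config)
print(sp.minimal_panel(grid).to_string(index=False))
```

```
    disperser     direction  minimal_panel_size
  Mallala_017 highest_first                   6
  Mallala_017  lowest_first                  14
Munglinup_015 highest_first                   1
Munglinup_015  lowest_first                  15
   Orange_025 highest_first                  12
   Orange_025  lowest_first                  16
```

Ranking informative loci first pays: the same candidates need 6–12 loci
when the highest-PIC markers are genotyped first, but 14–16 when the
least informative come first.

## Command line

The same pipeline is exposed as a CLI:

```bash
sdapower simulate --preset starling-like --seed 1 --out sim.gen
sdapower stats --input sim.gen --out stats/
sdapower assign --input sim.gen --nsim 1000 --seed 1 --out assign.csv
sdapower validate-panel --input sim.gen --nsim 1000 --seed 1 --out sda/
```

`validate-panel` runs the full workflow (HWE screen, differentiation,
baseline assignment, SDA grid, minimal panels, heatmap, power model) and
writes a `manifest.json` recording completed stages.

## Reproduction

```bash
python -m pytest -q tests/            # unit + acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script computes every reported number at run time; with
`--seed 1` it reports, among others, 27 treatments / 57 nested panels
for the 3-population × 29-locus design, a detector type-I error rate of
0.006 at α = 0.01 on 500 synthetic residents (KS uniformity statistic
0.025), mean recovered θ of 0.0789 for a configured F of 0.08, and a
grid-level correct-classification rate of 0.855 (highest-PIC-first)
vs 0.742 (lowest-PIC-first). Two acceptance tests require the original
study's supplementary data files (`data/starling_genotypes.csv`,
`data/literature_records.csv`), which are not distributed here; they
fail with an explanatory message until those files are supplied.

See `docs/methods.md` for the statistical methods and their numerical
details.
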