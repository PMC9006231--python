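# wolsweep

Fig wasps on tropical elevation gradients often carry *Wolbachia*,
maternally inherited bacteria whose cytoplasmic incompatibility (CI)
sterilises crosses between hosts with mismatched infections.  Two linked
ecological rules can predict which strains occur where:

* **contact contingency** — only incipient host species that actually
  co-occur (same host fig community) need distinguishable CI strains; a
  community with a single species carries none;
* **adaptive decay** — hosts purge *Wolbachia* once their nearest
  relatives in the community are so diverged that other isolation
  mechanisms make CI redundant.

`wolsweep` turns these rules into a testable prediction engine for
communities of host figs sampled along an elevation gradient, plus a
fitness model asking when CI itself is adaptive.  It is aimed at
researchers with (i) a tip-level host phylogeny, (ii) per-individual
strain typing, and (iii) a community/elevation sampling design.

## What it computes

**Species-delimitation sweep.** A putative species is a contiguous run of
elevation sites within one host (occupancy vector, e.g. `1110`); a host
with *n* sites admits 2^(n−1) delimitations (compositions of the site
line), and a putative species combination (PSC) picks one per host — the
six-host study layout yields 8 × 1 × 2 × 2 × 8 × 32 = 8192 PSCs.  For
each PSC, strains are ascribed under contact contingency, then removed
under adaptive decay across a grid of purge thresholds applied to
min-linkage patristic distances,

d(psp₁, psp₂) = min over i, j of d(Tᵢ ∈ psp₁, Tⱼ ∈ psp₂),

a species being purged only when *every* community neighbour lies
strictly beyond the threshold.

**Accuracy scoring.** Predictions are scored against empirical typing by
a constrained matching: in the ascribed × empirical contingency matrix,
pick at most one cell per row and per column maximising the total count
(an exact assignment-problem solution).  This yields WIA (positive
infection accuracy), uWIA (uninfected accuracy) and PSC accuracy
(putative vs. empirical species), with OLS regressions, a label-shuffling
null and Welch's *t*-test for evaluation.

**Fecundity trade-off model.** With oviposition layers of decreasing
quality ω₁ ≥ … ≥ ω_L and finite capacities, a foundress laying N eggs
(N_c conspecific, π_c = N_c/N) has fitness

W_r = Σ_l (π_c ω_c + π_h ω_h) · eggs_l · ω_l  (no CI, random order)
W_p = ω_c Σ_l eggs_l · ω_l over the N_c conspecific eggs  (CI),

since CI kills incompatible eggs before they waste premium sites.  The
package maps ΔW = W_p − W_r over (ω_c, ω_h) space and reports the
fraction of fitness space favouring CI per conspecific-mating level.

Because deposited empirical data are not bundled, a first-class synthetic
generator produces trees, metadata and ground truth mirroring the study
conditions (253 individuals, four communities, 80% strain penetrance, 2%
horizontal-transfer noise).

## Worked example

```python
import wolsweep as w
from wolsweep.synthetic import GeneratorConfig, generate_study

study = generate_study(GeneratorConfig(seed=1))       # 253 wasps, truth known
dist = w.patristic_matrix(study.tree)
grid = w.threshold_grid(dist, n_steps=10)             # disabled + 10 thresholds
result = w.run_sweep(dist, study.records, study.design, grid)
print(result.best_wia_row()[["psc_id", "wia", "n_species"]])
sub = result.frame[result.frame.threshold_index == 0]  # no-purge rows
print(w.regress(sub, "psc_accuracy", "wia", transform="cube"))
```

prints (seed 1):

```
psc_id       2116.0
wia           204.0
n_species       9.0
RegressionResult(slope=78497.7..., intercept=..., adj_r_squared=0.6824,
                 f_statistic=17602.3, p_value=0.0, n=8192)
```

PSC 2116 is exactly the planted nine-species delimitation: the sweep
recovers it as the unique WIA maximum, predicting 204 of the 205 infected
individuals (one horizontal-transfer noise tip resists).  Across all 8192
delimitations, better species hypotheses give better strain predictions
(adjusted R² = 0.68 on cube-transformed accuracy), and against a
strain-shuffled null the real labels score far above chance (mean sweep
WIA 97.0 vs. 30.0; Welch *t* ≈ 396).

The same pipeline runs from files — your own newick tree and typing
table — via the CLI:

```bash
wolsweep simulate --seed 1 --out-dir fixtures/
wolsweep sweep --tree fixtures/tree.nwk --meta fixtures/meta.csv \
               --design fixtures/design.csv --steps 10 --null 1 --out results.csv
wolsweep eval --results results.csv --null-results results.null0.csv
wolsweep fecundity --grid 100 --out heatmaps.csv
```

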