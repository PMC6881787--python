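# rhizotrial

Statistical analysis of legume genotype × rhizobium strain (G<sub>L</sub> ×
G<sub>R</sub>) inoculation trials.

Symbiotic nitrogen fixation in grain legumes such as common bean
(*Phaseolus vulgaris* L.) depends on the specific pairing of host genotype
and rhizobium strain. Screening experiments cross a genotype panel with a
strain panel in replicated, blocked designs (modified Leonard jars for wide
screening, sand pots for confirmation with shoot-nitrogen measurement) and
ask two questions: which strains are broadly effective, and how much of the
performance is pairing-specific interaction rather than additive main
effects? This package provides the full analysis chain for such trials, for
agronomists and microbiologists running inoculant-screening programmes:

- **Symbiosis metrics** — relative symbiotic efficiency
  RSE = (SDW<sub>i</sub> − SDW<sub>neg</sub>)/SDW<sub>pos</sub> (also called
  relative shoot dry weight, RSDW), total shoot N = SDW·%N/100, nitrogen
  derived from the atmosphere by the N-difference method
  Ndfa = TSN<sub>in</sub> − TSN<sub>neg</sub>, and its relative form
  RNdfa = Ndfa/TSN<sub>pos</sub>, each normalised against the genotype's own
  uninoculated controls; plus min–max-scaled nodulation/fixation score
  matrices for heat-maps.
- **Factorial RCBD ANOVA** — exact closed-form sequential (type I)
  decomposition y<sub>ijk</sub> = μ + rep<sub>k</sub> + g<sub>j</sub> +
  s<sub>i</sub> + (gs)<sub>ij</sub> + ε<sub>ijk</sub> for balanced designs,
  and a group-contrast model (genepool, growth habit, origin) with
  genotypes nested in groups and expected-mean-squares F tests.
- **AMMI** — additive main effects and multiplicative interaction:
  Y<sub>ij</sub> = μ + α<sub>i</sub> + β<sub>j</sub> +
  Σ<sub>k</sub> λ<sub>k</sub> ξ<sub>ik</sub> η<sub>kj</sub> + ε<sub>ij</sub>,
  estimated by SVD of the double-centered cell-mean matrix (rows = strains,
  columns = genotypes), with Gollob axis degrees of freedom
  (g + e − 1 − 2k), axis F tests against the ANOVA residual, and
  symmetric-scaling biplot coordinates.
- **Synthetic trials** — a generator that emulates the jar (10 genotypes ×
  8 strains × 5 replicates + controls = 500 units) and pot (5 × 6 × 5 +
  controls = 200 units) designs with known additive effects, rank-t
  interaction, block effects and nod/fix phenotypes, so the entire chain is
  testable end to end.

Models are scikit-learn-style estimators (`FactorialAnova`, `GroupAnova`,
`AmmiModel`) with thin functional wrappers, plus a `rhizotrial` command-line
pipeline (`simulate` → `analyze` → `report`).

## Worked example

```python
import rhizotrial as rt

records = rt.simulate_trial(rt.jar_config(seed=11))     # 500-unit jar trial
derived = rt.add_derived_responses(records)             # adds rsdw
model = rt.FactorialAnova(response="rsdw").fit(derived)
print(model.table_.to_text())

ammi = rt.AmmiModel(n_axes=2, replicates=model.n_replicates_).fit(model.cell_means_)
print(ammi.f_tests(model.residual_ms_, model.residual_df_))
```

prints

```
Response: rsdw
Source                         DF          MS         F         p
Rep                             4     0.04431         -         -
Genotype                        9     0.02433     3.377 0.0005689  ***
Strain                          7        1.06   147.118 1.857e-95  ***
Genotype x Strain              63      0.0332     4.608 5.798e-20  ***
Residual                      316    0.007204         -         -

 axis  df     ss     ms       f      p
    1  15 1.5132 0.1009 14.0036 0.0000
    2  13 0.3792 0.0292  4.0492 0.0000
    3  11 0.1188 0.0108  1.4999 0.1300
    ...
```

Read: strain choice dominates relative shoot biomass (Strain MS far above
Genotype MS), but the genotype × strain interaction is highly significant
(F = 4.6 on 63 and 316 df), and the AMMI decomposition concentrates that
interaction on the first two axes (15 + 13 of the 63 interaction df, both
significant) — specific genotype–strain pairings matter beyond additive
performance. The seven axis df values 15, 13, 11, 9, 7, 5, 3 are fixed by
the 8 × 10 table shape; the axis SS always sum to the ANOVA interaction SS.

The same pipeline from the shell:

```sh
rhizotrial simulate --preset jar --seed 11 --out jar.csv
rhizotrial analyze --input jar.csv --outdir out/ --response rsdw
rhizotrial report --outdir out/
```

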