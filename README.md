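# acoscale

Ordinal confirmatory factor analysis and ant-colony short-form selection
for multi-domain clinical questionnaires.

## The problem

Dimensional assessment of personality-disorder severity rests on long
self-report questionnaires: here, a 97-item instrument measuring
personality functioning across four domains (Identity, Self-direction,
Empathy, Intimacy, two subscales each) on a 5-point ordinal scale, used to
separate adolescent patients with a personality disorder from healthy
controls. Two questions drive the analysis:

1. **Latent structure.** Is the item pool essentially unidimensional
   (one general severity factor), four correlated domains, a bifactor
   structure (general + orthogonal domain specifics), or a hierarchy
   (domain factors under a second-order severity factor)? Nine competing
   configurations are fitted to the polychoric correlation matrix and
   compared on CFI, RMSEA and SRMR, with ordinal alpha and hierarchical
   omega (ωH for the total score, ωHS per domain) quantifying how much
   reliable variance each scale retains.

2. **Screening short form.** A 20-item form (5 items per domain) is
   selected by **ant colony optimization**: virtual ants assemble
   candidate subsets with probability proportional to item "pheromone",
   each candidate is scored by a pheromone function

   φ-total = φ(fit) + φ(reliability) + φ(validity) ∈ (0, 3),

   where each φ is a logistic gate — fit from the CFI/RMSEA of a
   hierarchical CFA with **equal higher-order loadings**, reliability from
   the minimum domain omega and minimum loading, validity from the
   adjusted R² of the patient/control indicator regressed on the sum
   score — and the best candidate's items are reinforced while all
   pheromone evaporates. The winner is benchmarked against random
   quota-respecting subsets and evaluated clinically (Cohen's *d*,
   ROC/AUC, Youden-optimal cutoff with sensitivity/specificity and
   T-score).

Because clinical item-level data of this kind cannot be redistributed,
the package ships a synthetic-data generator that emulates the study
conditions (97 items, 4 domains, 5-point responses, a strong general
factor, 337 controls vs 96 patients shifted 2.1 SD on the severity
factor), so every stage is testable end to end.

Everything is computed in-package on top of numpy/scipy/pandas: two-step
polychoric estimation (with a vectorized Drezner–Wesolowsky/Genz
bivariate-normal CDF), least-squares CFA with analytic Jacobians and a
batched Gauss–Newton fitter fast enough to score ~200,000 candidate
subsets, closed-form omega coefficients via Schmid–Leiman residualization,
and exact-arithmetic Youden cutoff selection.

## Worked example

The numbered scripts under `analysis/` run the two studies on the default
synthetic cohort and write tables under `results/`:

```bash
python analysis/01_simulate.py    # 433 x 97 response table + scale map
python analysis/02_structure.py   # nine-model comparison + reliabilities
python analysis/03_shortform.py   # ant colony + clinical utility
python analysis/04_baseline.py    # search-space size + random benchmark
```

`02_structure.py` prints the model-comparison table (synthetic cohort,
seed 1):

```
model_id  factors  par  chi_square   CFI  RMSEA  SRMR classification  identified
       1        1  485     26494.2 0.881  0.106 0.115           poor        True
       2        2  486     20280.6 0.915  0.089 0.100           poor        True
       3        4  491      3547.0 1.000  0.000 0.042           good        True
       4        2  582      8614.0 0.977  0.046 0.065           good        True
       5        4  582      2942.3 1.000  0.000 0.038           good        True
      6a        2  487     20280.6 0.915  0.089 0.100           poor       False
      6b        2  486     20280.6 0.915  0.089 0.100           poor        True
      7a        4  489      3693.5 1.000  0.000 0.043           good        True
      7b        4  486      3914.6 1.000  0.000 0.044           good        True
```

`par` counts estimated parameters (4 thresholds per item plus structural
parameters), so e.g. the one-factor model has 97·4 + 97 = 485. Model 6a —
a second-order factor over only two first-order factors with free
higher-order loadings — is flagged **not identified** (only the product of
the two loadings enters the implied moments); its equality-constrained
variant 6b is the identified version of the same fit. The data were
generated from a four-domain hierarchy, and exactly the configurations
that nest it (3, 5, 7a, 7b) classify as `good`.

`03_shortform.py` then reports the optimized 20-item form:

```
selected 20 items after 79 iterations (1969 candidate evaluations)
fit: CFI=1.000 RMSEA=0.000 SRMR=0.041
reliability: min domain omega=0.828 min loading=0.595 ordinal alpha (total)=0.896
validity: adj R2=0.368  d=1.84  AUC=0.888 [0.843, 0.932]
cutoff: total score >= 28 (T-score 60) -> sensitivity 79.2%, specificity 85.2%

random-combination benchmark (1000 draws): CFI 1.000 (sd 0.001), adj R2 0.285 (sd 0.014)
```

The optimized form beats **every one of 1,000 random** quota-respecting
subsets on criterion validity (adjusted R² 0.368 vs 0.285 ± 0.014) while
keeping excellent fit — the signature result of pheromone-guided item
selection. The cutoff line is the clinical-utility readout: flagging
respondents with a sum score ≥ 28 catches 79% of patients at 85%
specificity.

A `acoscale` console command exposes the same steps
(`acoscale simulate|structure|shortform|baseline|all --config cfg.json`).

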