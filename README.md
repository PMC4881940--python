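# twinstage

Twin ACE variance decomposition across the stages of a behavioral
intervention: cohort simulation, preprocessing, maximum-likelihood twin
modeling, piecewise growth curves, and design power — as one tested
pipeline.

## The problem

A classical twin study contrasts monozygotic (MZ) pairs, who share all
segregating genes, with dizygotic (DZ) same-sex pairs, who share half on
average, to split the phenotypic variance of a trait into additive genetic
(A), shared environmental (C) and non-shared environmental (E) components.
Embedding a universal well-being intervention inside a twin cohort adds a
longitudinal question: when mean well-being rises in response to the
intervention, do the *same* genetic and environmental factors keep driving
individual differences, or do *new* influences arise?

The four-occasion design modeled here (baseline, end of a control phase,
end of the intervention phase, follow-up; weeks 1/4/7/10) answers this with
a triangular ("Cholesky") factor decomposition per component: factor *j*
loads only on stages *j..4*, so its diagonal loading is variance newly
arising at stage *j* (an **innovation**) and its sub-diagonal loadings are
variance **transmitted** to later stages. With loadings Λ stacked as a
lower-triangular 4×4 matrix per component, a pair's 8 stage scores have
covariance

```
within-twin  block:  Σ = Λa Λaᵀ + Λc Λcᵀ + Λe Λeᵀ
cross-twin   block:  r·Λa Λaᵀ + Λc Λcᵀ ,   r = 1 (MZ), 0.5 (DZ)
```

and the model is fit by two-group Gaussian maximum likelihood (optionally
full-information over partially observed pairs), with profile-likelihood
confidence intervals on the standardized contributions. The derived
*stage-specific proportion* — the diagonal contribution divided by the
summed contributions of a component at a stage — quantifies how much of,
say, the non-shared environmental influence at the intervention stage is
specific to that stage.

Mean response is modeled separately with a piecewise multilevel growth
model (occasions nested in individuals nested in pairs):

```
y = γ00 + γ10·time + γ20·time2 + u_pair + b0 + b1·time + b2·time2 + ε
time  = 0,1,2,3      time2 = 0,0,1,2
```

so γ20 is the additional per-occasion slope beginning with the
intervention. A Monte-Carlo module gives the power of the boundary-mixture
likelihood-ratio test for heritability at any MZ/DZ design size.

No individual-level data from the motivating study are distributed;
everything runs on simulated cohorts whose generating parameters are the
published standardized component tables (square-root loadings), so the
pipeline's acceptance surface is parameter recovery plus the worked
derived statistics.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_twin_models.py
python analysis/04_growth_models.py
python analysis/05_power.py
```

`01` simulates 750 individuals (167 MZ + 208 DZ pairs, ages ~16.6 ± 0.5)
with occasion-level attrition; `02` writes the baseline-standardized
composites and the twin-analysis table (van der Waerden rank-normalized
per stage, then age/sex-residualized). `03` prints, for this seed, MZ
intraclass correlations around .35–.49 against DZ correlations of
.15–.34, and the standardized Cholesky tables, e.g. for well-being an E
innovation share at the intervention stage of

```
E innovation share at the intervention stage: 37%
```

(the generating structure's value is .20/(.22+.06+.20) = 42%; a 375-pair
cohort estimates it with sampling noise of this order). `04` prints the
piecewise growth fit for well-being:

```
          estimate      se       t    df       p
gamma_00   -0.0095  0.0418 -0.2281  2954  0.8196
gamma_10   -0.0021  0.0189 -0.1094  2954  0.9129
gamma_20    0.0616  0.0238  2.5876  2954  0.0097
piecewise preferred over unconditional: LRT=18.0 (df=4, p=0.0012)
```

— a flat control phase (γ10 ≈ 0) and a +0.06 SD per-occasion rise after
the intervention begins (generating value 0.07), with the piecewise model
preferred over the unconditional one. `05` estimates ~71% power for
detecting a² = 0.40 (c² = 0) at the study size, rising past 80% with a
modest shared-environment variance or a larger sample.

The same chain runs config-driven from a single command:

```bash
twinstage run-all --config config.example.yaml --out results/run
```

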