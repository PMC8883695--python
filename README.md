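# causalfpr

**How likely is an analyst to reject a *true* causal model — and how much
bias does that mistake inject into the causal effect estimates?**

`causalfpr` quantifies the *causal false-positive risk* for the two
elementary building blocks of epidemiological causal diagrams, the
confounder and the collider, in linear Gaussian Markovian structural causal
models (SCMs).  It is aimed at biostatisticians and methodologists studying
model validation in causal inference from observational data.

## The problem

A structural causal model over observables with a DAG *G* entails *testable
implications*: partial regression coefficients β<sub>YX|Z</sub> that must
vanish (when Z d-separates X from Y in G) or must not vanish (when no set
does).  A careful analyst checks these implications before computing causal
effects and edits the DAG when the data contradict them.  But hypothesis
tests err: even when the data really come from *G*, some implication will
occasionally be flagged, the true DAG will be modified, and the causal
estimands — built from the wrong graph — become biased.

The package simulates exactly this analyst.  Per replicate:

1. **Simulate** n joint samples from the true SCM
   (confounder: C = U<sub>C</sub>, X = βC + U<sub>X</sub>,
   Y = αX + γC + U<sub>Y</sub>;
   collider: C = αX + βW + U<sub>C</sub>, Y = γC + U<sub>Y</sub>;
   all errors standard normal).
2. **Test** every implication with the Bayes factor BF<sub>01</sub> for
   H<sub>0</sub>: β = 0 vs H<sub>1</sub>: β ≠ 0 at threshold 1, computed in
   closed form as the Savage–Dickey density ratio of a conjugate Bayesian
   ridge regression with N(0, 1) slope priors.
   Confounder implications: β<sub>YX|C</sub> ≠ 0, β<sub>YC|X</sub> ≠ 0,
   β<sub>XC</sub> ≠ 0.  Collider implications: β<sub>YX|C</sub> = 0,
   β<sub>YW|C</sub> = 0, β<sub>WX</sub> = 0, β<sub>CW|{X,Y}</sub> ≠ 0,
   β<sub>CX|{W,Y}</sub> ≠ 0, β<sub>YC|{W,X}</sub> ≠ 0.
3. **Edit** the DAG for each violated implication (delete the questioned
   arrow, or add the domain-knowledge-directed arrow for the collider's
   zero-implications).
4. **Recompute** the average, direct and indirect effects of treatment X on
   outcome Y on the modified DAG: ACE = Σ over directed X→Y paths of the
   product of edge coefficients, each edge identified by its minimal
   single-door adjustment set; DE = the direct edge's coefficient (0 when
   absent); IE = ACE − DE.

Across replicates this yields the causal false-positive risk (fraction of
replicates rejecting the true model) and the Monte Carlo drift of the
ACE/DE/IE estimates away from their true path-tracing values.

## Worked example

```
causalfpr run --motif confounder --alpha 0.25 --beta 1 --gamma 1 \
              --n 100 --reps 2000 --seed 7 --out results
```

writes `results/results.csv`, whose single row reads

```
     motif  alpha  beta  gamma   n  reps   fpr  mean_ace   se_ace  true_ace
confounder   0.25   1.0    1.0 100  2000 0.312  0.214595 0.003477      0.25
```

Reading: with very strong balanced confounding (β = γ = 1) and 100 samples
per variable, 31% of replicates reject the true confounder model (`fpr`),
almost always by deleting the treatment arrow X→Y after its implication
β<sub>YX|C</sub> ≠ 0 fails the Bayes-factor check.  Those replicates set
the ACE estimate to 0, dragging the Monte Carlo mean to ≈ 0.215 — roughly
15–20% below the true ACE = α = 0.25 — even though each surviving
replicate's C-adjusted estimator is consistent.

Ad-hoc graph queries use the same machinery:

```
$ causalfpr check W X --given C --motif collider
W and X given {C}: not d-separated
minimal backdoor set for (W, X): []
```

The full published grids (16 confounder and 21 collider settings) are
available via `causalfpr run --registry confounder --n-grid 10,20,...,100`
and `causalfpr registry-list`.  The library API mirrors the CLI:
`simulate`, `bf01`, `evaluate_implications`, `apply_edits`,
`estimand_plan`, `estimate_effects`, `run_study`.

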