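# pedvar

Partitioning phenotypic variance into genetic and nongenetic components
with **multiple-matrix animal models**.

Quantitative geneticists use the animal model — a linear mixed model whose
genetic random effect carries the pedigree-derived additive relatedness
matrix **A** as its covariance structure — to estimate additive genetic
variance V_a and heritability h² = V_a / V_p. But genes are not the only
reason relatives resemble one another: shared environments, transmissible
epigenetic states, and social interactions all create structured phenotypic
similarity, and when relatives also share those, V_a is inflated. The
remedy is to give each nongenetic source its own random effect with its own
similarity matrix, exactly as A serves the genetic term:

```
y = Xβ + Σ_k Z_k u_k + r,    u_k ~ N(0, S_k V_k),    r ~ N(0, I V_r)
```

where S_k is A for genetic terms (direct or maternal), an environmental
similarity matrix S_n = 1 − d/max(d) over scaled environmental measures, an
epiallelic similarity matrix S_epi of the same form over methylation
counts, or a social-network matrix S_c = 1/(1 + g) over geodesic distances
g. A term's incidence matrix Z_k either points each record at itself
(direct effects) or at its mother (maternal effects, so full and maternal
half sibs load on the same level).

`pedvar` provides, in one package:

* a **population simulator** with known ground truth: ten semelparous
  generations of breeding pairs (with 10% extra-pair events) on a 50×50
  grid, spatially autocorrelated environmental fields (covariance
  e^(−φd), φ = 0.15), lognormal maternal dispersal, environment-responsive
  and maternally transmissible epialleles, a distance-structured social
  network, and three phenotypes composed from unit-variance components
  (y1 = a+n+r, y2 = a+n+Mn+r, y3 = a+Ma+n+Mn+r);
* **matrix builders** for A (tabular method with inbreeding), S_n, S_epi,
  S_c, including positive-semidefinite repair by eigenvalue clipping;
* an **AI-REML fitter** for arbitrary combinations of (matrix, carrier)
  random terms, with standard errors from the average-information matrix,
  delta-method heritabilities, Wald and boundary-corrected
  likelihood-ratio tests;
* a **pipeline** that runs the full 13-model comparison suite and a
  data-requirements (phenotype subsampling) study, plus a thin CLI
  (`pedvar simulate | matrices | fit | suite | subsample`).

## A worked example

`examples/03_fit_animal_model.py` simulates a 6-generation population in
which relatives share autocorrelated environments, then fits tail-fin
colour (y1 = a + n + r, all components unit variance) two ways:

```
naive model (genetic + residual):
    term  estimate       se   p_wald
additive  1.685687 0.355388 0.000001
residual  1.494340 0.207006      NaN
h2 = 0.530 (SE 0.081)  <- inflated, absorbs environmental variance

true model (genetic + environmental + residual):
    term  estimate       se   p_wald
additive  1.064390 0.238741 0.000004
     env  1.018429 0.312481 0.000559
residual  0.889965 0.142073      NaN
h2 = 0.358 (SE 0.074)  <- close to the simulated 1/3

LRT for the environmental term: statistic 206.8, boundary-corrected p = 3.40e-47
```

The naive fit attributes the shared-environment similarity to genes
(V̂_a ≈ 1.7 against a simulated 1.0). Adding the environmental similarity
matrix as a second random term recovers all three components near 1 and
the heritability near its expected 1/3. The other example scripts cover
the simulator, the four matrices, the 13-model suite, and the subsampling
study, each printing what it computes.

```python
import pedvar as pv

pop = pv.simulate_population(pv.SimulationConfig(), seed=1)
mats = pv.build_all_matrices(pop)
fit = pv.fit_model(pop, mats, "y1",
                   (pv.RandomTerm("additive", "A"), pv.RandomTerm("env", "Sn")))
h2, se = pv.heritability(fit)
```

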