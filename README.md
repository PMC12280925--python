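# allomod

Quantitative analysis for structure-based discovery of GPCR positive
allosteric modulators (PAMs), built around the A1 adenosine receptor
extrahelical-site campaign workflow:

* **Allosteric pharmacology.** Global nonlinear fits of whole-cell
  radioligand interaction binding to the allosteric ternary complex model
  (ATCM), and of cAMP concentration–response families to the operational
  model of allosterism, yielding the standard log-scale estimates:
  modulator affinity pK_B, binding cooperativity logα, functional
  cooperativity composite logαβ, and allosteric agonism logτ_B. One-site
  displacement fits, the Cheng–Prusoff K_I conversion, three-parameter Hill
  fits, and one-sample-t hit calling (ΔpK_I, ΔpEC50) round out the assay
  stack.
* **Virtual-screen enrichment.** Stepwise ROC curves and the adjusted
  logAUC early-recognition metric over per-snapshot docking scores,
  best-energy ensemble aggregation across MD snapshots, top-snapshot
  selection, and DUD-E-style property-matched decoy assignment.
* **Screening-funnel triage.** MW/LogP library windows, top-fraction rank
  cuts, the S246/L276 hydrogen-bond pose filter, ECFP4 Tanimoto leader
  clustering with best-scoring representatives, and substructure/similarity
  analog searches.
* **Synthetic data.** Seeded generators emulate every input — binding and
  functional interaction experiments, screen replicate tables, correlated
  snapshot score libraries, and template-generated molecule/pose tables —
  so the whole pipeline runs and is tested fully offline.

## The models

Interaction binding (radioligand A, orthosteric agonist I, modulator B):

    Y = Bmax·[A] / ([A] + (K_A·K_B/(α_A[B]+K_B)) · (1 + [I]/K_I + [B]/K_B + α_I[I][B]/(K_I·K_B)))

Functional modulation (operational model of allosterism):

    E = E_m·(τ_A[A](K_B+αβ[B]) + τ_B[B]K_A)^n /
        (([A]K_B + K_A·K_B + [B]K_A + α[A][B])^n + (τ_A[A](K_B+αβ[B]) + τ_B[B]K_A)^n)

Constants are fitted in log10 space (pK, logα, logτ) with box bounds and a
seeded Latin-hypercube multistart; functional fits constrain pK_A, pK_B (and
by default logα) to the binding estimates and report the composite logαβ.

Enrichment uses the adjusted logAUC: the area under the ROC curve against
log10(FPR) from λ = 0.001 to 1, normalized to percent, minus the
random-ranking expectation (≈14.46%), so random screens score ~0 and a
perfect screen ≈85.5.

## Worked example

```
$ python analysis/01_simulate_assays.py   # seeded synthetic assay tables
$ python analysis/02_fit_pharmacology.py
compound1: pKB 5.10 (true 5.18), logα 2.16 (true 2.09), logαβ 0.84 (true 0.78), logτ_B 0.60 (true 0.56)
compound12: pKB 4.64 (true 4.63), logα 0.96 (true 0.99), logαβ 0.67 (true 0.68), logτ_B -0.66 (true -0.65)
compound54: pKB 5.19 (true 5.15), logα 1.13 (true 1.15), logαβ 0.84 (true 0.84), logτ_B -0.39 (true -0.37)
compound56: pKB 4.99 (true 5.00), logα 1.31 (true 1.30), logαβ 0.93 (true 0.92), logτ_B -0.07 (true -0.07)
```

Each line is one simulated study (4 replicate experiments, 5% proportional
noise) refit globally: the recovered modulator affinity (pK_B), binding
cooperativity with the agonist (logα), functional cooperativity (logαβ) and
allosteric agonism (logτ_B) sit within fit error of the generating truth —
e.g. compound 12 is read back as a ~25 µM-affinity PAM with ~10-fold binding
cooperativity and negligible allosteric agonism. The remaining drivers run
the screen hit-calling (`03`, prints the 11.5% hit rate for 3 hits of 26
tested and the corrected 3.8% for the single novel scaffold), the snapshot
enrichment protocol (`04`), and the triage funnel (`05`), writing tables
under `results/`.

The same operations are available as a CLI (`allomod simulate|fit-binding|
fit-function|screen-summary|enrich|triage|run`); see `--help`.

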