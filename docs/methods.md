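# Methods

## Scope and shape

The package is organised as an analysis project: the numbered drivers under
`analysis/` narrate the workflow (simulate assays → fit pharmacology → call
screen hits → evaluate enrichment → run the triage funnel), while all
computation lives in the `allomod` library so tests and the acceptance
script exercise the same code paths.

## Allosteric ternary complex model (interaction binding)

Specific radioligand binding over an (agonist × modulator) grid at fixed
tracer concentration is modelled as

Y = Bmax·[A] / ([A] + (K_A·K_B/(α_A[B]+K_B))·(1 + [I]/K_I + [B]/K_B + α_I[I][B]/(K_I·K_B)))

with A the antagonist radioligand, I the orthosteric agonist, B the
modulator. The model assumes equilibrium, a single allosteric site, and
constant cooperativities (α_A with the radioligand, α_I with the agonist;
α > 1 positive, α < 1 negative, α = 1 neutral). At B = 0 it reduces exactly
to two-ligand competition, and with α_A = α_I = 1 it is independent of B —
both reductions are enforced as machine-precision tests.

**Fitting.** All curves of an experiment series are fitted globally: pK_B,
pK_I, logα_I, logα_A and Bmax are shared across replicates; the radioligand
affinity pK_A must be supplied fixed because the interaction design cannot
identify it (in practice it comes from saturation binding). α_A is free by
default — PAMs of this series show a modest *decrease* in antagonist
radioligand binding, i.e. α_A slightly below 1 — and can be fixed to 1 via
`fixed={"log_alpha_A": 0}`.

Equilibrium constants and cooperativities are parameterized in log10 space
(pK ∈ [3, 12], logα/logτ ∈ [−4, 4]; Bmax bounded by a multiple of the data
range), which matches the scale of the reported estimates and stabilizes
the optimization. Optimization is trust-region-reflective least squares
(`scipy.optimize.least_squares`, ftol = xtol = 1e−10) from 20 seeded
Latin-hypercube starts plus one heuristic start; the winner is the lowest
objective with ties broken by start index. Standard errors are the usual
Gauss–Newton asymptotics, s²(JᵀJ)⁻¹. Fits that finish pinned to a box bound
return `converged=False` with a reason code (`boundary`) instead of
raising; flat displacement/response curves are flagged `flat_curve`.

## Operational model of allosterism (functional data)

cAMP concentration–response families are fitted to

E = E_m·(τ_A[A](K_B+αβ[B]) + τ_B[B]K_A)^n / (([A]K_B + K_A·K_B + [B]K_A + α[A][B])^n + (τ_A[A](K_B+αβ[B]) + τ_B[B]K_A)^n)

where τ_A, τ_B are operational efficacies, β scales agonist efficacy and n
is the transducer slope. pK_A and pK_B are constrained to the binding
estimates; n is fixed at 1 by default (overridable through `fixed`), and by
default logα is also fixed to the binding cooperativity so the free logβ
carries the reported composite logαβ = logα + logβ. These two conventions
are the package's declared resolution of choices the assay literature often
leaves implicit; both are configurable. Responses are on the
forskolin-anchored percent scale (forskolin reference → 0, buffer → 100;
`normalize_camp`).

Raw potency is summarized per curve with a three-parameter Hill fit (basal,
E_max, pEC50, unit slope) and competition binding with the one-site
mass-action curve plus Cheng–Prusoff conversion K_I = IC50/(1 + [A]/K_D);
the radioligand K_D is a required user input for the conversion.

## Screen statistics

For each screened compound, ΔpK_I and ΔpEC50 are means of matched
replicate differences (treated − control); each endpoint is tested against
zero with a two-sided one-sample t test. A hit requires p < α (default
0.05) on *both* endpoints with positive means — enhancement only, since the
campaign calls PAMs, not NAMs. Hit rate is 100 × hits/tested reported to
one decimal. Zero-variance Δ vectors give an undefined t (p = NaN) and can
never be hits.

## Enrichment metrics

ROC curves are stepwise over the energy-sorted library (lower score =
better; a flag inverts). Tied scores advance actives and negatives
simultaneously, tracing a diagonal segment, so the AUC equals the
normalized Mann–Whitney U with ties counted half (asserted against a
pair-counting oracle and scikit-learn in tests).

Adjusted logAUC integrates TPR against log10(FPR) from λ = 0.001 to 1
exactly over the piecewise-linear curve, normalizes by log10(1/λ) to
percent, and subtracts the random-ranking expectation
100·(1−λ)/(ln10·log10(1/λ)) ≈ 14.462%. FPR below λ contributes nothing; the
first segment is clamped to λ. Random rankings therefore average ~0 and a
perfect classifier scores ≈85.54. λ is configurable.

Snapshot ensembles combine by each molecule's best (minimum) energy across
the snapshots where it docked; molecules docked nowhere are excluded with a
logged count (a strict mode ranking them last was considered and rejected
as inconsistent with docking practice — sparse snapshots would be
penalized). Snapshot selection ranks snapshots by single-structure adjusted
logAUC, ties broken by id.

Decoy matching follows the DUD-E idea at desk scale: pool molecules with
ECFP4 Tanimoto ≥ 0.35 to any active are excluded as topological lookalikes,
then each active takes its n nearest available pool molecules (default 40)
by Euclidean distance in pool-z-scored property space (MW, cLogP, HBD, HBA,
net charge, rotatable bonds), without reuse. The 0.35 threshold and the
z-scored distance are declared choices; published decoy generators bin
properties instead, which matters only at database scale.

## Triage funnel

Library windows: fragment = MW < 250 Da, lead-like = 250 ≤ MW < 350 Da,
both with 2.5 ≤ LogP ≤ 4.5 inclusive. The MW = 250 boundary is assigned to
lead-like (the windows as usually quoted leave it ambiguous); LogP is
inclusive on both ends. Rank cut keeps ceil(f·N) best molecules (default
f = 0.005). The hydrogen-bond filter retains a molecule when its best pose
has, at *each* required site (S246 side chain, L276 backbone carbonyl), at
least one contact with heavy-atom distance ≤ 3.5 Å and angle ≥ 120° —
declared geometric defaults, since pose filters are usually applied with
unstated criteria. Leader clustering greedily seeds clusters from the
best-scoring unassigned molecule at Tanimoto ≥ 0.5 (ECFP4-like radius-2,
2048-bit fingerprints), making representatives pairwise dissimilar by
construction. All ties break on (score, molecule_id), so every funnel run
is bit-reproducible. The final visual-inspection stage of a real campaign
is out of scope; the funnel emits the ranked candidate list that would feed
it.

## Synthetic data

Generators are pure functions of (design, seed) via
`numpy.random.default_rng`. Assay noise is proportional Gaussian,
y = ŷ(1 + ε), ε ~ N(0, cv) with cv = 0.05 by default (an additive
component is available); real assay noise structure is unknown, and 5% CV
is a realistic figure for replicate-averaged radioligand and cAMP data.
Default designs copy the assay conditions: binding agonist ladder 0.3 nM–10
µM (half-log), functional ladder 0.01 nM–100 µM, modulator {0, 3, 10, 30}
µM, ~1 nM radioligand, n = 4 replicates, with agonist-free points included
so α_A and τ_B are observable.

Reference truths (`allomod.presets`) use the reported estimates: pK_B/logα
of 5.18/2.09 (compound 1), 4.63/0.99 (12), 5.15/1.15 (54), logα 1.30 (56);
logαβ/logτ_B of 0.78/0.56 (1), 0.68/−0.65 (12), 0.84/−0.37 (54),
0.92/−0.07 (56). Constants the assays do not report alongside them are
package defaults, chosen once: radioligand pK_A 9.0 (~1 nM K_D tracer used
at ~1 nM), agonist pK_I 6.5, Bmax 200 (placing the modulator- and
agonist-free control at 100%), logα_A −0.15 (the observed modest negative
radioligand cooperativity), operational E_m 100, logτ_A 1.0 (full agonist),
n = 1, and pK_B 5.0 for compound 56 (micromolar, in line with its series).

Score libraries are equicorrelated Gaussians (default ρ = 0.8 across
snapshots) with actives shifted toward better energies; they are
statistical stand-ins for docking output, not physics. Molecule tables are
template-generated SMILES (alkylated 2-aminothiazole, naphthalene,
chloroarene and aroyl-thiazole scaffolds) with rdkit-computed properties
spanning both library windows, Gaussian dock scores, and pose-contact
records satisfying the hydrogen-bond predicate with a controllable
probability.

**What passing tests do and do not show.** Recovery tests demonstrate that
the estimators are unbiased and well-identified *under the generating
models* at the assay design and noise level; they cannot validate the
models against real receptor behaviour (cooperative binding beyond the
ternary complex, non-proportional noise, plate effects, compound
solubility limits). Enrichment and funnel results on synthetic libraries
check the metrics and algorithms, not docking accuracy.

## Problem sizes

Recovery studies use 20 seeded studies × 4 replicates per compound
(~0.3 s per global fit), the permutation null 1,000 relabelings of a
1,550-molecule library, and null calibration 1,000 simulated compounds —
sizes at which the Monte-Carlo error of every reported mean is well below
the assay-scale differences of interest while the full suite stays fast.

## Known limitations

* Equilibrium models only: no kinetic (non-equilibrium) binding, Schild
  analysis, or biased-signaling quantification; no Bayesian fitting.
* Docking scores, poses, and contact geometries are consumed as inputs;
  the package neither docks nor post-processes 3D coordinates.
* The decoy matcher is a nearest-neighbour formulation of property
  matching, appropriate for benchmark-sized libraries rather than
  database-scale decoy generation.
* Standard errors are asymptotic; for the shallow, correlated parameters of
  operational fits (e.g. E_m vs τ_A) profile-likelihood intervals would be
  more faithful near bounds.
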