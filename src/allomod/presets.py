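"""Reference parameter bundles for the characterized A1R PAMs.

The binding (ATCM) and functional (operational) estimates reported for the
reference PAM MIPS521 ("compound1"), the virtual-screening hit "compound12"
and the optimized analogs "compound54"/"compound56" serve as ground truths
for the synthetic-data generators and recovery studies.

Quantities the assays report directly: pK_B, logα (binding cooperativity
with the agonist), logαβ (functional composite) and logτ_B. Assay-level
constants not reported alongside them — the radioligand affinity, agonist
affinity/efficacy, B_max, and the modest negative radioligand cooperativity
(α_A < 1) — are package defaults chosen to match typical whole-cell
[3H]DPCPX / cAMP assay behaviour (see docs/methods.md). The compound-56
allosteric affinity is likewise a package default at the micromolar level of
its series.
"""

from __future__ import annotations

from allomod.datatypes import ATCMParams, OperationalParams

#: [3H]DPCPX affinity (-log10 M); ~1 nM K_D, used at ~1 nM
RADIOLIGAND_PKA = 9.0
#: NECA competition-binding affinity (-log10 M)
AGONIST_PKI = 6.5
#: maximal specific binding; with ~1 nM tracer at K_D the B=I=0 control sits at 100%
BMAX = 200.0
#: modest negative cooperativity of PAMs with the antagonist radioligand
LOG_ALPHA_A = -0.15

#: operational-model system maximum and agonist efficacy (full agonist)
EM = 100.0
LOG_TAU_A = 1.0
#: NECA functional affinity (constrained to the binding estimate)
FUNCTIONAL_PKA = AGONIST_PKI
#: compound-56 allosteric affinity default (micromolar, in line with its series)
PKB_56 = 5.0

_BINDING = {
    # compound: (pKB, log_alpha_I)
    "compound1": (5.18, 2.09),
    "compound12": (4.63, 0.99),
    "compound54": (5.15, 1.15),
    "compound56": (PKB_56, 1.30),
}

_FUNCTIONAL = {
    # compound: (log_alphabeta, log_tau_B)
    "compound1": (0.78, 0.56),
    "compound12": (0.68, -0.65),
    "compound54": (0.84, -0.37),
    "compound56": (0.92, -0.07),
}

COMPOUNDS = tuple(_BINDING)


def atcm_truth(compound: str) -> ATCMParams:
    """ATCM generating truth for a reference compound."""

    pkb, log_alpha_i = _BINDING[compound]
    return ATCMParams(
        bmax=BMAX,
        pKA=RADIOLIGAND_PKA,
        pKB=pkb,
        pKI=AGONIST_PKI,
        log_alpha_A=LOG_ALPHA_A,
        log_alpha_I=log_alpha_i,
    )


def operational_truth(compound: str) -> OperationalParams:
    """Operational-model generating truth for a reference compound.

    The binding cooperativity α is shared with the ATCM bundle and the
    efficacy-modulation factor β carries the remainder of the reported
    functional composite: logβ = logαβ − logα.
    """

    pkb, log_alpha = _BINDING[compound]
    log_alphabeta, log_tau_b = _FUNCTIONAL[compound]
    return OperationalParams(
        em=EM,
        pKA=FUNCTIONAL_PKA,
        pKB=pkb,
        log_tau_A=LOG_TAU_A,
        log_tau_B=log_tau_b,
        log_alpha=log_alpha,
        log_beta=log_alphabeta - log_alpha,
        n=1.0,
    )
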