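"""Staged models of TNFα/EGF signalling in HT-29 colon carcinoma cells.

The network is built in the order a modeller would grow it against
time-course data:

* ``basic``        — TNFα activates its receptor, which directly activates
  JNK1 and MK2; with no inactivating processes the responses saturate.
* ``feedback``     — adds constitutive phosphatases and a delayed
  receptor-internalisation negative feedback (both are needed to turn the
  saturating responses into the observed transient peaks).
* ``late``         — adds IKK, slow autocrine IL-1 secretion, and the
  Casp8 -> Casp3 apoptotic arm (the late response).
* ``separate_tnf`` / ``separate_egf`` — the two full pathways in
  isolation (TNFR -> MEKK1 -> JNK1/p38/MK2/IKK; EGFR -> Ras -> Raf ->
  MEK -> ERK).
* ``merged``       — both pathways plus the autocrine crosstalk: TNFR
  triggers rapid TGFα release, TGFα activates EGFR, EGFR drives late
  IL-1α secretion, and IL-1ra (downstream of TNFR) antagonises the IL-1
  receptor.  In this variant TGFα alone suffices for IL-1α — the defect
  that motivates the first hypothesis.
* ``hyp1``         — IL-1α expression is rewired through the AP-1
  transcription factor: JNK1 -> c-Jun, ERK -> c-Fos, and an AND gate
  (c-Jun AND c-Fos) -> AP-1 -> IL-1α.  TGFα alone can no longer induce
  IL-1α because the JNK1 branch stays silent.
* ``final``        — additionally makes MEKK1 activation require both the
  TNF branch and Ras (an AND gate), and adds the EGFR-blocking antibody
  C225 as an ordinary always-active node with an inhibition edge onto
  EGFR.  Under TNFα + C225, Ras stays off, so JNK1 and MK2 stay silent.

All rate constants are per minute (``time_unit = "min"``) and are this
package's own tuning against the qualitative behaviours above; the C225
inhibition constant is deliberately much larger than the TGFα->EGFR
activation constant so that the blocked receptor's activity is pinned to
a duty cycle too small for Ras to take even a single level step within
the two-hour observation window.
"""

from __future__ import annotations

from ..netmodel import ACTIVATION, AND, INHIBITION, Network, S2_REACTANT_SUBSTRATE

TNF_EGF_VARIANTS = (
    "basic",
    "feedback",
    "late",
    "separate_tnf",
    "separate_egf",
    "merged",
    "hyp1",
    "final",
)

#: Reference stimulus dose (ng/ml): a dose of X maps to the initial
#: activity fraction min(1, X / REFERENCE_DOSE) of the stimulus node.
REFERENCE_DOSE = 100.0


def dose_fraction(dose: float, reference: float = REFERENCE_DOSE) -> float:
    """Linear dose -> initial-activity map, saturating at the reference."""
    if dose < 0:
        raise ValueError(f"dose must be non-negative, got {dose}")
    return min(1.0, dose / reference)


def with_stimulus(network: Network, fractions: dict[str, float]) -> Network:
    """Set stimulus nodes' initial activity fractions (0 for all others
    is the fixtures' default, so only the treated ligands need listing)."""
    out = network
    for name, frac in fractions.items():
        out = out.set_initial_fraction(name, frac)
    return out


def _act(net: Network, src, tgt: str, k: float, scenario=S2_REACTANT_SUBSTRATE) -> Network:
    return net.add_interaction(src, tgt, ACTIVATION, scenario, k=k)

def _inh(net: Network, src, tgt: str, k: float, scenario=S2_REACTANT_SUBSTRATE) -> Network:
    return net.add_interaction(src, tgt, INHIBITION, scenario, k=k)


def build_tnf_egf(variant: str = "final") -> Network:
    """Build the requested construction stage of the TNFα/EGF model.

    Stimulus nodes (TNFa, EGF, TGFa, C225 where present) start inactive;
    apply doses with :func:`with_stimulus` / :func:`dose_fraction`.
    """
    if variant not in TNF_EGF_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {TNF_EGF_VARIANTS}")

    net = Network(time_unit="min")

    def node(name: str, initial: int = 0) -> None:
        nonlocal net
        net = net.add_node(name, levels=100, initial_level=initial)

    # --- stage: basic (Fig-8-style direct activation) ---------------------
    if variant in ("basic", "feedback", "late"):
        node("TNFa")
        node("TNFR")
        node("JNK1")
        node("MK2")
        net = _act(net, "TNFa", "TNFR", 0.5)
        net = _act(net, "TNFR", "JNK1", 0.5)
        net = _act(net, "TNFR", "MK2", 0.5)
        if variant == "basic":
            return net
        # inactivating phosphatases + delayed receptor internalisation;
        # either alone cannot produce the observed transient peaks
        node("PP", initial=100)
        node("TNFR_int")
        net = _inh(net, "PP", "JNK1", 0.15)
        net = _inh(net, "PP", "MK2", 0.15)
        net = _act(net, "TNFR", "TNFR_int", 0.03)
        net = _inh(net, "TNFR_int", "TNFR", 3.0)
        if variant == "feedback":
            return net
        node("IKK")
        node("IL1")
        node("Casp8")
        node("Casp3")
        net = _act(net, "TNFR", "IKK", 0.2)
        net = _inh(net, "PP", "IKK", 0.15)
        net = _act(net, "TNFR", "IL1", 0.01)  # slow autocrine secretion
        net = _act(net, "IL1", "JNK1", 0.1)
        net = _act(net, "IL1", "MK2", 0.1)
        net = _act(net, "TNFR", "Casp8", 0.01)
        net = _act(net, "Casp8", "Casp3", 0.02)
        return net

    # --- full pathways ----------------------------------------------------
    tnf_side = variant in ("separate_tnf", "merged", "hyp1", "final")
    egf_side = variant in ("separate_egf", "merged", "hyp1", "final")
    crosstalk = variant in ("merged", "hyp1", "final")

    node("PP", initial=100)  # constitutive phosphatase pool

    if tnf_side:
        for n in ("TNFa", "TNFR", "TNFR_int", "MEKK1", "JNK1", "p38", "MK2", "IKK", "Casp8", "Casp3"):
            node(n)
        net = _act(net, "TNFa", "TNFR", 0.5)
        net = _act(net, "TNFR", "TNFR_int", 0.03)
        net = _inh(net, "TNFR_int", "TNFR", 3.0)
        if variant != "final":
            net = _act(net, "TNFR", "MEKK1", 0.2)
        net = _act(net, "MEKK1", "JNK1", 0.5)
        net = _act(net, "MEKK1", "p38", 0.5)
        net = _act(net, "p38", "MK2", 0.5)
        net = _act(net, "TNFR", "IKK", 0.2)
        net = _act(net, "TNFR", "Casp8", 0.01)
        net = _act(net, "Casp8", "Casp3", 0.02)
        for n in ("MEKK1", "JNK1", "p38", "MK2", "IKK"):
            net = _inh(net, "PP", n, 0.15)

    if egf_side:
        for n in ("EGF", "EGFR", "Ras", "Raf", "MEK", "ERK"):
            node(n)
        net = _act(net, "EGF", "EGFR", 0.5)
        net = _act(net, "EGFR", "Ras", 0.05)
        net = _act(net, "Ras", "Raf", 0.2)
        net = _act(net, "Raf", "MEK", 0.2)
        net = _act(net, "MEK", "ERK", 0.2)
        net = _inh(net, "PP", "EGFR", 0.02)
        for n in ("Ras", "Raf", "MEK", "ERK"):
            net = _inh(net, "PP", n, 0.05)

    if crosstalk:
        for n in ("TGFa", "IL-1a", "IL-1ra", "IL1R"):
            node(n)
        net = _act(net, "TNFR", "TGFa", 0.08)  # rapid TGFα release
        net = _inh(net, "PP", "TGFa", 0.01)
        net = _act(net, "TGFa", "EGFR", 0.05)
        net = _act(net, "IL-1a", "IL1R", 0.1)
        net = _act(net, "IL1R", "MEKK1", 0.2)  # late autocrine reactivation
        net = _act(net, "TNFR", "IL-1ra", 0.01)
        net = _inh(net, "IL-1ra", "IL1R", 0.2)
        if variant == "merged":
            # late IL-1α secretion directly downstream of EGFR: the stage
            # at which TGFα alone (wrongly) suffices for IL-1α
            net = _act(net, "EGFR", "IL-1a", 0.004)

    if variant in ("hyp1", "final"):
        for n in ("c-Jun", "c-Fos", "AP-1"):
            node(n)
        net = _act(net, "JNK1", "c-Jun", 0.1)
        net = _act(net, "ERK", "c-Fos", 0.1)
        net = net.add_interaction(("c-Jun", "c-Fos"), "AP-1", ACTIVATION, AND, k=0.2)
        net = _act(net, "AP-1", "IL-1a", 0.01)
        for n in ("c-Jun", "c-Fos", "AP-1"):
            net = _inh(net, "PP", n, 0.02)

    if variant == "final":
        # MEKK1 needs both the TNF branch and Ras; C225 blocks EGFR
        net = net.add_interaction(("TNFR", "Ras"), "MEKK1", ACTIVATION, AND, k=0.5)
        node("C225")
        net = _inh(net, "C225", "EGFR", 60.0)

    return net
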