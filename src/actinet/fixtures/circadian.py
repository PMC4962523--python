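"""Drosophila circadian-clock model with a repressilator day/night driver.

Topology (time unit: hours; lower-case names are mRNAs, upper-case are
proteins; every node carries a negative self-loop so that levels decay
when activating inputs are absent):

* ``BASAL`` — constitutive production machinery, pinned fully active by a
  self-activation stronger than its self-decay; it sources the basal
  production of the constitutive proteins and of the driver nodes.
* ``LIGHT, DRV2, DRV3`` — a three-node repressilator (ring of cooperative
  inhibitions, each node produced from BASAL) tuned so its period equals
  ``light_period_hours``; ``LIGHT`` is the day/night signal.
* ``CRY`` — the light-regulated cryptochrome, driven by ``LIGHT``; its
  only outgoing influence is to promote the degradation of TIM
  (``CRY -| TIM``), which is how the clock reads the time zone.
* Core loop: ``CLK`` and ``CYC`` (both basally produced) form the
  ``CLK_CYC`` complex (AND gate), which transcribes the mRNAs ``per``,
  ``tim`` and ``cwo``; the proteins PER, TIM and CWO are translated from
  them.  CWO inhibits the mRNAs (the counterweight to CLK_CYC).  PER
  represses CLK (sequestration of the free complex-forming pool), closing
  the negative-feedback loop; DBT (basally produced) promotes PER
  degradation, and TIM shields PER by suppressing DBT activity.  CRY's
  light-gated degradation of TIM therefore advances PER turnover during
  the day and lets PER accumulate at night — an autonomous relaxation
  oscillator with a free-running period near one day, phase-locked to the
  driver.

Knock-outs behave as in the reference dynamics: removing CLK or CYC
silences transcription and every downstream node decays to a fixed point;
removing DBT lets PER saturate and clamp CLK down, extinguishing the
rhythm.  Scaling the rate constants downstream of CLK_CYC changes the
free-running period and thereby the observed one.

All ``k`` values below are this package's tuning against those
behaviours; they are plain constants, not hidden magic.
"""

from __future__ import annotations

from ..netmodel import ACTIVATION, AND, INHIBITION, Network, S1_REACTANT, S2_REACTANT_SUBSTRATE

#: Rate constants (fractions of full range per hour) for the circadian
#: model.  Grouped by mechanism; see the module docstring for the wiring.
CIRCADIAN_PARAMS: dict[str, float] = {
    # constitutive machinery
    "basal_self_act": 0.4,
    "basal_self_deg": 0.1,
    # repressilator driver (values give a 24 h ring period; scaled for
    # other day lengths)
    "drv_prod": 0.0817,
    "drv_rep": 0.817,
    "drv_deg": 0.0136,
    # light readout
    "cry_on": 0.25,
    "cry_deg": 0.20,
    # constitutive proteins
    "clk_prod": 0.252,
    "clk_deg": 0.042,
    "cyc_prod": 0.252,
    "cyc_deg": 0.042,
    "dbt_prod": 0.42,
    "dbt_deg": 0.084,
    # complex formation and transcription
    "cc_form": 0.672,
    "cc_deg": 0.336,
    "tx": 0.42,
    "mrna_deg": 0.252,
    "cwo_rep": 0.252,
    # translation and protein turnover
    "per_tl": 0.336,
    "per_deg": 0.0084,
    "tim_tl": 0.504,
    "tim_deg": 0.084,
    "cwo_tl": 0.168,
    "cwo_deg": 0.168,
    # regulatory edges (the two cooperative repressions are the relay
    # switches of the oscillator).  The core rates above put the
    # free-running period near 27 h; the light-gated TIM degradation can
    # only advance the clock, so the free period must exceed the day
    # length for stable 1:1 entrainment at 24 h.
    "dbt_per": 1.008,  # DBT -| PER: DBT-promoted PER degradation
    "tim_dbt": 1.26,   # TIM -| DBT (cooperative): TIM shields PER from DBT
    "per_clk": 5.04,   # PER -| CLK (cooperative): sequestration
    "cry_tim": 0.50,   # CRY -| TIM: light-gated TIM degradation
}

#: Initial levels (on L = 100) placing the clock on its entrained cycle
#: at dawn (LIGHT rising), so short runs need no settling transient.
_INITIAL = {
    "BASAL": 100,
    "LIGHT": 51,
    "DRV2": 5,
    "DRV3": 10,
    "CRY": 30,
    "CLK": 5,
    "CYC": 86,
    "CLK_CYC": 1,
    "per": 6,
    "tim": 6,
    "cwo": 6,
    "PER": 17,
    "TIM": 27,
    "CWO": 14,
    "DBT": 49,
}


def build_circadian(light_period_hours: float = 24.0, levels: int = 100) -> Network:
    """Build the circadian model entrained to a *light_period_hours* day."""
    if not light_period_hours > 0:
        raise ValueError(f"light_period_hours must be positive, got {light_period_hours}")
    p = CIRCADIAN_PARAMS
    drv_scale = 24.0 / light_period_hours

    net = Network(time_unit="h")
    for name, init in _INITIAL.items():
        net = net.add_node(name, levels=levels, initial_level=round(init * levels / 100))

    def act(src, tgt, k, scenario=S2_REACTANT_SUBSTRATE):
        nonlocal net
        net = net.add_interaction(src, tgt, ACTIVATION, scenario, k=k)

    def inh(src, tgt, k, scenario=S2_REACTANT_SUBSTRATE):
        nonlocal net
        net = net.add_interaction(src, tgt, INHIBITION, scenario, k=k)

    def selfdeg(name, k):
        nonlocal net
        net = net.add_interaction(name, name, INHIBITION, S1_REACTANT, k=k, id=f"{name} self-deg")

    # constitutive machinery: self-activation outweighs self-decay
    act("BASAL", "BASAL", p["basal_self_act"], S1_REACTANT)
    selfdeg("BASAL", p["basal_self_deg"])

    # day/night repressilator: cooperative (squared) ring inhibitions
    ring = ["LIGHT", "DRV2", "DRV3"]
    for i, name in enumerate(ring):
        act("BASAL", name, p["drv_prod"] * drv_scale)
        prev = ring[i - 1]
        inh((prev, prev), name, p["drv_rep"] * drv_scale, AND)
        selfdeg(name, p["drv_deg"] * drv_scale)

    # light readout
    act("LIGHT", "CRY", p["cry_on"])
    selfdeg("CRY", p["cry_deg"])

    # constitutive proteins
    act("BASAL", "CLK", p["clk_prod"])
    selfdeg("CLK", p["clk_deg"])
    act("BASAL", "CYC", p["cyc_prod"])
    selfdeg("CYC", p["cyc_deg"])
    act("BASAL", "DBT", p["dbt_prod"])
    selfdeg("DBT", p["dbt_deg"])

    # complex formation and transcription
    act(("CLK", "CYC"), "CLK_CYC", p["cc_form"], AND)
    selfdeg("CLK_CYC", p["cc_deg"])
    for mrna in ("per", "tim", "cwo"):
        act("CLK_CYC", mrna, p["tx"])
        inh("CWO", mrna, p["cwo_rep"])
        selfdeg(mrna, p["mrna_deg"])

    # translation and protein turnover
    act("per", "PER", p["per_tl"])
    selfdeg("PER", p["per_deg"])
    act("tim", "TIM", p["tim_tl"])
    selfdeg("TIM", p["tim_deg"])
    act("cwo", "CWO", p["cwo_tl"])
    selfdeg("CWO", p["cwo_deg"])

    # regulatory edges closing the loop; the duplicated-source AND gates
    # make the two relay repressions cooperative (rate ~ activity^2),
    # which gives them the switch-like character the oscillation needs
    inh("DBT", "PER", p["dbt_per"])
    inh(("TIM", "TIM"), "DBT", p["tim_dbt"], AND)
    inh(("PER", "PER"), "CLK", p["per_clk"], AND)
    inh("CRY", "TIM", p["cry_tim"])

    return net
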