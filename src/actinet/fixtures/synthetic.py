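"""Self-generated reference data for parameter-recovery tests.

A network simulated at known rate constants, sampled at chosen times and
optionally corrupted with seeded Gaussian noise, stands in for an
experimental time course whose generating parameters are known exactly —
the ground truth a parameter sweep should recover.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..engine import simulate
from ..experiments import ReferenceData
from ..netmodel import Network


def synthetic_reference(
    network: Network,
    k_overrides: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_times: Sequence[float] | None = None,
    nodes: Sequence[str] | None = None,
) -> ReferenceData:
    """Simulate *network* (center mode) and return it as reference data.

    ``k_overrides`` maps interaction ids to the generating rate constants;
    unknown ids raise.  Gaussian noise with SD *noise_sd* (activity units)
    is added pointwise and the result clipped to [0, 100].  ``nodes``
    restricts the columns (default: all nodes).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    net = network
    for iid, k in (k_overrides or {}).items():
        net = net.set_k(iid, k)  # raises on unknown id
    if sample_times is None:
        sample_times = np.linspace(0.0, 100.0, 11)
    sample_times = np.asarray(sample_times, dtype=float)
    duration = float(sample_times[-1])
    series = simulate(net, duration, mode="center")
    cols = list(nodes) if nodes is not None else series.node_names
    rng = np.random.default_rng(seed)
    data = {}
    for col in cols:
        vals = series.value_at(col, sample_times)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        data[col] = np.clip(vals, 0.0, 100.0)
    table = pd.DataFrame(data, index=pd.Index(sample_times, name="time"))
    prov = {c: f"synthetic(seed={seed}, noise_sd={noise_sd})" for c in cols}
    return ReferenceData(table, prov)
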