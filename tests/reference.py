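"""Naive direct-method SSA used as an independent oracle in tests.

Deliberately simple and slow: it evaluates every channel propensity from
scratch at every step via the symbolic channel objects, independent of the
compiled engine's cached/flattened implementation.
"""

from __future__ import annotations

import numpy as np

from icmsim.lattice import Lattice, build_transport_channels
from icmsim.params import ParameterSet
from icmsim.reactions import NSTATE, S, build_cell_channels


def naive_ssa(
    params: ParameterSet,
    lattice: Lattice,
    variant: str,
    init: np.ndarray,
    t_end: float,
    rng: np.random.Generator,
):
    """One trajectory of the tissue CTMC by the textbook direct method.

    Returns the state at ``t_end``.
    """
    cell_channels = build_cell_channels(params, variant)
    transport = build_transport_channels(params, lattice, variant)
    L = lattice.n_cells
    x = init.astype(np.int64).copy()
    t = 0.0
    while True:
        props = []
        actions = []
        for i in range(L):
            for ch in cell_channels:
                a = ch.propensity(x[i])
                if a > 0:
                    props.append(a)
                    actions.append(("cell", i, ch))
        for tc in transport:
            src_idx = S.FGF4 if tc.kind in ("autocrine", "paracrine") else S.M_FGFR_FGF4
            a = tc.rate * x[tc.source, src_idx]
            if a > 0:
                props.append(a)
                actions.append(("transport", tc, src_idx))
        total = float(np.sum(props))
        if total <= 0:
            return x
        t += rng.exponential(1.0 / total)
        if t > t_end:
            return x
        j = rng.choice(len(props), p=np.asarray(props) / total)
        kind = actions[j][0]
        if kind == "cell":
            _, i, ch = actions[j]
            x[i] = ch.apply(x[i])
        else:
            _, tc, src_idx = actions[j]
            x[tc.source, src_idx] -= 1
            x[tc.destination, S.M_FGFR_FGF4] += 1
        if (x < 0).any():
            raise RuntimeError("oracle produced a negative count")
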