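"""Shared test utilities: random small instances and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from dilpnet import (
    MeasurementTable,
    NetworkState,
    PerturbationSpec,
    SignedNetwork,
    make_random_network,
    step,
)


def random_small_instance(seed: int) -> tuple[SignedNetwork, MeasurementTable]:
    """A random acyclic network with <= 8 reactions and a random ternary
    measurement table over <= 3 timepoints (roots always measured)."""
    rng = np.random.default_rng(seed)
    n_edges = int(rng.integers(2, 9))
    n_roots = int(rng.integers(1, 3))
    n_prot = int(rng.integers(n_roots + 1, n_roots + n_edges + 1))
    max_e = sum(d for d in range(n_roots, n_prot))
    ne = max(min(n_edges, max_e), n_prot - n_roots)
    net = make_random_network(n_prot, ne, inhibition_fraction=0.3,
                              n_roots=n_roots, seed=seed)
    L = int(rng.integers(1, 4))
    states = pd.DataFrame(
        rng.choice([-1, 0, 1], size=(n_prot, L)),
        index=list(net.proteins),
        columns=[f"t{k + 1}" for k in range(L)],
    )
    roots = set(net.roots)
    measured = [p for p in net.proteins if p in roots or rng.random() < 0.8]
    return net, MeasurementTable.from_states(states.loc[measured])


def all_states(net: SignedNetwork):
    """Every ternary state of the network (3^n of them)."""
    for combo in itertools.product((-1, 0, 1), repeat=net.n_proteins):
        yield NetworkState(dict(zip(net.proteins, combo)))


def attractor_by_transition_graph(
    net: SignedNetwork,
    init: NetworkState,
    perturbation: PerturbationSpec | None = None,
):
    """Independent attractor oracle: build the full 3^n functional
    transition graph, follow the path from ``init`` to its terminal cycle,
    and report (kind, entry index, attractor state tuples)."""
    perturbation = perturbation or PerturbationSpec.none()
    if perturbation.clamps:
        init = NetworkState({**dict(init.values), **perturbation.clamps})
    nxt = {}
    for s in all_states(net):
        key = s.as_tuple(net)
        if any(key[list(net.proteins).index(p)] != v
               for p, v in perturbation.clamps.items()):
            continue  # unreachable under the clamp
        nxt[key] = step(net, s, perturbation).as_tuple(net)
    path = [init.as_tuple(net)]
    index = {path[0]: 0}
    while True:
        succ = nxt[path[-1]]
        if succ in index:
            cycle_start = index[succ]
            cycle = path[cycle_start:]
            kind = "fixed-point" if len(cycle) == 1 else "cycle"
            return kind, cycle_start, cycle
        index[succ] = len(path)
        path.append(succ)


def consistency_holds(net, states, occurrence) -> bool:
    """Check the state-consistency relation on an inference result: for
    every non-root protein and timepoint, the predicted state must match
    the occurring incoming influences (0 if none, the shared sign if
    single-signed, anything if conflicting)."""
    L = states.shape[1]
    labels = list(occurrence.index)
    for p in net.proteins:
        inc = net.incoming(p)
        if not inc:
            continue
        for k in range(L):
            pos = neg = False
            for i in inc:
                if not bool(occurrence.iloc[i, k] if i < len(labels) else False):
                    continue
                r = net.reactions[i]
                sigma = r.sign * int(states.loc[r.source].iloc[k])
                pos |= sigma == 1
                neg |= sigma == -1
            x = int(states.loc[p].iloc[k])
            if pos and neg:
                continue
            expected = 1 if pos else (-1 if neg else 0)
            if x != expected:
                return False
    return True
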