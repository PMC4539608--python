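"""Ground-truth scenarios for end-to-end testing of the inference pipeline.

Generates layered acyclic signed networks and per-timepoint ternary
measurements with the statistical structure the inference assumes: root
proteins follow a prescribed stimulus program, downstream states are
propagated with the sign-of-sum rule independently at each timepoint
(snapshots sharing one topology), and measurement error is modeled as
random state flips.  Ratios consistent with the discretization bands are
synthesized alongside the states so the full load -> discretize -> infer
pipeline can run on generated files.

Default dimensions mirror the study design this package targets: 31
proteins, 45 reactions (~20% inhibitory), 3 timepoints, 24 of 31 proteins
measured (72 measured entries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ACTIVATION, INHIBITION, Reaction, SignedNetwork, write_sif
from .rppa import MeasurementTable

__all__ = [
    "SyntheticScenario",
    "make_random_network",
    "make_root_program",
    "generate_measurements",
    "paper_scale_scenario",
    "write_scenario",
]

# representative fold-change bands per ternary state (up/none/down)
_RATIO_BANDS = {1: (1.3, 2.0), 0: (0.85, 1.15), -1: (0.4, 0.75)}


@dataclass
class SyntheticScenario:
    """A ground-truth network with clean and noise-corrupted measurements."""

    network: SignedNetwork
    root_program: dict[str, tuple[int, ...]]
    clean_table: MeasurementTable
    noisy_table: MeasurementTable
    flip_probability: float
    seed: int
    flipped_entries: tuple[tuple[str, int], ...]


def make_random_network(
    n_proteins: int,
    n_edges: int,
    inhibition_fraction: float = 0.2,
    n_roots: int = 3,
    seed: int = 0,
) -> SignedNetwork:
    """A random layered acyclic signed network, deterministic per seed.

    Proteins ``P01..Pnn`` are in topological order by index; the first
    ``n_roots`` are roots.  Every non-root receives at least one incoming
    reaction (a random backbone), remaining reactions are sampled from the
    forward pairs; each sign is inhibitory with probability
    ``inhibition_fraction``.
    """
    if n_roots < 1 or n_roots >= n_proteins:
        raise ValueError("need 1 <= n_roots < n_proteins")
    n_nonroot = n_proteins - n_roots
    max_edges = sum(min(d, n_proteins) - 0 for d in range(n_roots, n_proteins))
    # forward pairs (u, d): u < d, d non-root -> d has d predecessors
    max_edges = sum(d for d in range(n_roots, n_proteins))
    if not (n_nonroot <= n_edges <= max_edges):
        raise ValueError(
            f"n_edges must be in [{n_nonroot}, {max_edges}] for "
            f"{n_proteins} proteins with {n_roots} roots, got {n_edges}"
        )
    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    names = [f"P{i + 1:0{width}d}" for i in range(n_proteins)]
    pairs: set[tuple[int, int]] = set()
    for d in range(n_roots, n_proteins):
        u = int(rng.integers(0, d))
        pairs.add((u, d))
    candidates = [
        (u, d)
        for d in range(n_roots, n_proteins)
        for u in range(d)
        if (u, d) not in pairs
    ]
    extra = n_edges - len(pairs)
    if extra:
        chosen = rng.choice(len(candidates), size=extra, replace=False)
        for ix in sorted(chosen):
            pairs.add(candidates[ix])
    ordered = sorted(pairs, key=lambda ud: (ud[1], ud[0]))
    signs = rng.random(len(ordered))
    reactions = [
        Reaction(
            names[u],
            names[d],
            INHIBITION if s < inhibition_fraction else ACTIVATION,
        )
        for (u, d), s in zip(ordered, signs)
    ]
    return SignedNetwork(tuple(names), tuple(reactions))


def make_root_program(
    net: SignedNetwork, n_timepoints: int, seed: int = 0, p_zero: float = 0.2
) -> dict[str, tuple[int, ...]]:
    """A random stimulus program: each root gets a ternary value per
    timepoint, mostly nonzero (roots model driven receptors)."""
    rng = np.random.default_rng(seed)
    program = {}
    for p in net.roots:
        vals = rng.choice((-1, 0, 1), size=n_timepoints, p=((1 - p_zero) / 2, p_zero, (1 - p_zero) / 2))
        program[p] = tuple(int(v) for v in vals)
    return program


def _propagate(net: SignedNetwork, root_values: Mapping[str, int]) -> dict[str, int]:
    """Single-snapshot propagation of root values through the DAG with the
    sign-of-sum rule."""
    order = net.topological_order()
    state: dict[str, int] = {}
    for p in order:
        inc = net.incoming(p)
        if not inc:
            state[p] = int(root_values.get(p, 0))
        else:
            total = sum(
                net.reactions[i].sign * state[net.reactions[i].source] for i in inc
            )
            state[p] = (total > 0) - (total < 0)
    return state


def _ratio_for_state(state: int, rng: np.random.Generator) -> float:
    lo, hi = _RATIO_BANDS[state]
    return float(np.round(rng.uniform(lo, hi), 4))


def generate_measurements(
    net: SignedNetwork,
    root_program: Mapping[str, Sequence[int]],
    n_timepoints: int,
    measured_fraction: float = 1.0,
    flip_probability: float = 0.0,
    seed: int = 0,
    flip_indices: Sequence[tuple[str, int]] | None = None,
) -> SyntheticScenario:
    """Generate clean and noisy tables from a ground-truth network.

    Each timepoint is an independent snapshot: root states come from
    ``root_program`` and propagate downstream in topological order.  The
    measured set always contains every root (the experimentally driven
    inputs) plus a random sample of non-roots up to
    ``round(measured_fraction * n_proteins)`` proteins.  Noise replaces a
    measured entry by a uniformly chosen *different* ternary value with
    probability ``flip_probability`` — or at exactly the entries listed in
    ``flip_indices`` (reproducible fixed-index mode).  Synthesized ratios
    always discretize back to the recorded states.
    """
    if not net.is_acyclic():
        raise ValueError("generator requires an acyclic network")
    if not (0 < measured_fraction <= 1):
        raise ValueError("measured_fraction must be in (0, 1]")
    if not (0 <= flip_probability < 1):
        raise ValueError("flip_probability must be in [0, 1)")
    for p in net.roots:
        if p not in root_program or len(root_program[p]) != n_timepoints:
            raise ValueError(f"root program must cover root {p!r} at all timepoints")
    rng = np.random.default_rng(seed)
    timepoints = [f"t{k + 1}" for k in range(n_timepoints)]

    clean = {}
    for k in range(n_timepoints):
        snapshot = _propagate(
            net, {p: root_program[p][k] for p in net.roots}
        )
        for p, v in snapshot.items():
            clean.setdefault(p, []).append(v)
    clean_states = pd.DataFrame(
        {tp: [clean[p][k] for p in net.proteins] for k, tp in enumerate(timepoints)},
        index=list(net.proteins),
    ).astype(int)

    n_measured = max(len(net.roots), int(round(measured_fraction * net.n_proteins)))
    nonroots = [p for p in net.proteins if p not in set(net.roots)]
    extra = n_measured - len(net.roots)
    chosen = (
        list(rng.choice(nonroots, size=extra, replace=False)) if extra else []
    )
    measured = [p for p in net.proteins if p in set(net.roots) or p in set(chosen)]

    clean_states_meas = clean_states.loc[measured]
    clean_ratios = clean_states_meas.map(lambda s: _ratio_for_state(int(s), rng))
    clean_table = MeasurementTable(ratios=clean_ratios, states=clean_states_meas)

    noisy_states = clean_states_meas.copy()
    flipped: list[tuple[str, int]] = []
    if flip_indices is not None:
        targets = list(flip_indices)
    else:
        targets = [
            (p, k)
            for p in measured
            for k in range(n_timepoints)
            if rng.random() < flip_probability
        ]
    for p, k in targets:
        if p not in set(measured) or not (0 <= k < n_timepoints):
            raise ValueError(f"flip index ({p!r}, {k}) outside the measured table")
        old = int(noisy_states.loc[p].iloc[k])
        new = int(rng.choice([v for v in (-1, 0, 1) if v != old]))
        noisy_states.loc[p, timepoints[k]] = new
        flipped.append((p, k))
    noisy_ratios = clean_ratios.copy()
    for p, k in flipped:
        noisy_ratios.loc[p, timepoints[k]] = _ratio_for_state(
            int(noisy_states.loc[p].iloc[k]), rng
        )
    noisy_table = MeasurementTable(ratios=noisy_ratios, states=noisy_states.astype(int))

    return SyntheticScenario(
        network=net,
        root_program={p: tuple(int(v) for v in root_program[p]) for p in net.roots},
        clean_table=clean_table,
        noisy_table=noisy_table,
        flip_probability=float(flip_probability),
        seed=int(seed),
        flipped_entries=tuple(flipped),
    )


def paper_scale_scenario(
    seed: int,
    n_proteins: int = 31,
    n_edges: int = 45,
    n_timepoints: int = 3,
    inhibition_fraction: float = 0.2,
    n_roots: int = 7,
    measured_fraction: float = 1.0,
    flip_probability: float = 0.0,
    flip_indices: Sequence[tuple[str, int]] | None = None,
) -> SyntheticScenario:
    """Convenience scenario at the dimensions of the studied pathway maps."""
    net = make_random_network(
        n_proteins, n_edges, inhibition_fraction, n_roots, seed=seed
    )
    program = make_root_program(net, n_timepoints, seed=seed + 1)
    return generate_measurements(
        net,
        program,
        n_timepoints,
        measured_fraction=measured_fraction,
        flip_probability=flip_probability,
        seed=seed + 2,
        flip_indices=flip_indices,
    )


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> None:
    """Write the SIF network, clean/noisy ratio CSVs, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sif(scenario.network, outdir / "network.sif")
    scenario.clean_table.ratios.to_csv(outdir / "clean.csv", index_label="protein")
    scenario.noisy_table.ratios.to_csv(outdir / "noisy.csv", index_label="protein")
    manifest = {
        "seed": scenario.seed,
        "n_proteins": scenario.network.n_proteins,
        "n_reactions": scenario.network.n_reactions,
        "n_timepoints": scenario.clean_table.n_timepoints,
        "flip_probability": scenario.flip_probability,
        "root_program": {p: list(v) for p, v in scenario.root_program.items()},
        "flipped_entries": [list(e) for e in scenario.flipped_entries],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
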