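"""Synchronous ternary state-transition simulation of a signed network.

Starting from an initial ternary state vector (typically the predicted
states of an inferred condition-specific network at one timepoint), every
protein is updated simultaneously: a non-root protein takes the sign of the
summed signed influence of its parents, a root holds its value (a sustained
extracellular stimulus), and a drug-targeted protein is clamped at -1 at
every step.  Iteration continues until a fixed point X with step(X) = X, a
revisited state (a cycle), or a step cap.  The fixed point reached under a
drug clamp is the predicted post-treatment steady state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .network import SignedNetwork

__all__ = [
    "NetworkState",
    "PerturbationSpec",
    "Trajectory",
    "step",
    "simulate_to_attractor",
    "apply_drug",
    "consistent_successors",
]

TERNARY = (-1, 0, 1)


def _sign(v: int) -> int:
    return (v > 0) - (v < 0)


@dataclass(frozen=True)
class NetworkState:
    """A complete ternary assignment protein -> {-1, 0, 1}."""

    values: Mapping[str, int]

    @classmethod
    def of(cls, net: SignedNetwork, values: Mapping[str, int]) -> "NetworkState":
        missing = [p for p in net.proteins if p not in values]
        if missing:
            raise ValueError(f"state is incomplete, missing {missing}")
        clean = {}
        for p in net.proteins:
            v = int(values[p])
            if v not in TERNARY:
                raise ValueError(f"state of {p!r} must be ternary, got {v}")
            clean[p] = v
        return cls(dict(clean))

    @classmethod
    def uniform(cls, net: SignedNetwork, value: int = 0) -> "NetworkState":
        return cls.of(net, {p: value for p in net.proteins})

    def __getitem__(self, protein: str) -> int:
        return self.values[protein]

    def as_tuple(self, net: SignedNetwork) -> tuple[int, ...]:
        return tuple(self.values[p] for p in net.proteins)


@dataclass(frozen=True)
class PerturbationSpec:
    """Proteins held at a forced state at every step (drug clamps)."""

    clamps: Mapping[str, int]

    def __post_init__(self) -> None:
        for p, v in self.clamps.items():
            if int(v) not in TERNARY:
                raise ValueError(f"clamp of {p!r} must be ternary, got {v}")

    @classmethod
    def none(cls) -> "PerturbationSpec":
        return cls({})

    def validate_against(self, net: SignedNetwork) -> None:
        unknown = [p for p in self.clamps if p not in set(net.proteins)]
        if unknown:
            raise KeyError(f"clamp targets not in network: {unknown}")


@dataclass
class Trajectory:
    """A simulated state sequence X_0 .. X_end with attractor metadata.

    ``steps_to_attractor`` counts transitions: an initial state that
    confirms itself on the first update reports 0 steps.
    """

    states: list[NetworkState]
    attractor_kind: Literal["fixed-point", "cycle", "max-steps"]
    steps_to_attractor: int
    attractor_states: list[NetworkState] = field(default_factory=list)

    @property
    def final_state(self) -> NetworkState:
        return self.states[-1]


def step(
    net: SignedNetwork,
    state: NetworkState,
    perturbation: PerturbationSpec | None = None,
    root_mode: Literal["hold", "decay"] = "hold",
) -> NetworkState:
    """One synchronous update.

    Clamped proteins take their forced value; roots hold their previous
    value (or decay to 0 with ``root_mode="decay"``); every other protein
    becomes the sign of the sum of signed parent influences
    ``sum_i s_i * x(u_i)``.
    """
    perturbation = perturbation or PerturbationSpec.none()
    perturbation.validate_against(net)
    nxt: dict[str, int] = {}
    for p in net.proteins:
        if p in perturbation.clamps:
            nxt[p] = int(perturbation.clamps[p])
        elif net.is_root(p):
            nxt[p] = state[p] if root_mode == "hold" else 0
        else:
            total = sum(
                net.reactions[i].sign * state[net.reactions[i].source]
                for i in net.incoming(p)
            )
            nxt[p] = _sign(total)
    return NetworkState(nxt)


def simulate_to_attractor(
    net: SignedNetwork,
    init: NetworkState,
    perturbation: PerturbationSpec | None = None,
    max_steps: int = 100,
    root_mode: Literal["hold", "decay"] = "hold",
) -> Trajectory:
    """Iterate :func:`step` until a fixed point, a cycle, or ``max_steps``.

    The perturbation clamps are imposed on the initial state as well, so
    every recorded state respects them.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    perturbation = perturbation or PerturbationSpec.none()
    perturbation.validate_against(net)
    if perturbation.clamps:
        init = NetworkState(
            {**dict(init.values), **{p: int(v) for p, v in perturbation.clamps.items()}}
        )
    states = [init]
    seen = {init.as_tuple(net): 0}
    for t in range(max_steps):
        nxt = step(net, states[-1], perturbation, root_mode=root_mode)
        key = nxt.as_tuple(net)
        if key == states[-1].as_tuple(net):
            return Trajectory(
                states=states + [nxt],
                attractor_kind="fixed-point",
                steps_to_attractor=t,
                attractor_states=[nxt],
            )
        if key in seen:
            start = seen[key]
            return Trajectory(
                states=states + [nxt],
                attractor_kind="cycle",
                steps_to_attractor=start,
                attractor_states=states[start:],
            )
        seen[key] = len(states)
        states.append(nxt)
    return Trajectory(
        states=states,
        attractor_kind="max-steps",
        steps_to_attractor=max_steps,
        attractor_states=[],
    )


def apply_drug(
    net: SignedNetwork,
    state: NetworkState,
    targets: Iterable[str],
) -> tuple[NetworkState, PerturbationSpec]:
    """Model inhibitor treatment: targeted proteins are set to -1 in the
    initial state and clamped at -1 for all subsequent steps."""
    targets = list(targets)
    known = set(net.proteins)
    unknown = [t for t in targets if t not in known]
    if unknown:
        raise KeyError(f"drug targets not in network: {unknown}")
    clamps = {t: -1 for t in targets}
    new_state = NetworkState({**dict(state.values), **clamps})
    return new_state, PerturbationSpec(clamps)


def consistent_successors(
    net: SignedNetwork,
    state: NetworkState,
    perturbation: PerturbationSpec | None = None,
) -> list[NetworkState]:
    """All successors consistent with the state-consistency relation.

    Audit mode: a protein receiving both positive and negative occurring
    influences may take any value in {-1, 0, 1}; the deterministic
    :func:`step` picks the sign of the net sum, which is always one of
    these.  Proteins with single-signed or no influence have a unique
    consistent value.
    """
    perturbation = perturbation or PerturbationSpec.none()
    perturbation.validate_against(net)
    fixed: dict[str, int] = {}
    conflicted: list[str] = []
    for p in net.proteins:
        if p in perturbation.clamps:
            fixed[p] = int(perturbation.clamps[p])
        elif net.is_root(p):
            fixed[p] = state[p]
        else:
            influences = [
                net.reactions[i].sign * state[net.reactions[i].source]
                for i in net.incoming(p)
            ]
            has_pos = any(v == 1 for v in influences)
            has_neg = any(v == -1 for v in influences)
            if has_pos and has_neg:
                conflicted.append(p)
            else:
                fixed[p] = 1 if has_pos else (-1 if has_neg else 0)
    out = []
    for combo in itertools.product(TERNARY, repeat=len(conflicted)):
        out.append(NetworkState({**fixed, **dict(zip(conflicted, combo))}))
    return out
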