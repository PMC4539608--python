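"""Signed directed pathway maps.

A pathway map is a set of signaling proteins ``P`` and a list of signed
directed reactions ``E``: each reaction ``(u, d, s)`` says that the upstream
protein *u* activates (``s = +1``) or inhibits (``s = -1``) the downstream
protein *d*.  Maps are read and written in a three-column SIF dialect::

    SOURCE  activate  TARGET
    SOURCE  inhibit   TARGET

with ``1``/``-1`` accepted as synonyms for the relation token and ``#``
starting a comment line.  Reaction order in the file defines the reaction
index used throughout the inference model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Reaction",
    "SignedNetwork",
    "SifParseError",
    "NetworkValidationError",
    "read_sif",
    "write_sif",
    "linking_pattern",
]

ACTIVATION = 1
INHIBITION = -1

_RELATION_TOKENS = {
    "activate": ACTIVATION,
    "inhibit": INHIBITION,
    "1": ACTIVATION,
    "-1": INHIBITION,
}

_RELATION_NAMES = {ACTIVATION: "activate", INHIBITION: "inhibit"}


class SifParseError(ValueError):
    """Malformed SIF input (reported with a line number)."""


class NetworkValidationError(ValueError):
    """A network violating the structural invariants."""


@dataclass(frozen=True)
class Reaction:
    """One signed directed reaction ``source -> target`` (sign +1) or
    ``source -| target`` (sign -1)."""

    source: str
    target: str
    sign: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        arrow = "->" if self.sign == ACTIVATION else "-|"
        return f"{self.source} {arrow} {self.target}"


def _check_identifier(name: str) -> None:
    if not name or any(ch.isspace() for ch in name):
        raise NetworkValidationError(
            f"protein identifier {name!r} must be non-empty and whitespace-free"
        )


@dataclass(frozen=True)
class SignedNetwork:
    """An ordered signed directed graph of signaling reactions.

    ``proteins`` is the ordered protein set P (first appearance in the
    reaction list, then any explicitly listed isolated proteins);
    ``reactions`` is the ordered reaction list E.  Roots — proteins with no
    incoming reaction — are computed, never stored.
    """

    proteins: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    _incoming: dict[str, tuple[int, ...]] = field(
        init=False, repr=False, compare=False, hash=False, default=None
    )

    def __post_init__(self) -> None:
        seen_proteins = set()
        for p in self.proteins:
            _check_identifier(p)
            if p in seen_proteins:
                raise NetworkValidationError(f"duplicate protein {p!r}")
            seen_proteins.add(p)
        seen_edges = set()
        incoming: dict[str, list[int]] = {p: [] for p in self.proteins}
        for i, r in enumerate(self.reactions):
            if r.sign not in (ACTIVATION, INHIBITION):
                raise NetworkValidationError(
                    f"reaction {i}: sign must be +1 or -1, got {r.sign!r}"
                )
            for endpoint in (r.source, r.target):
                if endpoint not in seen_proteins:
                    raise NetworkValidationError(
                        f"reaction {i}: protein {endpoint!r} not in protein set"
                    )
            if r.source == r.target:
                raise NetworkValidationError(
                    f"reaction {i}: self-loop on {r.source!r} is not allowed"
                )
            key = (r.source, r.target, r.sign)
            if key in seen_edges:
                raise NetworkValidationError(f"duplicate reaction {r}")
            seen_edges.add(key)
            incoming[r.target].append(i)
        object.__setattr__(
            self, "_incoming", {p: tuple(ix) for p, ix in incoming.items()}
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_reactions(
        cls,
        reactions: Iterable[tuple[str, str, int] | Reaction],
        extra_proteins: Sequence[str] = (),
    ) -> "SignedNetwork":
        """Build a network from (source, target, sign) triples; the protein
        order is first appearance as source or target."""
        rlist = [
            r if isinstance(r, Reaction) else Reaction(*r) for r in reactions
        ]
        proteins: list[str] = []
        seen = set()
        for r in rlist:
            for p in (r.source, r.target):
                if p not in seen:
                    seen.add(p)
                    proteins.append(p)
        for p in extra_proteins:
            if p not in seen:
                seen.add(p)
                proteins.append(p)
        return cls(tuple(proteins), tuple(rlist))

    # -- structure ---------------------------------------------------------

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def roots(self) -> tuple[str, ...]:
        """Proteins with no incoming reaction, in protein order."""
        return tuple(p for p in self.proteins if not self._incoming[p])

    def incoming(self, protein: str) -> tuple[int, ...]:
        """Indices of reactions targeting ``protein``."""
        try:
            return self._incoming[protein]
        except KeyError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def is_root(self, protein: str) -> bool:
        return not self.incoming(protein)

    def subnetwork(self, keep: Iterable[int]) -> "SignedNetwork":
        """Network with only the reactions at indices ``keep`` (order kept);
        the protein set is unchanged."""
        keep = sorted(set(keep))
        return SignedNetwork(
            self.proteins, tuple(self.reactions[i] for i in keep)
        )

    def topological_order(self) -> tuple[str, ...]:
        """Proteins in a topological order; raises on cyclic networks."""
        import graphlib

        ts = graphlib.TopologicalSorter(
            {p: [self.reactions[i].source for i in self._incoming[p]]
             for p in self.proteins}
        )
        try:
            return tuple(ts.static_order())
        except graphlib.CycleError as exc:
            raise NetworkValidationError("network contains a cycle") from exc

    def is_acyclic(self) -> bool:
        try:
            self.topological_order()
        except NetworkValidationError:
            return False
        return True


def linking_pattern(net: SignedNetwork, protein: str) -> str:
    """Classify how ``protein`` is regulated by its incoming reactions.

    Returns one of ``root``, ``single-activation``, ``single-inhibition``,
    ``multiple-activation``, ``multiple-inhibition``, ``mixed`` — the five
    regulation patterns of a downstream node (plus the unregulated root
    case): a unique activating or inhibiting parent, several parents of one
    sign, or parents of both signs (whose joint effect can be up, down or
    no change).
    """
    idx = net.incoming(protein)
    if not idx:
        return "root"
    signs = {net.reactions[i].sign for i in idx}
    if signs == {ACTIVATION}:
        return "single-activation" if len(idx) == 1 else "multiple-activation"
    if signs == {INHIBITION}:
        return "single-inhibition" if len(idx) == 1 else "multiple-inhibition"
    return "mixed"


def read_sif(path: str | Path) -> SignedNetwork:
    """Read a signed network from a SIF file (see module docstring)."""
    path = Path(path)
    reactions: list[tuple[str, str, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise SifParseError(
                    f"{path.name}:{lineno}: expected 3 fields "
                    f"(source relation target), got {len(fields)}"
                )
            source, relation, target = fields
            sign = _RELATION_TOKENS.get(relation.lower())
            if sign is None:
                raise SifParseError(
                    f"{path.name}:{lineno}: unknown relation token "
                    f"{relation!r} (expected activate/inhibit/1/-1)"
                )
            reactions.append((source, target, sign))
    return SignedNetwork.from_reactions(reactions)


def write_sif(net: SignedNetwork, path: str | Path) -> None:
    """Write ``net`` to ``path``; ``read_sif`` round-trips to an identical
    network (same reaction order)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in net.reactions:
            fh.write(f"{r.source}\t{_RELATION_NAMES[r.sign]}\t{r.target}\n")
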