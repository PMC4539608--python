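"""Condition-specific subnetwork inference by integer linear programming.

Given a generic signed pathway map and a discretized protein × timepoint
measurement table, the model chooses, for every reaction *i* and timepoint
*k*, whether the reaction occurs (binary ``z[i,k]``, 0 = occurs) and whether
it is removed from the condition-specific network altogether (binary
``y[i]``).  A reaction is retained iff it occurs at at least one timepoint:

    y[i] <= z[i,k]            for every k          (occurs somewhere -> kept)
    y[i] >= sum_k z[i,k] - (L - 1)                 (occurs nowhere  -> removed)

Predicted ternary protein states ``x[j,k]`` must be consistent with the
occurring reactions: a non-root protein is +1 if some occurring incoming
influence is positive and none negative, -1 in the mirror case, 0 if no
occurring reaction carries signal, and free in {-1, 0, 1} when positive and
negative influences collide.  Root proteins are clamped to their measured
states (they are the experimentally driven inputs); unmeasured roots are
held at 0.  A binary mismatch indicator ``a[j,k]`` is 1 iff the prediction
disagrees with the measurement, and the objective

    minimize  sum_jk a[j,k]  +  beta * sum_i y[i]        (beta < 0)

trades fitting error against network size; |beta| * n_r < 1 keeps sparsity
strictly subordinate to a single fitting error.  The model is solved to
proven optimality with the HiGHS mixed-integer solver.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .network import ACTIVATION, SignedNetwork
from .rppa import MeasurementTable

__all__ = [
    "DILPModel",
    "InferenceResult",
    "build_model",
    "solve",
    "restore_missing_edges",
    "fitting_precision",
    "brute_force_infer",
    "auto_beta",
]


def auto_beta(n_reactions: int) -> float:
    """Default sparsity weight: beta = -1 / (2 n_r), so that removing every
    reaction rewards the objective by exactly 0.5 — less than one fitting
    error."""
    return -1.0 / (2 * n_reactions) if n_reactions else -0.5


class _VarSpace:
    """Flat 0/1 variable index allocator."""

    def __init__(self) -> None:
        self.n = 0

    def block(self, count: int) -> int:
        start = self.n
        self.n += count
        return start


@dataclass
class DILPModel:
    """Assembled MILP for one condition (all variables binary).

    The ternary state of protein j at timepoint k is encoded as
    ``x = xp - xn`` with ``xp + xn <= 1``; per-(reaction, timepoint)
    auxiliary binaries linearize the signed influence of the upstream
    protein, gated by the occurrence variable.
    """

    network: SignedNetwork
    data: MeasurementTable
    beta: float
    n_timepoints: int
    measured: tuple[str, ...]
    n_variables: int
    n_constraints: int
    # flat index blocks
    _xp0: int
    _xn0: int
    _z0: int
    _y0: int
    _a0: int
    _a_index: dict[tuple[str, int], int]
    _A: sparse.csr_matrix
    _b: np.ndarray
    _c: np.ndarray
    _lb: np.ndarray
    _ub: np.ndarray
    m: dict[str, np.ndarray] = field(repr=False, default=None)

    # -- variable accessors (flat indices) --------------------------------

    def xp(self, j: int, k: int) -> int:
        return self._xp0 + j * self.n_timepoints + k

    def xn(self, j: int, k: int) -> int:
        return self._xn0 + j * self.n_timepoints + k

    def z(self, i: int, k: int) -> int:
        return self._z0 + i * self.n_timepoints + k

    def y(self, i: int) -> int:
        return self._y0 + i

    def a(self, protein: str, k: int) -> int:
        return self._a_index[(protein, k)]


@dataclass
class InferenceResult:
    """A solved (or brute-forced) condition-specific subnetwork."""

    network: SignedNetwork            # retained reactions, all proteins kept
    retained_edges: tuple[int, ...]   # generic-map reaction indices, y = 0
    removed_edges: tuple[int, ...]    # generic-map reaction indices, y = 1
    occurrence: pd.DataFrame          # reactions x timepoints, bool (z complement)
    predicted_states: pd.DataFrame    # proteins x timepoints, {-1,0,1}
    data_term: int
    objective: float
    beta: float
    n_measured_entries: int
    solver_status: str = "optimal"
    restored_edges: tuple[int, ...] = ()

    @property
    def optimal(self) -> bool:
        return self.solver_status == "optimal"

    @property
    def fitting_precision(self) -> float:
        return fitting_precision(self)

    def report(self) -> dict:
        """JSON-serializable run report."""
        return {
            "objective": self.objective,
            "data_term": self.data_term,
            "fitting_precision": round(self.fitting_precision, 2),
            "beta": self.beta,
            "n_retained_edges": len(self.retained_edges),
            "removed_edges": [
                f"{r.source}{'->' if r.sign == ACTIVATION else '-|'}{r.target}"
                for r in (self.network_removed_reactions())
            ],
            "restored_edges": list(self.restored_edges),
            "solver_status": self.solver_status,
        }

    def network_removed_reactions(self):
        gen = _generic_reactions.get(id(self))
        if gen is None:
            return []
        return [gen[i] for i in self.removed_edges]


# weak side-table: generic reaction list per result (for report labels)
_generic_reactions: dict[int, tuple] = {}


def fitting_precision(result: InferenceResult) -> float:
    """Percentage of measured (protein, timepoint) entries whose predicted
    state equals the discretized measurement: 100 * (1 - data_term / N)."""
    n = result.n_measured_entries
    if n == 0:
        raise ValueError("fitting precision undefined: no measured entries")
    return 100.0 * (1.0 - result.data_term / n)


def build_model(
    net: SignedNetwork,
    data: MeasurementTable,
    beta: float | str = "auto",
) -> DILPModel:
    """Assemble the DILP over a generic map and a discretized table.

    ``beta`` may be a negative float or ``"auto"`` (-1 / (2 n_r)).  Raises
    if the table has not been discretized, a measured protein is missing
    from the network, or beta is out of range.
    """
    if data.states is None:
        raise ValueError("measurement table must be discretized first")
    if isinstance(beta, str):
        if beta != "auto":
            raise ValueError(f"beta must be a negative number or 'auto', got {beta!r}")
        beta = auto_beta(net.n_reactions)
    beta = float(beta)
    if net.n_reactions and not (beta < 0):
        raise ValueError(f"beta must be negative, got {beta}")
    if net.n_reactions and abs(beta) * net.n_reactions >= 1:
        raise ValueError(
            f"|beta| * n_r must be < 1 (beta={beta}, n_r={net.n_reactions}): "
            "sparsity would outweigh a fitting error"
        )
    missing = [p for p in data.proteins if p not in set(net.proteins)]
    if missing:
        raise ValueError(f"measured proteins absent from network: {missing}")

    L = data.n_timepoints
    proteins = net.proteins
    pindex = {p: j for j, p in enumerate(proteins)}
    roots = set(net.roots)
    measured = tuple(p for p in proteins if p in set(data.proteins))
    m = {p: data.states.loc[p].to_numpy().astype(int) for p in measured}

    space = _VarSpace()
    n_s, n_r = net.n_proteins, net.n_reactions
    xp0 = space.block(n_s * L)
    xn0 = space.block(n_s * L)
    z0 = space.block(n_r * L)
    y0 = space.block(n_r)
    p0 = space.block(n_r * L)   # occurring positive influence indicator
    q0 = space.block(n_r * L)   # occurring negative influence indicator
    nonroots = [p for p in proteins if p not in roots]
    nr_index = {p: d for d, p in enumerate(nonroots)}
    pos0 = space.block(len(nonroots) * L)
    neg0 = space.block(len(nonroots) * L)
    a_index = {}
    a0 = space.block(len(measured) * L)
    for jj, p in enumerate(measured):
        for k in range(L):
            a_index[(p, k)] = a0 + jj * L + k

    def xp(j, k):
        return xp0 + j * L + k

    def xn(j, k):
        return xn0 + j * L + k

    def zv(i, k):
        return z0 + i * L + k

    def pv(i, k):
        return p0 + i * L + k

    def qv(i, k):
        return q0 + i * L + k

    def posv(p, k):
        return pos0 + nr_index[p] * L + k

    def negv(p, k):
        return neg0 + nr_index[p] * L + k

    lb = np.zeros(space.n)
    ub = np.ones(space.n)

    # clamp roots: measured roots to m, unmeasured roots to 0
    for p in roots:
        j = pindex[p]
        for k in range(L):
            mv = int(m[p][k]) if p in m else 0
            lb[xp(j, k)] = ub[xp(j, k)] = 1.0 if mv == 1 else 0.0
            lb[xn(j, k)] = ub[xn(j, k)] = 1.0 if mv == -1 else 0.0

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b: list[float] = []

    def add_row(terms: list[tuple[int, float]], rhs: float) -> None:
        r = len(b)
        for col, v in terms:
            rows.append(r)
            cols.append(col)
            vals.append(v)
        b.append(rhs)

    # ternary encoding for non-root proteins
    for p in nonroots:
        j = pindex[p]
        for k in range(L):
            add_row([(xp(j, k), 1), (xn(j, k), 1)], 1)

    # influence indicators p/q: AND of (reaction occurs) and (source pushes
    # the corresponding sign)
    for i, r in enumerate(net.reactions):
        u = pindex[r.source]
        for k in range(L):
            act = xp(u, k) if r.sign == ACTIVATION else xn(u, k)
            inh = xn(u, k) if r.sign == ACTIVATION else xp(u, k)
            add_row([(pv(i, k), 1), (zv(i, k), 1)], 1)
            add_row([(pv(i, k), 1), (act, -1)], 0)
            add_row([(pv(i, k), -1), (act, 1), (zv(i, k), -1)], 0)
            add_row([(qv(i, k), 1), (zv(i, k), 1)], 1)
            add_row([(qv(i, k), 1), (inh, -1)], 0)
            add_row([(qv(i, k), -1), (inh, 1), (zv(i, k), -1)], 0)

    # Pos/Neg: OR of influence indicators over incoming reactions
    for p in nonroots:
        j = pindex[p]
        inc = net.incoming(p)
        for k in range(L):
            for i in inc:
                add_row([(pv(i, k), 1), (posv(p, k), -1)], 0)
                add_row([(qv(i, k), 1), (negv(p, k), -1)], 0)
            add_row([(posv(p, k), 1)] + [(pv(i, k), -1) for i in inc], 0)
            add_row([(negv(p, k), 1)] + [(qv(i, k), -1) for i in inc], 0)
            # state consistency: x = Pos - Neg unless both present (free)
            add_row(
                [(xp(j, k), -1), (xn(j, k), 1), (posv(p, k), 1), (negv(p, k), -2)],
                0,
            )
            add_row(
                [(xp(j, k), 1), (xn(j, k), -1), (posv(p, k), -2), (negv(p, k), 1)],
                0,
            )

    # removal/occurrence linkage
    for i in range(n_r):
        for k in range(L):
            add_row([(y0 + i, 1), (zv(i, k), -1)], 0)
        add_row([(zv(i, k), 1) for k in range(L)] + [(y0 + i, -1)], L - 1)

    # mismatch indicators
    for p in measured:
        j = pindex[p]
        for k in range(L):
            av = a_index[(p, k)]
            mv = int(m[p][k])
            add_row([(av, -2), (xp(j, k), -1), (xn(j, k), 1)], -mv)
            add_row([(av, -2), (xp(j, k), 1), (xn(j, k), -1)], mv)

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(b), space.n)
    )
    c = np.zeros(space.n)
    for (_, _), av in a_index.items():
        c[av] = 1.0
    c[y0 : y0 + n_r] = beta

    return DILPModel(
        network=net,
        data=data,
        beta=beta,
        n_timepoints=L,
        measured=measured,
        n_variables=space.n,
        n_constraints=len(b),
        _xp0=xp0,
        _xn0=xn0,
        _z0=z0,
        _y0=y0,
        _a0=a0,
        _a_index=a_index,
        _A=A,
        _b=np.asarray(b, dtype=float),
        _c=c,
        _lb=lb,
        _ub=ub,
        m=m,
    )


def _run_milp(model, c, extra_eq=None, ub_override=None, time_limit=300.0):
    constraints = []
    if model._A.shape[0]:
        constraints.append(LinearConstraint(model._A, -np.inf, model._b))
    if extra_eq is not None:
        A_eq, rhs = extra_eq
        constraints.append(LinearConstraint(A_eq, rhs, rhs))
    ub = model._ub if ub_override is None else ub_override
    res = milp(
        c,
        constraints=constraints,
        integrality=np.ones(model.n_variables),
        bounds=Bounds(model._lb, ub),
        options={"time_limit": float(time_limit), "presolve": True},
    )
    return res


def _extract(model: DILPModel, x: np.ndarray, force_status: str) -> InferenceResult:
    net = model.network
    L = model.n_timepoints
    vals = np.rint(x).astype(int)
    pindex = {p: j for j, p in enumerate(net.proteins)}
    states = np.zeros((net.n_proteins, L), dtype=int)
    for p, j in pindex.items():
        for k in range(L):
            states[j, k] = vals[model.xp(j, k)] - vals[model.xn(j, k)]
    tps = list(model.data.ratios.columns) if model.data.n_timepoints == L else list(range(L))
    predicted = pd.DataFrame(states, index=list(net.proteins), columns=tps)
    y = np.array([vals[model.y(i)] for i in range(net.n_reactions)], dtype=int)
    z = np.zeros((net.n_reactions, L), dtype=int)
    for i in range(net.n_reactions):
        for k in range(L):
            z[i, k] = vals[model.z(i, k)]
    occurrence = pd.DataFrame(
        (1 - z).astype(bool),
        index=[f"{r.source}|{'+' if r.sign == ACTIVATION else '-'}|{r.target}"
               for r in net.reactions],
        columns=tps,
    )
    data_term = 0
    for p in model.measured:
        j = pindex[p]
        data_term += int(np.sum(states[j] != model.m[p]))
    retained = tuple(int(i) for i in np.flatnonzero(y == 0))
    removed = tuple(int(i) for i in np.flatnonzero(y == 1))
    result = InferenceResult(
        network=net.subnetwork(retained),
        retained_edges=retained,
        removed_edges=removed,
        occurrence=occurrence,
        predicted_states=predicted,
        data_term=data_term,
        objective=float(data_term + model.beta * len(removed)),
        beta=model.beta,
        n_measured_entries=len(model.measured) * L,
        solver_status=force_status,
    )
    _generic_reactions[id(result)] = net.reactions
    return result


def solve(
    model: DILPModel,
    time_limit: float = 300.0,
    canonical: bool = True,
    force_retain: tuple[int, ...] = (),
) -> InferenceResult:
    """Solve the DILP to proven optimality.

    When ``canonical`` is set the optimum is re-solved a second time with
    the data term and removal count pinned, preferring removal of
    high-index reactions — a deterministic tie-break among equally optimal
    subnetworks.  ``force_retain`` pins the listed reactions into the
    network (y = 0), used by edge restoration.
    """
    if model.n_variables == 0:
        empty = pd.DataFrame()
        return InferenceResult(
            network=model.network, retained_edges=(), removed_edges=(),
            occurrence=empty, predicted_states=empty, data_term=0,
            objective=0.0, beta=model.beta, n_measured_entries=0,
        )
    ub = model._ub.copy()
    for i in force_retain:
        ub[model.y(i)] = 0.0
    res = _run_milp(model, model._c, ub_override=ub, time_limit=time_limit)
    if res.x is None:
        raise RuntimeError(
            f"MILP solve failed (status {res.status}: {res.message}); "
            "the model is feasible by construction, so this indicates a "
            "time limit too small to find any incumbent"
        )
    status = "optimal" if res.status == 0 else "timeout"
    result = _extract(model, res.x, status)
    if not canonical or status != "optimal" or model.network.n_reactions == 0:
        return result
    # second stage: pin data term and removal count, push removals to
    # high-index reactions so the retained set is reproducible
    n = model.n_variables
    a_cols = [model.a(p, k) for (p, k) in model._a_index]
    y_cols = [model.y(i) for i in range(model.network.n_reactions)]
    A_eq = sparse.lil_matrix((2, n))
    for col in a_cols:
        A_eq[0, col] = 1.0
    for col in y_cols:
        A_eq[1, col] = 1.0
    rhs = np.array([float(result.data_term), float(len(result.removed_edges))])
    c2 = np.zeros(n)
    for i in range(model.network.n_reactions):
        c2[model.y(i)] = -(i + 1)
    res2 = _run_milp(
        model, c2, extra_eq=(A_eq.tocsr(), rhs), ub_override=ub,
        time_limit=time_limit,
    )
    if res2.x is None or res2.status != 0:
        return result  # keep the verified optimum if the tie-break times out
    return _extract(model, res2.x, "optimal")


def restore_missing_edges(
    result: InferenceResult,
    model: DILPModel,
    time_limit: float = 300.0,
) -> InferenceResult:
    """Add removed reactions back when doing so leaves the fit unchanged.

    Removed reactions are revisited in generic-map order; each candidate is
    pinned into the network together with the already-retained reactions and
    all previously accepted ones, and the model re-solved.  The candidate is
    accepted iff the optimal data term is unchanged, so the network grows
    monotonically.  Passes repeat until one accepts nothing.
    """
    if not result.optimal:
        raise ValueError("restoration requires a proven-optimal result")
    base = result.data_term
    accepted: list[int] = []
    current = result
    changed = True
    while changed:
        changed = False
        for i in result.removed_edges:
            if i in accepted:
                continue
            trial = solve(
                model,
                time_limit=time_limit,
                force_retain=result.retained_edges + tuple(accepted) + (i,),
            )
            if trial.optimal and trial.data_term == base:
                accepted.append(i)
                current = trial
                changed = True
    if not accepted:
        return InferenceResult(
            **{**result.__dict__, "restored_edges": ()}
        )
    final = InferenceResult(
        **{**current.__dict__, "restored_edges": tuple(accepted)}
    )
    _generic_reactions[id(final)] = model.network.reactions
    return final


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def brute_force_infer(
    net: SignedNetwork,
    data: MeasurementTable,
    beta: float | str = "auto",
    max_edges: int = 8,
    max_timepoints: int = 3,
) -> InferenceResult:
    """Globally optimal inference by exhaustive enumeration (testing oracle).

    Enumerates, per timepoint, every subset of occurring reactions and every
    consistent ternary state assignment, then minimizes the shared objective
    over all occurrence supports.  Only feasible for tiny instances
    (n_r <= 8, L <= 3); returns the same objective as :func:`solve` on every
    such instance.
    """
    if data.states is None:
        raise ValueError("measurement table must be discretized first")
    if net.n_reactions > max_edges:
        raise ValueError(f"oracle bound exceeded: {net.n_reactions} > {max_edges} edges")
    if data.n_timepoints > max_timepoints:
        raise ValueError(
            f"oracle bound exceeded: {data.n_timepoints} > {max_timepoints} timepoints"
        )
    if isinstance(beta, str):
        beta = auto_beta(net.n_reactions)
    beta = float(beta)

    proteins = list(net.proteins)
    pindex = {p: j for j, p in enumerate(proteins)}
    roots = set(net.roots)
    nonroots = [p for p in proteins if p not in roots]
    measured = [p for p in proteins if p in set(data.proteins)]
    m = {p: data.states.loc[p].to_numpy().astype(int) for p in measured}
    L = data.n_timepoints
    n_r = net.n_reactions

    if n_r == 0:
        # nothing to choose: every non-root is 0, roots clamped
        states = np.zeros((len(proteins), L), dtype=int)
        for p in roots & set(measured):
            states[pindex[p]] = m[p]
        data_term = sum(
            int(np.sum(states[pindex[p]] != m[p])) for p in measured
        )
        predicted = pd.DataFrame(
            states, index=proteins, columns=list(data.ratios.columns)
        )
        return InferenceResult(
            network=net, retained_edges=(), removed_edges=(),
            occurrence=pd.DataFrame(columns=list(data.ratios.columns)),
            predicted_states=predicted, data_term=data_term,
            objective=float(data_term), beta=beta,
            n_measured_entries=len(measured) * L,
        )

    free = nonroots  # every non-root state is enumerated
    combos = np.array(
        list(itertools.product((-1, 0, 1), repeat=len(free))), dtype=np.int8
    )
    R = combos.shape[0]
    n_sub = 1 << n_r
    f = np.full((L, n_sub), np.inf)
    argrow = np.zeros((L, n_sub), dtype=np.int64)
    in_mask = {
        d: sum(1 << i for i in net.incoming(d)) for d in nonroots
    }

    for k in range(L):
        X = np.zeros((R, len(proteins)), dtype=np.int8)
        for jj, p in enumerate(free):
            X[:, pindex[p]] = combos[:, jj]
        for p in roots:
            X[:, pindex[p]] = int(m[p][k]) if p in m else 0
        mismatch = np.zeros(R, dtype=np.int32)
        for p in measured:
            mismatch += (X[:, pindex[p]] != int(m[p][k])).astype(np.int32)
        # per-row bitmasks of reactions whose occurring influence would be
        # positive (pmask) / negative (qmask), restricted per target below
        pbits = np.zeros((R, n_r), dtype=bool)
        qbits = np.zeros((R, n_r), dtype=bool)
        for i, r in enumerate(net.reactions):
            src = X[:, pindex[r.source]]
            pbits[:, i] = src == r.sign
            qbits[:, i] = src == -r.sign
        weights = (1 << np.arange(n_r)).astype(np.int64)
        pmask_all = pbits @ weights
        qmask_all = qbits @ weights
        n_d = len(nonroots)
        Pm = np.zeros((R, n_d), dtype=np.int64)
        Qm = np.zeros((R, n_d), dtype=np.int64)
        Xd = np.zeros((R, n_d), dtype=np.int8)
        for dd, p in enumerate(nonroots):
            Pm[:, dd] = pmask_all & in_mask[p]
            Qm[:, dd] = qmask_all & in_mask[p]
            Xd[:, dd] = X[:, pindex[p]]
        for O in range(n_sub):
            Pos = (Pm & O) != 0
            Neg = (Qm & O) != 0
            required = Pos.astype(np.int8) - Neg.astype(np.int8)
            ok = (Pos & Neg) | (Xd == required)
            valid = ok.all(axis=1)
            if valid.any():
                cand = np.where(valid, mismatch, np.iinfo(np.int32).max)
                best = int(np.argmin(cand))
                f[k, O] = mismatch[best]
                argrow[k, O] = best

    # subset minimum: fmin[S] = min over O subset of S of f[O]
    fmin = f.copy()
    argsub = np.tile(np.arange(n_sub), (L, 1))
    for bit in range(n_r):
        has = (np.arange(n_sub) >> bit) & 1 == 1
        idx = np.flatnonzero(has)
        other = idx ^ (1 << bit)
        for k in range(L):
            better = fmin[k, other] < fmin[k, idx]
            fmin[k, idx[better]] = fmin[k, other[better]]
            argsub[k, idx[better]] = argsub[k, other[better]]

    popcount = np.array([bin(S).count("1") for S in range(n_sub)])
    totals = fmin.sum(axis=0) + beta * (n_r - popcount)
    best_S = int(np.argmin(totals))
    best_obj = float(totals[best_S])

    occ_sets = [int(argsub[k, best_S]) for k in range(L)]
    support = 0
    for O in occ_sets:
        support |= O
    removed = tuple(i for i in range(n_r) if not (support >> i) & 1)
    retained = tuple(i for i in range(n_r) if (support >> i) & 1)
    # the reported objective uses the realized support
    data_term = int(sum(fmin[k, best_S] for k in range(L)))
    objective = data_term + beta * len(removed)
    assert objective <= best_obj + 1e-9

    states = np.zeros((len(proteins), L), dtype=int)
    for k, O in enumerate(occ_sets):
        row = argrow[k, O]
        for jj, p in enumerate(free):
            states[pindex[p], k] = combos[row, jj]
        for p in roots:
            states[pindex[p], k] = int(m[p][k]) if p in m else 0
    tps = list(data.ratios.columns)
    predicted = pd.DataFrame(states, index=proteins, columns=tps)
    occurrence = pd.DataFrame(
        [[bool((occ_sets[k] >> i) & 1) for k in range(L)] for i in range(n_r)],
        index=[f"{r.source}|{'+' if r.sign == ACTIVATION else '-'}|{r.target}"
               for r in net.reactions],
        columns=tps,
    )
    result = InferenceResult(
        network=net.subnetwork(retained),
        retained_edges=retained,
        removed_edges=removed,
        occurrence=occurrence,
        predicted_states=predicted,
        data_term=data_term,
        objective=float(objective),
        beta=beta,
        n_measured_entries=len(measured) * L,
    )
    _generic_reactions[id(result)] = net.reactions
    return result


def write_result(result: InferenceResult, model: DILPModel, outdir: str | Path) -> None:
    """Write inferred SIF, occurrence CSV, predicted-state CSV and JSON report."""
    from .network import write_sif

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sif(result.network, outdir / "inferred.sif")
    result.occurrence.astype(int).to_csv(outdir / "occurrence.csv")
    result.predicted_states.to_csv(outdir / "predicted_states.csv")
    report = result.report()
    report.update(
        {
            "constraint_count": model.n_constraints,
            "variable_count": model.n_variables,
        }
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
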