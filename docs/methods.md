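# Methods

## Discretization

Fold-change ratios ρ (treated / reference, per protein per timepoint) are
mapped to ternary states with inclusive thresholds: ρ ≥ 1.2 → +1
(up-regulated), ρ ≤ 0.8 → −1 (down-regulated), otherwise 0.  Both
thresholds are configurable (`discretize(table, up=, down=)` with
`up > down > 0`).  The map is monotone and idempotent.  Missing cells are
an error — no imputation rule is defined, so the loader fails loudly and
names the offending cell.  Proteins present in a network but absent from
the table are treated as *unmeasured*: they carry state variables and may
transmit signal, but contribute no fitting error (they correspond to
predicted, unmeasured nodes of a pathway diagram).

## The inference MILP

**Variables (all binary).**  Each ternary state is split as
x = x⁺ − x⁻ with x⁺ + x⁻ ≤ 1.  Per reaction *i* and timepoint *k*,
z[i,k] = 1 iff the reaction does not occur at *k*; per reaction, y[i] = 1
iff it is removed from the inferred network.  Auxiliary binaries p[i,k]
(resp. q[i,k]) indicate that reaction *i* occurs at *k* *and* its upstream
protein pushes its target up (resp. down): for an activation from *u*,
p ⇔ (1−z) ∧ x⁺(u); for an inhibition, p ⇔ (1−z) ∧ x⁻(u).  Per non-root
target and timepoint, Pos/Neg are the ORs of p/q over incoming reactions.

**State consistency.**  For every non-root protein and timepoint:

    x ≥ Pos − 2·Neg        x ≤ 2·Pos − Neg

With (Pos, Neg) = (0,0) these pin x = 0 (no occurring input ⇒ no change);
(1,0) pins x = +1; (0,1) pins x = −1; (1,1) leaves x free in {−1, 0, +1}
(conflicting simultaneous influences).  The "no occurring input ⇒ 0" rule
is load-bearing: without it, removing every reaction and matching all data
perfectly would always be optimal, because the sparsity term rewards
removal.  Edge removals therefore genuinely cost fitting accuracy wherever
they cut a needed signal path.

**Roots.**  Proteins with no incoming reaction are the experimentally
driven inputs (receptors, stimuli).  Measured roots are clamped to their
discretized measurements at every timepoint; unmeasured roots are fixed at
0.  This choice closes the model at its boundary without inventing
unobserved stimuli.

**Mismatch and objective.**  For each measured protein, binary a[j,k]
satisfies 2a ≥ m − x and 2a ≥ x − m (m − x ∈ [−2, 2], so a = 1 exactly when
x ≠ m at the optimum); a disagreement of magnitude 2 counts the same as one
of magnitude 1.  The objective minimizes Σ a + β Σ y with β < 0.  Default
β = −1/(2 n_r): |β|·n_r = 0.5 < 1 guarantees the removal reward can never
outweigh one fitting error, so optima always minimize the data term first
and, among those, remove as many reactions as possible.  Any β with
|β|·n_r < 1 is accepted.

**Feasibility and bounds.**  Every instance is feasible (remove everything,
set all non-root states to 0), which also yields the upper bound
objective ≤ #{nonzero measured non-root entries} + β·n_r.

**Solver and tie-breaking.**  The MILP is solved with HiGHS through
`scipy.optimize.milp` to proven optimality (default time limit 300 s; a
timeout is flagged on the result and test assertions require proven
optimality).  Because multiple optimal subnetworks can exist, a second
solve pins the optimal data term and removal count and then prefers
removing high-index reactions (minimizing an index-weighted retained set).
This is a deterministic, reproducible tie-break; it approximates a
lexicographic preference for low-index retained reactions without the
numerically unusable 2^i weights exact lexicography would need.  The
per-timepoint occurrence pattern of a *retained* reaction whose upstream
state is 0 is undetermined (occurring with zero influence and not occurring
are indistinguishable); reported occurrence matrices are deterministic for
a fixed model but such entries carry no information.

**Restoration of fit-neutral edges.**  After solving, removed reactions are
revisited in generic-map order; each candidate is pinned into the network
(y = 0) together with everything already retained or previously accepted,
and the model re-solved.  The candidate is accepted iff the optimal data
term is unchanged, so the network grows monotonically; passes repeat until
nothing is accepted.  Note the criterion is literal: a reaction removed
purely for the sparsity reward (its inclusion never changes any fit, e.g.
because it can occur at a timepoint where its source is 0, or because it
joins a conflicting-influence node) is restored.  Restoration therefore
partially undoes minimality by design — it recovers edges whose removal was
not evidence-driven.

**Fitting precision** = 100 · (1 − Σa / (n_measured · L)), displayed with
two decimals.  With 24 measured proteins over 3 timepoints the granularity
is 1/72 ≈ 1.39 percentage points.

## The exhaustive oracle

`brute_force_infer` finds the global optimum independently of the MILP for
instances with ≤ 8 reactions and ≤ 3 timepoints.  Per timepoint it
enumerates every occurrence subset O ⊆ E and every ternary assignment of
non-root states (roots clamped as in the MILP), keeping the minimal
mismatch f_k(O) over consistent assignments.  A subset-minimum (zeta)
transform then yields min_{O⊆S} f_k(O) for every support S, and the global
optimum is min_S Σ_k min_{O⊆S} f_k(O) + β·(n_r − |S|); the realized support
(union of the per-timepoint minimizers) attains it.  The oracle shares no
code with the MILP assembly and is the reference in the solver-equivalence
tests.

## Ternary state-transition simulation

Synchronous update: every non-root protein simultaneously becomes
sign(Σ_i s_i · x(u_i)) over its incoming reactions; roots hold their value
(sustained stimulus; a `decay` mode zeroing them exists behind a flag);
clamped proteins take their forced value at every step, modeling an
inhibitor as a −1 clamp.  Conflicting influences are resolved
deterministically by the net sum (exact balance → 0), which is always one
of the values the consistency relation allows; `consistent_successors`
enumerates the full successor set for audit.  Iteration stops at the first
fixed point, the first revisited state (a cycle), or `max_steps` (default
100, flagged, not an error).  `steps_to_attractor` counts transitions, so a
self-confirming initial state reports 0.  Occurrence patterns from
inference play no role here: all retained reactions are always active on
the inferred topology.

## Synthetic scenarios

The generator emulates the statistical structure of a discretized RPPA
contrast experiment.  A layered acyclic signed network is sampled (every
non-root gets a backbone parent among lower-indexed proteins, remaining
reactions drawn from forward pairs, signs inhibitory with a configurable
fraction); a root program assigns each root a ternary value per timepoint
(mostly nonzero — driven receptors); downstream states propagate with the
sign-of-sum rule *independently at each timepoint*, mirroring the
inference's treatment of timepoints as snapshots sharing one topology
rather than a single trajectory.  Ratios are sampled inside the band of
each state (up: 1.3–2.0, none: 0.85–1.15, down: 0.4–0.75) so the generated
tables discretize back to their states exactly.  Measurement noise replaces
an entry by a uniformly chosen different ternary value, either
independently with a flip probability or at an exact list of indices
(reproducible fixed-index mode); flips are recorded.  Roots are always in
the measured set, since the inference clamps measured roots.

Defaults mirror the targeted study design: 31 proteins, 45 reactions
(inhibitory fraction 0.2), 7 roots, 3 timepoints, and — where a partial
measured set is wanted — 24 of 31 proteins measured (72 entries) with a
0.15 flip rate (~11 expected flips).  What passing tests on these scenarios
show: the MILP recovers exactly-consistent data (data term 0) and degrades
by at most one error per flipped entry.  What they do not show: robustness
to real RPPA features outside the model — continuous intensity noise near
the thresholds, antibody cross-reactivity, feedback loops (the generator is
DAG-only, though inference and simulation accept cyclic maps), or
correlated replicate error.

## Bundled pathway maps

`normoxia_generic.sif` (31 proteins, 45 reactions) and
`hypoxia_generic.sif` (31 proteins, 42 reactions) are best-effort
transcriptions of the published generic myeloma–osteoclast maps: node and
edge counts match the printed figures, all proteins named in the source
text are present (ASCII identifiers, e.g. NF-κB → NFKB), and edge
directions/signs follow the canonical pathway literature for the named
cascades.  Individual edges beyond the explicitly described ones are not
verifiable from text and should be treated as a faithful reconstruction,
not a certified copy.

## Problem sizes used in the checks

The acceptance script and test suite run the solver-vs-oracle comparison on
100 random instances of ≤ 8 reactions and ≤ 3 timepoints, noise-free
recovery on 20 scenarios at 31 proteins / 45 reactions / 3 timepoints, and
attractor verification against the full 3^n transition graph on networks of
≤ 6 proteins — sizes at which the exhaustive oracles are exact and the
whole suite completes in well under a minute of solver time.  At map scale
the assembled model has on the order of 850 variables and 1800 constraints;
encodings differ in auxiliary-variable count, so model-size checks are
order-of-magnitude diagnostics, not equalities.

## Known limitations

- Inference treats timepoints as independent snapshots; no dynamics link
  x[·,k] to x[·,k+1] during fitting (dynamics enter only in simulation).
- The restoration criterion is literal "fit unchanged", so sparsity-only
  removals are undone; a stricter necessity criterion would keep them out.
- Conflicting-influence nodes are deterministic only in simulation (net
  sum); inference leaves them free, so predicted states at such nodes
  follow the data rather than a mechanism.
- The CLI exposes the pipeline per condition; multi-condition joint
  inference is out of scope.
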