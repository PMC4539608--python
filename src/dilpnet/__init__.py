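"""dilpnet: condition-specific signaling subnetwork inference by dynamic
integer linear programming, plus ternary state-transition simulation of
drug perturbations."""

from importlib import resources

from .network import (
    Reaction,
    SignedNetwork,
    SifParseError,
    NetworkValidationError,
    linking_pattern,
    read_sif,
    write_sif,
)
from .rppa import (
    MeasurementTable,
    TableFormatError,
    discretize,
    load_table,
    ratio_of_conditions,
)
from .inference import (
    DILPModel,
    InferenceResult,
    auto_beta,
    brute_force_infer,
    build_model,
    fitting_precision,
    restore_missing_edges,
    solve,
)
from .dynamics import (
    NetworkState,
    PerturbationSpec,
    Trajectory,
    apply_drug,
    consistent_successors,
    simulate_to_attractor,
    step,
)
from .synthetic import (
    SyntheticScenario,
    generate_measurements,
    make_random_network,
    make_root_program,
    paper_scale_scenario,
    write_scenario,
)

__version__ = "0.1.0"


def fixture_path(name: str):
    """Path to a packaged generic pathway map (``normoxia_generic.sif`` or
    ``hypoxia_generic.sif``)."""
    ref = resources.files("dilpnet") / "fixtures" / name
    with resources.as_file(ref) as path:
        return path
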