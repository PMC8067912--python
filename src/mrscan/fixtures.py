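"""Deterministic synthetic C-alpha structures and brute-force oracles.

The helix generator mimics protein backbone geometry (consecutive
C-alpha spacing near 3.8 A) so that the default 12.5 A cutoff yields a
connected, non-collinear contact network with realistic contact counts.
The oracles here deliberately avoid the closed formulas they are used
to check: the expectation oracle only calls the force sampler and the
linear response, and the overlap oracle searches directions densely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic_network import (
    DEFAULT_CUTOFF,
    CAStructure,
    ContactTopology,
    CovarianceMatrix,
    build_contacts,
    linear_response,
)
from .errors import (
    BadFixtureError,
    DisconnectedNetworkError,
    FixtureOverflowError,
    InvalidParameterError,
    OracleRangeError,
)
from .mutation_forces import ForceModel, sample_mutation_force

MAX_PDB_RESIDUES = 9999


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic helical C-alpha trace.

    Defaults give consecutive site spacing of ~3.8 A (rise 1.5 A,
    radius 2.3 A, turn 100 degrees).  ``jitter`` adds seeded Gaussian
    noise to every coordinate.
    """

    n_sites: int
    geometry: str = "helix"
    rise: float = 1.5
    radius: float = 2.3
    turn_deg: float = 100.0
    jitter: float = 0.0
    seed: int = 0


def generate_helix(spec: FixtureSpec) -> CAStructure:
    """Generate a helical C-alpha structure from closed-form coordinates.

    Site ``t`` sits at ``(r cos(t theta), r sin(t theta), t * rise)``;
    optional seeded Gaussian jitter is added afterwards.  The result is
    verified to be connected at the default cutoff, else
    :class:`BadFixtureError` is raised.
    """
    if spec.n_sites < 4:
        raise InvalidParameterError(f"need n_sites >= 4, got {spec.n_sites}")
    t = np.arange(spec.n_sites)
    theta = np.deg2rad(spec.turn_deg) * t
    coords = np.column_stack(
        [spec.radius * np.cos(theta), spec.radius * np.sin(theta), spec.rise * t]
    )
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.jitter, size=coords.shape)
    ids = tuple(f"A:{i + 1}" for i in range(spec.n_sites))
    structure = CAStructure(ids, coords)
    try:
        build_contacts(structure, DEFAULT_CUTOFF)
    except DisconnectedNetworkError as exc:
        raise BadFixtureError(
            f"fixture disconnected at cutoff {DEFAULT_CUTOFF}: {exc}"
        ) from exc
    return structure


def write_fixture_pdb(structure: CAStructure) -> str:
    """Render a structure as minimal PDB text (CA/GLY/chain A records).

    Round-trips through :func:`parse_ca_structure` at the 3-decimal
    precision of the fixed-width coordinate fields.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = structure.n_sites
    if n > MAX_PDB_RESIDUES:
        raise FixtureOverflowError(
            f"{n} residues exceed the {MAX_PDB_RESIDUES} PDB serial limit"
        )
    if np.any(np.abs(structure.coords) > 9999.999):
        raise FixtureOverflowError("coordinate exceeds fixed-width field range")
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(structure.coords, dtype=np.float32)
    atoms.chain_id[:] = "A"
    atoms.res_id = np.arange(1, n + 1)
    atoms.ins_code[:] = ""
    atoms.res_name[:] = "GLY"
    atoms.hetero[:] = False
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    pdb_file = PDBFile()
    pdb_file.set_structure(atoms)
    return "\n".join(pdb_file.lines) + "\n"


def mc_expectation_oracle(
    covariance: CovarianceMatrix,
    topology: ContactTopology,
    sigma: float,
    site_j: int,
    n_samples: int,
    seed: int = 0,
):
    """Monte-Carlo estimate of the mean squared response to mutations.

    Returns ``(mean, se)`` over ``n_samples`` random mutations at
    ``site_j``: per-site means of the squared displacement and their
    standard errors.  Uses only the force sampler and the linear
    response — never the closed formula — so it is an independent
    oracle for the analytical sensitivity column.
    """
    if n_samples < 2:
        raise InvalidParameterError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    n = topology.n_sites
    if sigma == 0.0:
        return np.zeros(n), np.zeros(n)
    model = ForceModel(sigma=sigma, seed=seed)
    samples = np.empty((n_samples, n))
    for s in range(n_samples):
        force = sample_mutation_force(model, site_j, topology, rng=rng)
        disp = linear_response(covariance, force.assembled)
        samples[s] = disp.per_site_sq_norm()
    mean = samples.mean(axis=0)
    se = samples.std(axis=0, ddof=1) / np.sqrt(n_samples)
    return mean, se


def max_overlap_oracle(
    block, f_i: np.ndarray, sigma: float, n_directions: int, seed: int = 0
) -> float:
    """Dense direction search for the maximal squared overlap.

    Evaluates ``(f_i^T A f_j)^2`` at ``n_directions`` quasi-uniform
    points on the constraint sphere of radius ``sigma * sqrt(CN(j))``.
    Feasible only for CN(j) <= 3; always a lower bound on the true
    supremum.
    """
    A = block.matrix if hasattr(block, "matrix") else np.asarray(block, dtype=float)
    cn_j = A.shape[1]
    if cn_j > 3:
        raise OracleRangeError(f"dense search infeasible for CN(j) = {cn_j}")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_directions, cn_j))
    norms = np.linalg.norm(dirs, axis=1)
    dirs = dirs[norms > 0] / norms[norms > 0, None]
    f_j = sigma * np.sqrt(cn_j) * dirs
    vals = (f_j @ (A.T @ np.asarray(f_i, dtype=float))) ** 2
    return float(vals.max())
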