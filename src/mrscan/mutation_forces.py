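"""Point mutations modelled as random forces on the contacts of a site.

A mutation at site ``j`` applies, for each contact ``jl``, a force
``f(jl) e_jl`` to partner ``l`` and the reaction ``-f(jl) e_jl`` to
``j`` itself.  Scalars ``f(jl)`` are drawn i.i.d. N(0, sigma^2).  For
double scanning the scalar vector is renormalized onto the sphere
``sum f(jl)^2 = sigma^2 CN(j)`` so that the maximization over second
mutations is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic_network import ContactTopology
from .errors import (
    InconsistentInputsError,
    InvalidParameterError,
    IsolatedSiteError,
    ResampleRequired,
)

DEFAULT_SIGMA = 0.3


@dataclass(frozen=True)
class ForceModel:
    """Distribution settings for mutation forces.

    ``renormalize`` selects the constrained variant used by double
    scanning.  Identical seeds yield identical force sequences.
    """

    sigma: float = DEFAULT_SIGMA
    renormalize: bool = False
    seed: int | None = None

    def __post_init__(self):
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class MutationForce:
    """One sampled mutation: contact scalars plus the assembled 3N vector.

    ``contact_scalars`` are ordered by contact partner index, matching
    ``topology.contacts_of(site)``.
    """

    site: int
    contact_scalars: np.ndarray
    assembled: np.ndarray


def assemble_force_vector(
    site: int, contact_scalars: np.ndarray, topology: ContactTopology
) -> np.ndarray:
    """Build the 3N force vector of a mutation from its contact scalars.

    Entry blocks: ``+f(jl) e_jl`` at each partner ``l``, the summed
    reactions ``-sum f(jl) e_jl`` at ``site``, zero elsewhere.
    """
    partners, evecs = topology.contacts_of(site)
    scalars = np.asarray(contact_scalars, dtype=float)
    if scalars.shape != (len(partners),):
        raise InconsistentInputsError(
            f"{scalars.shape[0] if scalars.ndim == 1 else scalars.shape} "
            f"scalars for {len(partners)} contacts of site {site}"
        )
    f = np.zeros(3 * topology.n_sites)
    contrib = scalars[:, None] * evecs
    np.add.at(f.reshape(-1, 3), partners, contrib)
    f[3 * site : 3 * site + 3] -= contrib.sum(axis=0)
    return f


def sample_mutation_force(
    model: ForceModel,
    site: int,
    topology: ContactTopology,
    rng: np.random.Generator | None = None,
) -> MutationForce:
    """Draw one random mutation force at ``site``.

    Contact scalars are i.i.d. N(0, sigma^2); if ``model.renormalize``
    they are rescaled onto the constraint sphere (redrawing the
    probability-zero all-zero event).  The generator state advances
    deterministically.
    """
    if rng is None:
        rng = model.rng()
    partners, _ = topology.contacts_of(site)
    cn = len(partners)
    if cn == 0:
        raise IsolatedSiteError(f"site {site} has no contacts")
    scalars = rng.normal(0.0, model.sigma, size=cn)
    if model.renormalize:
        while not np.any(scalars):
            scalars = rng.normal(0.0, model.sigma, size=cn)
        scalars = _renormalized_scalars(scalars, model.sigma)
    assembled = assemble_force_vector(site, scalars, topology)
    return MutationForce(site=site, contact_scalars=scalars, assembled=assembled)


def _renormalized_scalars(scalars: np.ndarray, sigma: float) -> np.ndarray:
    norm = np.linalg.norm(scalars)
    if norm == 0.0:
        raise ResampleRequired("all-zero force draw; redraw required")
    return scalars * (sigma * np.sqrt(len(scalars)) / norm)


def renormalize_force(
    force: MutationForce, sigma: float, topology: ContactTopology
) -> MutationForce:
    """Rescale a mutation force onto the sphere ``|f|^2 = sigma^2 CN``.

    Ratios among the contact scalars are unchanged; the assembled vector
    is rebuilt.  Raises :class:`ResampleRequired` for an all-zero draw.
    """
    scalars = _renormalized_scalars(
        np.asarray(force.contact_scalars, dtype=float), sigma
    )
    return MutationForce(
        site=force.site,
        contact_scalars=scalars,
        assembled=assemble_force_vector(force.site, scalars, topology),
    )
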