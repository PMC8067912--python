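"""Double mutation-response scanning: the N x N compensation matrix.

``D[i, j]`` quantifies how well a mutation at ``j`` can compensate the
structural deformation of a mutation at ``i``: the root of the mean
(over first mutations) of the maximal squared overlap between the two
deformation fields, the second mutation constrained to
``|f(j)|^2 = sigma^2 CN(j)``.

The computation runs in contact space through the overlap blocks
``A_ij`` (CN(i) x CN(j)), for which the deformation dot product is the
bilinear form ``f(i)^T A_ij f(j)``.

Routes:

* :func:`sdmrs_compensation` — Monte-Carlo: maximize over M sampled
  second mutations, average over M first mutations;
* :func:`admrs_compensation` — closed form
  ``D_ij = sigma^2 sqrt(CN(j) Tr(A_ij A_ij^T))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elastic_network import ContactTopology, CovarianceMatrix
from .errors import (
    InconsistentInputsError,
    InvalidParameterError,
    IsolatedSiteError,
)
from .mrs import MarginalProfiles, marginal_profiles, site_response_columns
from .mutation_forces import ForceModel


@dataclass(frozen=True)
class OverlapBlock:
    """Contact-space overlap between deformations of two mutated sites.

    ``matrix[k, l] = e_ik^T (C_k - C_i)^T (C_l - C_j) e_jl`` so that
    ``f(i)^T A f(j)`` equals the dot product of the two linear-response
    displacement fields.
    """

    first_site: int
    second_site: int
    matrix: np.ndarray


@dataclass(frozen=True)
class CompensationMatrix:
    """N x N nonnegative compensation values with run metadata.

    Rows index the first-mutated site ``i``, columns the compensating
    site ``j``.
    """

    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


def overlap_block(
    covariance: CovarianceMatrix, topology: ContactTopology, i: int, j: int
) -> OverlapBlock:
    """Compute the CN(i) x CN(j) overlap block ``A_ij``."""
    if topology.contact_counts[i] == 0 or topology.contact_counts[j] == 0:
        raise IsolatedSiteError(f"site {i if topology.contact_counts[i] == 0 else j} has no contacts")
    Gi = site_response_columns(covariance, topology, i)
    Gj = site_response_columns(covariance, topology, j)
    # both factors carry the 1/kBT of the linear response, so the
    # displacement dot-product identity holds at any kBT
    return OverlapBlock(first_site=i, second_site=j, matrix=Gi.T @ Gj)


def max_compensation_given_first(
    f_i: np.ndarray, block: OverlapBlock, sigma: float, cn_j: int
) -> float:
    """Maximal squared overlap achievable by the second mutation.

    On the constraint sphere ``|f(j)|^2 = sigma^2 CN(j)`` the maximum of
    ``(f(i)^T A f(j))^2`` is attained at ``f(j)`` proportional to
    ``A^T f(i)`` (Cauchy-Schwarz) and equals
    ``sigma^2 CN(j) |A^T f(i)|^2``.
    """
    f_i = np.asarray(f_i, dtype=float)
    if f_i.shape != (block.matrix.shape[0],):
        raise InconsistentInputsError(
            f"f_i has shape {f_i.shape}, block expects ({block.matrix.shape[0]},)"
        )
    v = block.matrix.T @ f_i
    return float(sigma**2 * cn_j * (v @ v))


def _check_same_structure(covariance, topology):
    if topology.n_sites != covariance.n_sites:
        raise InconsistentInputsError(
            "covariance and topology built from different structures"
        )


def _response_basis(covariance, topology):
    """Per-site response bases stacked into one 3N x sum(CN) matrix."""
    n = topology.n_sites
    Gs = [site_response_columns(covariance, topology, x) for x in range(n)]
    starts = np.concatenate(([0], np.cumsum(topology.contact_counts)))
    return Gs, np.hstack(Gs), starts


def admrs_compensation(
    covariance: CovarianceMatrix, topology: ContactTopology, sigma: float
) -> CompensationMatrix:
    """Analytical compensation matrix.

    ``D_ij = sigma^2 sqrt(CN(j) Tr(A_ij A_ij^T))``: the trace is the
    squared Frobenius norm of the overlap block, read off one Gram
    matrix of all per-contact response columns.
    """
    _check_same_structure(covariance, topology)
    _, G, starts = _response_basis(covariance, topology)
    gram_sq = (G.T @ G) ** 2
    seg = starts[:-1]
    traces = np.add.reduceat(np.add.reduceat(gram_sq, seg, axis=0), seg, axis=1)
    cn = topology.contact_counts.astype(float)
    D = sigma**2 * np.sqrt(traces * cn[None, :])
    return CompensationMatrix(
        matrix=D, meta={"method": "admrs", "sigma": float(sigma)}
    )


def draw_renormalized_site_forces(
    topology: ContactTopology, model: ForceModel, M: int
) -> list[np.ndarray]:
    """Draw M renormalized contact-scalar vectors for every site.

    Sites consume random draws in site order (mutation index within a
    site varies fastest), so results do not depend on the pair loop
    order.  Each row of the returned (M, CN(x)) arrays lies on the
    sphere of radius ``sigma * sqrt(CN(x))``.
    """
    rng = model.rng()
    forces = []
    for x in range(topology.n_sites):
        cn = int(topology.contact_counts[x])
        F = rng.normal(0.0, model.sigma, size=(M, cn))
        norms = np.linalg.norm(F, axis=1)
        while np.any(norms == 0.0):  # probability-zero guard
            bad = norms == 0.0
            F[bad] = rng.normal(0.0, model.sigma, size=(int(bad.sum()), cn))
            norms = np.linalg.norm(F, axis=1)
        F *= (model.sigma * np.sqrt(cn) / norms)[:, None]
        forces.append(F)
    return forces


def sdmrs_compensation(
    covariance: CovarianceMatrix,
    topology: ContactTopology,
    model: ForceModel,
    M: int,
) -> CompensationMatrix:
    """Simulation-based compensation matrix.

    M renormalized forces are drawn once per site and reused across all
    pairs.  For a pair ``(i, j)``,
    ``D_ij = sqrt(mean_mu max_nu (f(i,mu)^T A_ij f(j,nu))^2)``; the
    bilinear overlaps are evaluated in contact space, which is
    algebraically identical to dot products of the full displacement
    fields.  One overlap table per unordered pair serves both ``D_ij``
    and ``D_ji``.  Deterministic given the model seed.
    """
    if int(M) < 1:
        raise InvalidParameterError(f"M must be >= 1, got {M}")
    M = int(M)
    _check_same_structure(covariance, topology)
    n = topology.n_sites
    forces = draw_renormalized_site_forces(topology, model, M)

    Gs, G, starts = _response_basis(covariance, topology)
    D = np.empty((n, n))
    for i in range(n):
        Hi = Gs[i] @ forces[i].T  # (3N, M) displacement fields of i
        tail = G[:, starts[i] :]
        Z = tail.T @ Hi  # rows: A_ij^T f(i,mu) stacked over j >= i
        for j in range(i, n):
            Zj = Z[starts[j] - starts[i] : starts[j + 1] - starts[i]]
            overlaps = np.abs(Zj.T @ forces[j].T)  # (M, M): mu x nu
            D[i, j] = np.sqrt(np.mean(overlaps.max(axis=1) ** 2))
            D[j, i] = np.sqrt(np.mean(overlaps.max(axis=0) ** 2))
    return CompensationMatrix(
        matrix=D,
        meta={
            "method": "sdmrs",
            "sigma": float(model.sigma),
            "M": M,
            "seed": model.seed,
        },
    )


def compensation_profiles(D: CompensationMatrix | np.ndarray) -> MarginalProfiles:
    """D_j (column means; compensating power) and D_i (row means;
    compensability) profiles."""
    return marginal_profiles(D)
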