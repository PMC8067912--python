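"""Single mutation-response scanning: the N x N sensitivity matrix.

``S[i, j]`` is the mean squared displacement of site ``i`` over random
mutations at site ``j``.  Two routes are provided:

* :func:`smrs_sensitivity` — Monte-Carlo average over M sampled
  mutations per site;
* :func:`amrs_sensitivity` — the closed form
  ``S_ij = sigma^2 sum_{jl} |(C_il - C_ij) e_jl|^2``,
  the exact expectation of the simulated estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elastic_network import ContactTopology, CovarianceMatrix
from .errors import InconsistentInputsError, InvalidParameterError
from .mutation_forces import ForceModel


def site_response_columns(
    covariance: CovarianceMatrix, topology: ContactTopology, site: int
) -> np.ndarray:
    """Response basis of a mutated site: a 3N x CN(site) matrix ``G``.

    Column for contact ``jl`` is ``(C_l - C_j) e_jl / kBT`` where
    ``C_x`` is the 3N x 3 column block of the covariance.  The response
    to a mutation with contact scalars ``f`` is then ``G @ f``, exactly
    the linear response to the assembled force vector.
    """
    partners, evecs = topology.contacts_of(site)
    B = covariance.matrix
    n3 = B.shape[0]
    blocks = B.reshape(n3, -1, 3)  # columns grouped by site
    diff = blocks[:, partners, :] - blocks[:, [site], :]
    return np.einsum("ncd,cd->nc", diff, evecs) / covariance.kBT


@dataclass(frozen=True)
class SensitivityMatrix:
    """N x N nonnegative sensitivity values with run metadata.

    Rows index the responding site ``i``, columns the mutated site
    ``j``.  ``meta`` records sigma, method tag and, for simulated
    matrices, ``M`` and the seed.
    """

    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class MarginalProfiles:
    """Row- and column-averaged marginals of a scan matrix.

    ``influence[j]`` is the mean over rows of column ``j`` (average
    effect of mutating ``j``); ``sensitivity[i]`` is the mean over
    columns of row ``i`` (average response of ``i``).  For compensation
    matrices the same averages are the D_j and D_i profiles.
    """

    influence: np.ndarray
    sensitivity: np.ndarray


def amrs_sensitivity(
    covariance: CovarianceMatrix, topology: ContactTopology, sigma: float
) -> SensitivityMatrix:
    """Analytical sensitivity matrix.

    ``S_ij = sigma^2 sum_{jl in C(j)} e_jl^T (C_il - C_ij)^T
    (C_il - C_ij) e_jl`` evaluated through the site column blocks: the
    per-contact response column is computed once and reused for all
    responding sites.
    """
    if topology.n_sites != covariance.n_sites:
        raise InconsistentInputsError(
            "covariance and topology built from different structures"
        )
    n = topology.n_sites
    S = np.empty((n, n))
    for j in range(n):
        G = site_response_columns(covariance, topology, j)
        per_site = (G * G).reshape(n, 3, -1).sum(axis=(1, 2))
        S[:, j] = per_site
    S *= sigma**2
    return SensitivityMatrix(
        matrix=S, meta={"method": "amrs", "sigma": float(sigma)}
    )


def smrs_sensitivity(
    covariance: CovarianceMatrix,
    topology: ContactTopology,
    model: ForceModel,
    M: int,
) -> SensitivityMatrix:
    """Simulation-based sensitivity matrix.

    For each site ``j``, ``M`` mutation forces are drawn (i.i.d. normal
    contact scalars), responses computed by linear response, and squared
    per-site displacements averaged.  Deterministic given the model
    seed; sites consume random draws in site order, mutations within a
    site in draw order.
    """
    if int(M) < 1:
        raise InvalidParameterError(f"M must be >= 1, got {M}")
    M = int(M)
    if topology.n_sites != covariance.n_sites:
        raise InconsistentInputsError(
            "covariance and topology built from different structures"
        )
    n = topology.n_sites
    rng = model.rng()
    S = np.empty((n, n))
    for j in range(n):
        cn = int(topology.contact_counts[j])
        F = rng.normal(0.0, model.sigma, size=(M, cn))
        if model.renormalize:
            norms = np.linalg.norm(F, axis=1)
            while np.any(norms == 0.0):  # probability-zero guard
                bad = norms == 0.0
                F[bad] = rng.normal(0.0, model.sigma, size=(bad.sum(), cn))
                norms = np.linalg.norm(F, axis=1)
            F *= (model.sigma * np.sqrt(cn) / norms)[:, None]
        G = site_response_columns(covariance, topology, j)
        disp = G @ F.T  # (3N, M) response fields
        S[:, j] = (disp * disp).reshape(n, 3, M).sum(axis=1).mean(axis=1)
    return SensitivityMatrix(
        matrix=S,
        meta={
            "method": "smrs",
            "sigma": float(model.sigma),
            "M": M,
            "seed": model.seed,
            "renormalize": model.renormalize,
        },
    )


def marginal_profiles(S: SensitivityMatrix | np.ndarray) -> MarginalProfiles:
    """Row/column mean profiles of a scan matrix."""
    m = S.matrix if hasattr(S, "matrix") else np.asarray(S, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InconsistentInputsError(f"expected square matrix, got {m.shape}")
    return MarginalProfiles(influence=m.mean(axis=0), sensitivity=m.mean(axis=1))
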