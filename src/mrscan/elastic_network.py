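"""Elastic-network machinery: C-alpha structures, contact topology,
Hessian assembly, covariance by pseudo-inversion, and linear response.

The model is the standard anisotropic network: one node per residue at
its C-alpha, harmonic springs of constant ``k`` between all node pairs
within a distance cutoff.  Equilibrium fluctuations are characterized by
``C = kBT * pinv(K)`` where ``K`` is the 3N x 3N Hessian of the network
energy at the native structure.  The linear response of the structure to
a force ``f`` is ``dr = (C / kBT) f``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import (
    ChainNotFoundError,
    DisconnectedNetworkError,
    EmptyStructureError,
    InconsistentInputsError,
    PdbParseError,
    RankDeficiencyError,
)

#: default distance cutoff (Angstrom) defining contacts
DEFAULT_CUTOFF = 12.5
#: relative eigenvalue tolerance separating rigid-body modes from the rest
RIGID_MODE_REL_TOL = 1e-8
#: number of zero modes expected for a connected, non-collinear network
N_RIGID_MODES = 6


@dataclass(frozen=True)
class CAStructure:
    """Ordered C-alpha sites of a structure.

    Parameters
    ----------
    site_ids : tuple of str
        Residue identifiers (chain, residue number, insertion code) in
        file order.  Order is preserved by every downstream matrix.
    coords : ndarray, shape (N, 3)
        Cartesian coordinates in Angstrom.
    """

    site_ids: tuple
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InconsistentInputsError(
                f"coords must have shape (N, 3), got {coords.shape}"
            )
        if len(self.site_ids) != coords.shape[0]:
            raise InconsistentInputsError(
                f"{len(self.site_ids)} site ids for {coords.shape[0]} coordinates"
            )
        if coords.shape[0] < 2:
            raise EmptyStructureError("structure must contain at least 2 sites")
        if not np.all(np.isfinite(coords)):
            raise InconsistentInputsError("non-finite coordinates")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]


def parse_ca_structure(pdb_text: str, chain=None, model: int = 1) -> CAStructure:
    """Extract the C-alpha trace from PDB-format text.

    Only ATOM records named ``CA`` of standard residues are used, one
    site per residue, in file order.  Alternate locations are resolved by
    highest occupancy (ties broken by altloc identifier order).

    Parameters
    ----------
    pdb_text : str
        Content of a PDB file.
    chain : str, optional
        Restrict to one chain; default concatenates all chains in file
        order.
    model : int
        1-based model number (NMR entries); default first model.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb_file = PDBFile.read(_io.StringIO(pdb_text))
        n_models = pdb_file.get_model_count()
        if n_models == 0:
            raise EmptyStructureError("no coordinate records found")
        if not 1 <= model <= n_models:
            raise InconsistentInputsError(
                f"model {model} requested but file has {n_models} model(s)"
            )
        atoms = pdb_file.get_structure(model=model, altloc="occupancy")
    except (ValueError, IndexError, KeyError) as exc:
        raise PdbParseError(f"malformed PDB input: {exc}") from exc

    if chain is not None:
        if chain not in set(atoms.chain_id):
            present = sorted(set(atoms.chain_id))
            raise ChainNotFoundError(
                f"chain {chain!r} not found; present: {present}"
            )
        atoms = atoms[atoms.chain_id == chain]

    # element check guards against calcium ions that are also named CA
    mask = (atoms.atom_name == "CA") & (~atoms.hetero) & (atoms.element == "C")
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise EmptyStructureError("no C-alpha records in selection")

    site_ids = []
    coords = []
    seen = set()
    for at in ca:
        key = (at.chain_id, int(at.res_id), at.ins_code)
        if key in seen:  # duplicate CA within one residue: keep first
            continue
        seen.add(key)
        site_ids.append(f"{at.chain_id}:{int(at.res_id)}{at.ins_code}".rstrip())
        coords.append(at.coord)
    if len(site_ids) < 2:
        raise EmptyStructureError(
            f"only {len(site_ids)} C-alpha site(s); need at least 2"
        )
    return CAStructure(tuple(site_ids), np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class ContactTopology:
    """Contact network of a structure under a distance cutoff.

    ``pairs`` holds each unordered contact once as ``(j, l)`` with
    ``j < l``; ``unit_vectors[c]`` points from ``pairs[c, 0]`` toward
    ``pairs[c, 1]`` and has unit norm.
    """

    cutoff: float
    n_sites: int
    pairs: np.ndarray
    unit_vectors: np.ndarray
    contact_counts: np.ndarray
    _partners: tuple = field(repr=False, default=())
    _partner_vectors: tuple = field(repr=False, default=())

    def contacts_of(self, site: int):
        """Return ``(partners, unit_vectors)`` for one site.

        Partners are sorted by index; each unit vector points from
        ``site`` toward the partner.
        """
        return self._partners[site], self._partner_vectors[site]


def build_contacts(structure: CAStructure, cutoff: float = DEFAULT_CUTOFF) -> ContactTopology:
    """Build the contact topology: all site pairs within ``cutoff``.

    The contact rule is inclusive (distance <= cutoff).  Raises
    :class:`DisconnectedNetworkError` if any site has no contact or the
    contact graph has more than one connected component, since the
    pseudo-inverse rank rule downstream assumes connectivity.
    """
    if not cutoff > 0:
        raise InconsistentInputsError(f"cutoff must be positive, got {cutoff}")
    coords = structure.coords
    n = structure.n_sites
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]

    counts = np.bincount(pairs.ravel(), minlength=n)
    if pairs.size == 0 or counts.min() == 0:
        isolated = np.flatnonzero(counts == 0)
        raise DisconnectedNetworkError(
            f"{isolated.size} site(s) without contacts at cutoff {cutoff}: "
            f"{isolated[:10].tolist()}"
        )
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise DisconnectedNetworkError(
            f"contact graph has {n_comp} components at cutoff {cutoff}"
        )

    diff = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    dist = np.linalg.norm(diff, axis=1)
    unit = diff / dist[:, None]

    partners = [[] for _ in range(n)]
    pvecs = [[] for _ in range(n)]
    for (j, l), e in zip(pairs, unit):
        partners[j].append(l)
        pvecs[j].append(e)
        partners[l].append(j)
        pvecs[l].append(-e)
    part_arrays = []
    vec_arrays = []
    for x in range(n):
        p = np.asarray(partners[x], dtype=int)
        v = np.asarray(pvecs[x], dtype=float)
        order = np.argsort(p)
        part_arrays.append(p[order])
        vec_arrays.append(v[order])

    return ContactTopology(
        cutoff=float(cutoff),
        n_sites=n,
        pairs=pairs,
        unit_vectors=unit,
        contact_counts=counts,
        _partners=tuple(part_arrays),
        _partner_vectors=tuple(vec_arrays),
    )


@dataclass(frozen=True)
class ANMHessian:
    """3N x 3N Hessian of the network energy at the native structure."""

    k: float
    matrix: np.ndarray


def build_hessian(structure: CAStructure, topology: ContactTopology, k: float = 1.0) -> ANMHessian:
    """Assemble the Hessian of the harmonic contact energy.

    For each contact ``jl`` the off-diagonal 3x3 super-element is
    ``-k * e_jl e_jl^T``; diagonal blocks are minus the sum of the
    site's off-diagonal blocks, which makes ``K`` exactly symmetric and
    translation invariant by construction.
    """
    if topology.n_sites != structure.n_sites:
        raise InconsistentInputsError(
            f"topology built for {topology.n_sites} sites, structure has "
            f"{structure.n_sites}"
        )
    n = structure.n_sites
    K = np.zeros((3 * n, 3 * n))
    for (j, l), e in zip(topology.pairs, topology.unit_vectors):
        block = k * np.outer(e, e)
        K[3 * j : 3 * j + 3, 3 * l : 3 * l + 3] -= block
        K[3 * l : 3 * l + 3, 3 * j : 3 * j + 3] -= block
        K[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
        K[3 * l : 3 * l + 3, 3 * l : 3 * l + 3] += block
    return ANMHessian(k=float(k), matrix=K)


@dataclass(frozen=True)
class CovarianceMatrix:
    """Equilibrium covariance ``C = kBT * pinv(K)`` with block accessors."""

    kBT: float
    matrix: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0] // 3

    def pair_block(self, x: int, y: int) -> np.ndarray:
        """3x3 covariance block between sites ``x`` and ``y``."""
        return self.matrix[3 * x : 3 * x + 3, 3 * y : 3 * y + 3]

    def site_columns(self, x: int) -> np.ndarray:
        """3N x 3 block holding the three columns of site ``x``."""
        return self.matrix[:, 3 * x : 3 * x + 3]


def covariance_from_hessian(
    hessian: ANMHessian,
    kBT: float = 1.0,
    rel_tol: float = RIGID_MODE_REL_TOL,
) -> CovarianceMatrix:
    """Pseudo-invert the Hessian: ``C = kBT * K^+``.

    A full symmetric eigendecomposition is used; eigenvalues with
    ``lam <= rel_tol * lam_max`` are treated as rigid-body zeros.
    Exactly six such modes are required — more indicates a degenerate
    (disconnected or collinear) network and raises
    :class:`RankDeficiencyError`.
    """
    K = hessian.matrix
    lam, vec = scipy.linalg.eigh(K)
    lam_max = lam[-1]
    if not lam_max > 0:
        raise RankDeficiencyError("Hessian has no positive eigenvalues")
    zero = lam <= rel_tol * lam_max
    n_zero = int(zero.sum())
    if n_zero != N_RIGID_MODES:
        raise RankDeficiencyError(
            f"expected {N_RIGID_MODES} rigid-body modes, found {n_zero} "
            f"eigenvalues below tolerance {rel_tol * lam_max:.3e}"
        )
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, lam))
    C = (vec * inv) @ vec.T * kBT
    C = (C + C.T) / 2.0
    return CovarianceMatrix(kBT=float(kBT), matrix=C)


@dataclass(frozen=True)
class DisplacementField:
    """3N displacement vector with per-site accessor."""

    vector: np.ndarray

    def site(self, i: int) -> np.ndarray:
        return self.vector[3 * i : 3 * i + 3]

    def per_site_sq_norm(self) -> np.ndarray:
        """Squared displacement magnitude of each site."""
        v = self.vector.reshape(-1, 3)
        return np.einsum("id,id->i", v, v)


def linear_response(covariance: CovarianceMatrix, force: np.ndarray) -> DisplacementField:
    """Structural response to a force: ``dr = (C / kBT) f``."""
    force = np.asarray(force, dtype=float)
    if force.shape != (covariance.matrix.shape[0],):
        raise InconsistentInputsError(
            f"force has shape {force.shape}, expected "
            f"({covariance.matrix.shape[0]},)"
        )
    return DisplacementField(vector=(covariance.matrix @ force) / covariance.kBT)
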