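import itertools
from pathlib import Path

import numpy as np
import pytest

from mrscan import (
    CAStructure,
    FixtureSpec,
    build_contacts,
    build_hessian,
    covariance_from_hessian,
    generate_helix,
    linear_response,
    parse_ca_structure,
    write_fixture_pdb,
)
from mrscan.errors import (
    ChainNotFoundError,
    DisconnectedNetworkError,
    EmptyStructureError,
    InconsistentInputsError,
    RankDeficiencyError,
)

DATA_DIR = Path(__file__).resolve().parents[1] / "data" / "structures"


def _collinear(n=10, spacing=3.8):
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return CAStructure(tuple(f"A:{i+1}" for i in range(n)), coords)


class TestParse:
    def test_fixture_round_trip(self):
        structure = generate_helix(FixtureSpec(n_sites=5))
        text = write_fixture_pdb(structure)
        parsed = parse_ca_structure(text)
        assert parsed.n_sites == 5
        np.testing.assert_allclose(parsed.coords, structure.coords, atol=5e-4)

    def test_hetatm_only_is_empty(self):
        text = (
            "HETATM    1  O   HOH A   1      11.000  12.000  13.000  1.00  0.00           O\n"
            "HETATM    2  O   HOH A   2      14.000  12.000  13.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(EmptyStructureError):
            parse_ca_structure(text)

    def test_unknown_chain(self):
        text = write_fixture_pdb(generate_helix(FixtureSpec(n_sites=5)))
        with pytest.raises(ChainNotFoundError):
            parse_ca_structure(text, chain="Q")

    def test_chain_selection_and_concatenation(self):
        def atom(serial, res, chain, x):
            return (
                f"ATOM  {serial:5d}  CA  GLY {chain}{res:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )

        lines = [atom(i + 1, i + 1, "A", 3.8 * i) for i in range(3)]
        lines += [atom(i + 4, i + 1, "B", 100.0 + 3.8 * i) for i in range(2)]
        text = "\n".join(lines) + "\nEND\n"
        both = parse_ca_structure(text)
        assert both.n_sites == 5
        only_a = parse_ca_structure(text, chain="A")
        assert only_a.n_sites == 3
        assert all(sid.startswith("A:") for sid in only_a.site_ids)

    def test_first_model_default(self):
        base = write_fixture_pdb(generate_helix(FixtureSpec(n_sites=4)))
        atoms = [l for l in base.splitlines() if l.startswith("ATOM")]
        shifted = [f"{l[:30]}{float(l[30:38]) + 50.0:8.3f}{l[38:]}" for l in atoms]
        text = (
            "MODEL        1\n" + "\n".join(atoms) + "\nENDMDL\n"
            "MODEL        2\n" + "\n".join(shifted) + "\nENDMDL\nEND\n"
        )
        first = parse_ca_structure(text)
        second = parse_ca_structure(text, model=2)
        np.testing.assert_allclose(second.coords[:, 0] - first.coords[:, 0], 50.0, atol=1e-3)
        with pytest.raises(InconsistentInputsError):
            parse_ca_structure(text, model=3)

    def test_altloc_highest_occupancy(self):
        def atom(serial, res, alt, occ, x):
            return (
                f"ATOM  {serial:5d}  CA {alt}GLY A{res:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{occ:6.2f}  0.00           C"
            )

        text = "\n".join(
            [
                atom(1, 1, "A", 0.4, 0.0),
                atom(2, 1, "B", 0.6, 9.0),
                atom(3, 2, " ", 1.0, 3.8),
            ]
        ) + "\nEND\n"
        parsed = parse_ca_structure(text)
        assert parsed.n_sites == 2
        assert parsed.coords[0, 0] == pytest.approx(9.0, abs=1e-3)

    @pytest.mark.skipif(
        not (DATA_DIR / "2ACY.pdb").exists(),
        reason="structure file data/structures/2ACY.pdb not available offline",
    )
    def test_2acy_site_count(self):
        text = (DATA_DIR / "2ACY.pdb").read_text()
        parsed = parse_ca_structure(text, chain="A")
        assert parsed.n_sites == 98


class TestContacts:
    def test_unit_square_all_pairs(self):
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float
        )
        structure = CAStructure(("a", "b", "c", "d"), coords)
        topo = build_contacts(structure, 1.5)
        # brute-force oracle
        expected = {
            (i, j)
            for i, j in itertools.combinations(range(4), 2)
            if np.linalg.norm(coords[j] - coords[i]) <= 1.5
        }
        assert {tuple(p) for p in topo.pairs} == expected
        assert len(expected) == 6
        assert np.all(topo.contact_counts == 3)

    def test_far_pair_disconnected(self):
        structure = CAStructure(
            ("a", "b"), np.array([[0.0, 0, 0], [20.0, 0, 0]])
        )
        with pytest.raises(DisconnectedNetworkError):
            build_contacts(structure, 12.5)

    def test_two_clusters_disconnected(self):
        helix = generate_helix(FixtureSpec(n_sites=6)).coords
        coords = np.vstack([helix, helix + [200.0, 0, 0]])
        structure = CAStructure(tuple(map(str, range(12))), coords)
        with pytest.raises(DisconnectedNetworkError):
            build_contacts(structure, 12.5)

    def test_collinear_chain_interior_cn(self):
        topo = build_contacts(_collinear(10, 3.8), 12.5)
        # brute-force: neighbors at 3.8, 7.6, 11.4 qualify; 15.2 does not
        for site in range(3, 7):
            assert topo.contact_counts[site] == 6

    def test_unit_vectors(self, topo12):
        norms = np.linalg.norm(topo12.unit_vectors, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        for site in range(topo12.n_sites):
            partners, evecs = topo12.contacts_of(site)
            assert list(partners) == sorted(partners)
            for partner, e in zip(partners, evecs):
                back_partners, back_vecs = topo12.contacts_of(partner)
                idx = list(back_partners).index(site)
                np.testing.assert_allclose(back_vecs[idx], -e, atol=1e-12)

    def test_permutation_invariance(self, helix12):
        topo = build_contacts(helix12, 12.5)
        rng = np.random.default_rng(7)
        perm = rng.permutation(helix12.n_sites)
        permuted = CAStructure(
            tuple(helix12.site_ids[p] for p in perm), helix12.coords[perm]
        )
        topo_p = build_contacts(permuted, 12.5)
        inv = np.argsort(perm)
        relabeled = {tuple(sorted((inv[j], inv[l]))) for j, l in topo.pairs}
        assert {tuple(p) for p in topo_p.pairs} == relabeled
        np.testing.assert_array_equal(topo_p.contact_counts, topo.contact_counts[perm])


def _anm_energy(coords_flat, ref, pairs, k):
    r = coords_flat.reshape(-1, 3)
    e = 0.0
    for j, l in pairs:
        d = np.linalg.norm(r[l] - r[j])
        d0 = np.linalg.norm(ref[l] - ref[j])
        e += 0.5 * k * (d - d0) ** 2
    return e


class TestHessian:
    def test_translation_invariance(self, helix12, topo12):
        K = build_hessian(helix12, topo12, k=1.0).matrix
        n = helix12.n_sites
        for axis in range(3):
            t = np.zeros(3 * n)
            t[axis::3] = 1.0
            np.testing.assert_allclose(K @ t, 0.0, atol=1e-10)

    def test_finite_difference_oracle_two_sites(self):
        coords = np.array([[0.0, 0, 0], [2.1, 2.9, 1.1]])
        structure = CAStructure(("a", "b"), coords)
        topo = build_contacts(structure, 5.0)
        K = build_hessian(structure, topo, k=1.0).matrix
        x0 = coords.ravel()
        h = 1e-5
        K_fd = np.zeros((6, 6))
        for a in range(6):
            for b in range(6):
                for sa, sb, w in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
                    x = x0.copy()
                    x[a] += sa * h
                    x[b] += sb * h
                    K_fd[a, b] += w * _anm_energy(x, coords, topo.pairs, 1.0)
        K_fd /= 4 * h * h
        assert np.linalg.norm(K_fd - K) / np.linalg.norm(K) < 1e-6

    def test_exact_symmetry(self, helix12, topo12):
        K = build_hessian(helix12, topo12, k=2.5).matrix
        assert np.array_equal(K, K.T)

    def test_size_mismatch(self, topo12):
        other = generate_helix(FixtureSpec(n_sites=8))
        with pytest.raises(InconsistentInputsError):
            build_hessian(other, topo12)

    def test_positive_semidefinite(self, helix12, topo12):
        K = build_hessian(helix12, topo12, k=1.0).matrix
        lam = np.linalg.eigvalsh(K)
        assert lam.min() > -1e-10


class TestCovariance:
    def test_pseudo_inverse_identities(self, helix12, topo12):
        hessian = build_hessian(helix12, topo12, k=1.0)
        kBT = 1.7
        cov = covariance_from_hessian(hessian, kBT=kBT)
        K, C = hessian.matrix, cov.matrix
        assert np.linalg.norm(K @ C @ K - kBT * K) / np.linalg.norm(K) < 1e-8
        assert np.linalg.norm(C @ K @ C - kBT * C) / np.linalg.norm(C) < 1e-8

    def test_exactly_six_zero_modes(self, helix12, topo12):
        K = build_hessian(helix12, topo12, k=1.0).matrix
        lam = np.sort(np.linalg.eigvalsh(K))
        tol = 1e-8 * lam[-1]
        assert np.sum(lam < tol) == 6
        assert lam[6] > 1e3 * tol

    def test_rigid_null_space(self, helix12, topo12, cov12):
        n = helix12.n_sites
        t = np.zeros(3 * n)
        t[0::3] = 1.0
        np.testing.assert_allclose(cov12.matrix @ t, 0.0, atol=1e-10)

    def test_doubling_k_halves_C(self, helix12, topo12):
        c1 = covariance_from_hessian(build_hessian(helix12, topo12, k=1.0)).matrix
        c2 = covariance_from_hessian(build_hessian(helix12, topo12, k=2.0)).matrix
        np.testing.assert_allclose(c2, c1 / 2.0, rtol=1e-10, atol=1e-12)

    def test_lstsq_column_oracle(self, helix12, topo12, cov12):
        # independent solver: min-norm least squares column by column
        K = build_hessian(helix12, topo12, k=1.0).matrix
        rng = np.random.default_rng(2)
        for col in rng.integers(0, K.shape[0], size=5):
            b = np.zeros(K.shape[0])
            b[col] = 1.0
            x, *_ = np.linalg.lstsq(K, b, rcond=1e-10)
            np.testing.assert_allclose(cov12.matrix[:, col], x, atol=1e-6)

    def test_collinear_is_rank_deficient(self):
        structure = _collinear(10, 3.8)
        topo = build_contacts(structure, 12.5)
        hessian = build_hessian(structure, topo, k=1.0)
        with pytest.raises(RankDeficiencyError):
            covariance_from_hessian(hessian)

    def test_symmetry(self, cov12):
        assert np.array_equal(cov12.matrix, cov12.matrix.T)

    def test_block_accessors(self, cov12):
        np.testing.assert_array_equal(
            cov12.pair_block(2, 5), cov12.matrix[6:9, 15:18]
        )
        np.testing.assert_array_equal(
            cov12.site_columns(3), cov12.matrix[:, 9:12]
        )


class TestLinearResponse:
    def test_zero_force(self, cov12):
        disp = linear_response(cov12, np.zeros(cov12.matrix.shape[0]))
        assert np.all(disp.vector == 0.0)

    def test_linearity(self, cov12):
        rng = np.random.default_rng(0)
        f = rng.normal(size=cov12.matrix.shape[0])
        d1 = linear_response(cov12, f).vector
        d3 = linear_response(cov12, 3.0 * f).vector
        np.testing.assert_allclose(d3, 3.0 * d1, rtol=1e-12)

    def test_length_mismatch(self, cov12):
        with pytest.raises(InconsistentInputsError):
            linear_response(cov12, np.zeros(5))

    def test_energy_minimizer_oracle(self, helix12, topo12, cov12):
        # response equals the min-norm minimizer of 1/2 x^T K x - f^T x
        K = build_hessian(helix12, topo12, k=1.0).matrix
        partners, evecs = topo12.contacts_of(0)
        f = np.zeros(3 * helix12.n_sites)
        f[3 * partners[0] : 3 * partners[0] + 3] = evecs[0]
        f[0:3] = -evecs[0]
        x, *_ = np.linalg.lstsq(K, f, rcond=1e-10)
        np.testing.assert_allclose(linear_response(cov12, f).vector, x, atol=1e-6)
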