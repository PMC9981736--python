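import math

import numpy as np
import pytest

from relay.structure_io import Selection, Structure
from relay.superpose import (
    ConvergenceError,
    GeometryError,
    ResiduePairing,
    RigidTransform,
    SuperpositionResult,
    apply_transform,
    iterative_superpose,
    kabsch_fit,
    match_residues,
)
from relay.synthetic_data import make_helix_domain, random_rigid_transform, rng_for

from conftest import atom


def rot_z(deg):
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


@pytest.fixture
def cloud():
    return rng_for(7, "cloud").normal(size=(20, 3)) * 5.0


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError, match="det"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_inverse_roundtrip(self, cloud):
        tr = random_rigid_transform(rng_for(1, "t"))
        back = tr.inverse().apply(tr.apply(cloud))
        assert np.allclose(back, cloud, atol=1e-9)

    def test_compose(self, cloud):
        t1 = random_rigid_transform(rng_for(2, "a"))
        t2 = random_rigid_transform(rng_for(2, "b"))
        assert np.allclose(
            t2.compose(t1).apply(cloud), t2.apply(t1.apply(cloud)), atol=1e-9
        )


class TestKabsch:
    def test_identity(self, cloud):
        res = kabsch_fit(cloud, cloud)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(res.transform.translation, 0.0, atol=1e-9)
        assert res.n_retained == len(cloud)

    def test_recovers_known_transform(self, cloud):
        moved = cloud @ rot_z(90).T + np.array([1.0, 2.0, 3.0])
        res = kabsch_fit(moved, cloud)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transform.apply(moved), cloud, atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(GeometryError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_fit(line, line)

    def test_unequal_lengths(self, cloud):
        with pytest.raises(GeometryError, match="differ"):
            kabsch_fit(cloud, cloud[:-1])

    def test_noise_rmsd_montecarlo(self):
        # Monte-Carlo oracle: with sigma=0.5 Å isotropic noise on n=50
        # points, the fitted rmsd concentrates near sigma*sqrt(3) ~ 0.87 Å.
        rng = rng_for(11, "mc")
        rmsds = []
        for _ in range(100):
            pts = rng.normal(size=(50, 3)) * 8.0
            noisy = pts + rng.normal(scale=0.5, size=pts.shape)
            rmsds.append(kabsch_fit(noisy, pts).rmsd)
        assert 0.6 <= min(rmsds) and max(rmsds) <= 1.1

    def test_rmsd_symmetry(self, cloud):
        other = cloud + rng_for(3, "n").normal(scale=1.0, size=cloud.shape)
        assert kabsch_fit(cloud, other).rmsd == pytest.approx(
            kabsch_fit(other, cloud).rmsd, abs=1e-9
        )

    def test_transform_invariance(self, cloud):
        other = cloud + rng_for(4, "n").normal(scale=1.0, size=cloud.shape)
        base = kabsch_fit(cloud, other).rmsd
        pre = random_rigid_transform(rng_for(5, "pre"))
        assert kabsch_fit(pre.apply(cloud), other).rmsd == pytest.approx(base, abs=1e-9)

    def test_optimality_vs_rotation_grid(self):
        # brute-force oracle: no rotation on a coarse SO(3) grid (with the
        # optimal translation for that rotation) beats the Kabsch fit
        rng = rng_for(13, "grid")
        for trial in range(5):
            n = int(rng.integers(4, 7))
            P = rng.normal(size=(n, 3))
            Q = rng.normal(size=(n, 3))
            res = kabsch_fit(P, Q)
            best = np.inf
            angles = np.radians(np.arange(0, 360, 20))
            betas = np.radians(np.arange(0, 181, 20))
            for a in angles:
                for b in betas:
                    for g in angles:
                        R = rot_zyz(a, b, g)
                        RP = P @ R.T
                        t = Q.mean(axis=0) - RP.mean(axis=0)
                        r = np.sqrt(np.mean(np.sum((RP + t - Q) ** 2, axis=1)))
                        best = min(best, r)
            assert best >= res.rmsd - 1e-9


def rot_zyz(a, b, g):
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return Rz1 @ Ry @ Rz2


def peptide(seq: str, chain="A", start=1):
    """CA-only structure spelling the given sequence along x."""
    from relay.structure_io import THREE_TO_ONE

    one_to_three = {v: k for k, v in THREE_TO_ONE.items() if k not in ("MSE",)}
    atoms = []
    for i, ch in enumerate(seq):
        atoms.append(atom(
            chain, start + i, "CA", (3.8 * i, (i % 3) * 0.5, 0.0),
            resname=one_to_three[ch],
        ))
    return Structure(atoms=atoms, id=f"pep_{seq}")


class TestMatchResidues:
    def test_identical_sequences(self):
        a = peptide("ACDEFGHIK")
        b = peptide("ACDEFGHIK", start=101)
        pairing = match_residues(a, b, mode="sequence")
        assert len(pairing.pairs) == 9
        assert pairing.pairs[0] == (("A", 1, ""), ("A", 101, ""))

    def test_deletion_leaves_residue_unpaired(self):
        # hand alignment: ACDEFG vs AC-EFG pairs 5 columns, D unpaired
        a = peptide("ACDEFG")
        b = peptide("ACEFG")
        pairing = match_residues(a, b, mode="sequence")
        assert len(pairing.pairs) == 5
        paired_a = {p[0][1] for p in pairing.pairs}
        assert 3 not in paired_a  # D at residue 3 is unpaired

    def test_ranges_mode_offset(self):
        a = peptide("AAAAAAAAAAAAAAA", start=10)
        b = peptide("AAAAAAAAAAAAAAA", start=110)
        pairing = match_residues(
            a, b, mode="ranges", ranges_a=[(10, 20)], ranges_b=[(110, 120)]
        )
        assert len(pairing.pairs) == 11
        for (_, ra, _), (_, rb, _) in pairing.pairs:
            assert rb - ra == 100

    def test_ranges_mode_unequal_lengths(self):
        a = peptide("AAAAAAAAAA")
        b = peptide("AAAAAAAAAA", start=101)
        with pytest.raises(ValueError, match="unequal"):
            match_residues(a, b, mode="ranges",
                           ranges_a=[(1, 5)], ranges_b=[(101, 108)])

    def test_empty_selection(self):
        a = peptide("ACDE")
        b = peptide("ACDE")
        with pytest.raises(ValueError, match="empty"):
            match_residues(a, b, sel_a=Selection(chains={"Z"}, atom_class="CA"))


class TestResiduePairing:
    def test_duplicate_residue_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            ResiduePairing([
                (("A", 1, ""), ("B", 1, "")),
                (("A", 1, ""), ("B", 2, "")),
            ])


class TestIterativeSuperpose:
    def _pairing(self, a, b):
        ids_a = [x.residue_id for x in a.atoms if x.atom == "CA"]
        ids_b = [x.residue_id for x in b.atoms if x.atom == "CA"]
        return ResiduePairing(list(zip(ids_a, ids_b)))

    def test_exact_fit_no_pruning(self):
        a = make_helix_domain(12)
        tr = random_rigid_transform(rng_for(21, "t"))
        b = apply_transform(a, tr)
        res = iterative_superpose(a, b, self._pairing(a, b))
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_iterations == 1
        assert res.n_retained == 12

    def test_outliers_pruned(self):
        rng = rng_for(22, "o")
        base = rng.normal(size=(22, 3)) * 6.0
        moved = base.copy()
        moved[20] += [10.0, 0, 0]
        moved[21] += [0, 10.0, 0]
        a = Structure(atoms=[atom("A", i + 1, "CA", base[i]) for i in range(22)])
        b = Structure(atoms=[atom("B", i + 1, "CA", moved[i]) for i in range(22)])
        res = iterative_superpose(a, b, self._pairing(a, b))
        assert res.n_retained == 20
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rmsd_nonincreasing_over_iterations(self):
        rng = rng_for(23, "m")
        base = rng.normal(size=(40, 3)) * 6.0
        noisy = base + rng.normal(scale=1.0, size=base.shape)
        noisy[::7] += rng.normal(scale=6.0, size=noisy[::7].shape)
        a = Structure(atoms=[atom("A", i + 1, "CA", base[i]) for i in range(40)])
        b = Structure(atoms=[atom("B", i + 1, "CA", noisy[i]) for i in range(40)])
        rmsds = []
        for it in range(1, 6):
            res = iterative_superpose(a, b, self._pairing(a, b),
                                      {"max_iter": it})
            rmsds.append(res.rmsd)
        assert all(r2 <= r1 + 1e-12 for r1, r2 in zip(rmsds, rmsds[1:]))

    def test_stored_rmsd_reproducible(self):
        rng = rng_for(24, "r")
        base = rng.normal(size=(15, 3)) * 5.0
        noisy = base + rng.normal(scale=0.8, size=base.shape)
        a = Structure(atoms=[atom("A", i + 1, "CA", base[i]) for i in range(15)])
        b = Structure(atoms=[atom("B", i + 1, "CA", noisy[i]) for i in range(15)])
        res = iterative_superpose(a, b, self._pairing(a, b))
        kept_a = np.array([base[p[0][1] - 1] for p in res.retained_pairs.pairs])
        kept_b = np.array([noisy[p[1][1] - 1] for p in res.retained_pairs.pairs])
        refit = kabsch_fit(kept_a, kept_b)
        assert refit.rmsd == pytest.approx(res.rmsd, abs=1e-6)

    def test_prune_below_three_raises(self):
        # three wildly scattered pairs cannot survive a tight absolute cutoff
        rng = rng_for(25, "x")
        base = rng.normal(size=(4, 3)) * 3.0
        far = base + rng.normal(scale=30.0, size=base.shape)
        a = Structure(atoms=[atom("A", i + 1, "CA", base[i]) for i in range(4)])
        b = Structure(atoms=[atom("B", i + 1, "CA", far[i]) for i in range(4)])
        with pytest.raises((ConvergenceError, GeometryError)):
            iterative_superpose(
                a, b, self._pairing(a, b),
                {"cutoff_factor": 0.01, "abs_cutoff": 0.01, "max_iter": 10},
            )


class TestApplyTransform:
    def test_identity_bitwise(self, tripeptide):
        out = apply_transform(tripeptide, RigidTransform.identity())
        assert np.allclose(out.coords(), tripeptide.coords(), atol=0.0)

    def test_translation_composition(self, tripeptide):
        t1 = RigidTransform(np.eye(3), np.array([1.0, 0, 0]))
        t2 = RigidTransform(np.eye(3), np.array([2.0, 0, 0]))
        twice = apply_transform(apply_transform(tripeptide, t1), t1)
        once = apply_transform(tripeptide, t2)
        assert np.allclose(twice.coords(), once.coords(), atol=0.0)

    def test_inverse_restores(self, tripeptide):
        tr = random_rigid_transform(rng_for(31, "z"))
        back = apply_transform(apply_transform(tripeptide, tr), tr.inverse())
        assert np.allclose(back.coords(), tripeptide.coords(), atol=1e-9)

    def test_non_coordinate_fields_unchanged(self, tripeptide):
        tr = random_rigid_transform(rng_for(32, "z"))
        out = apply_transform(tripeptide, tr)
        for a, b in zip(tripeptide.atoms, out.atoms):
            assert (a.chain, a.resseq, a.atom, a.bfactor) == \
                   (b.chain, b.resseq, b.atom, b.bfactor)
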