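"""Structural feature accumulation, PSSM parsing, interface propensity,
and 81-dimension assembly."""

import numpy as np
import pytest

from patchbind.clustering import RepresentativeSet
from patchbind.features import (AA_ORDER, PSSM_COLUMNS, STRUCTURAL_COLUMNS,
                                assemble_features, compute_propensity,
                                feature_columns, load_pssm,
                                structural_features)
from patchbind.fixtures import (FixtureSpec, load_benchmark,
                                make_planted_patches, make_pseudo_pssm)
from patchbind.patches import build_patches
from patchbind.structure import (AtomRecord, ComplexModel, ResidueModel,
                                 annotate_complex)
from patchbind.superposition import Patch, structural_similarity

from conftest import random_rigid
from test_patches import compact_residue, manual_index


def small_reps(rng, n3=3, n2=2):
    reps3 = [Patch(rng.normal(size=(3, 5, 3)) * 3) for _ in range(n3)]
    reps2 = [Patch(rng.normal(size=(2, 5, 3)) * 3) for _ in range(n2)]
    return RepresentativeSet(reps_3aa=reps3, reps_2aa=reps2)


class TestStructuralFeatures:
    def neighborhood(self, k):
        center = compact_residue(0, (0, 0, 0))
        others = [compact_residue(i + 1,
                                  2.5 * np.array([np.cos(2 * np.pi * i / max(k, 1)),
                                                  np.sin(2 * np.pi * i / max(k, 1)),
                                                  0.0]))
                  for i in range(k)]
        cm = ComplexModel("x", {"A": [center] + others})
        index = manual_index([center] + others)
        return center, index

    def test_k0_featureless(self, rng):
        center, index = self.neighborhood(0)
        sf = structural_features(center, index, small_reps(rng))
        assert sf.featureless
        assert np.all(sf.f == 0)

    def test_k1_uses_only_2aa_block(self, rng):
        reps = small_reps(rng)
        center, index = self.neighborhood(1)
        sf = structural_features(center, index, reps)
        assert not sf.featureless
        assert np.all(sf.f[:reps.n3] == 0)
        (patch,) = build_patches(center, index)
        for j, rep in enumerate(reps.reps_2aa):
            d, _ = structural_similarity(patch, rep)
            assert sf.f[reps.n3 + j] == pytest.approx(d, abs=1e-9)

    def test_k1_zero_against_matching_representative(self, rng):
        center, index = self.neighborhood(1)
        (patch,) = build_patches(center, index)
        reps = small_reps(rng)
        reps.reps_2aa[1] = Patch(patch.points.copy())
        sf = structural_features(center, index, reps)
        assert sf.f[reps.n3 + 1] == 0.0
        assert np.all(sf.f[:reps.n3] == 0)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_k_ge_2_accumulates_over_patches(self, rng, k):
        reps = small_reps(rng)
        center, index = self.neighborhood(k)
        patches = build_patches(center, index)
        assert len(patches) == k * (k - 1) // 2
        sf = structural_features(center, index, reps)
        assert sf.K == len(patches)
        assert np.all(sf.f[reps.n3:] == 0)  # 2-aa block zero
        for j, rep in enumerate(reps.reps_3aa):
            expected = sum(structural_similarity(p, rep)[0] for p in patches)
            assert sf.f[j] == pytest.approx(expected, abs=1e-7)

    def test_exactly_one_block_nonzero(self, rng):
        reps = small_reps(rng)
        for k in (1, 2, 3):
            center, index = self.neighborhood(k)
            sf = structural_features(center, index, reps)
            block3 = sf.f[:reps.n3].sum()
            block2 = sf.f[reps.n3:].sum()
            assert (block3 == 0) != (block2 == 0)

    def test_rigid_invariance(self, rng):
        reps = small_reps(rng)
        center, index = self.neighborhood(3)
        f0 = structural_features(center, index, reps).f
        rot, t = random_rigid(rng)
        for res in index.residue_map.values():
            res.shape_points = res.shape_points @ rot.T + t
        f1 = structural_features(center, index, reps).f
        np.testing.assert_allclose(f1, f0, atol=1e-6)

    def test_monotone_degradation_with_noise(self):
        """Median d_SS to the exact motif grows with jitter level."""
        exact = make_planted_patches("linear", 1, 0.0, seed=0)[0]
        medians = []
        for sigma in (0.0, 0.2, 0.5, 1.0):
            pats = make_planted_patches("linear", 30, sigma, seed=42)
            ds = [structural_similarity(p, exact)[0] for p in pats]
            medians.append(np.median(ds))
        assert all(a <= b + 1e-12 for a, b in zip(medians, medians[1:]))


class TestPssm:
    def test_round_trip(self):
        seq = "ACDEFGHIKLMN"
        text = make_pseudo_pssm(seq, seed=3)
        profile = load_pssm(text, expected_sequence=seq)
        assert profile.shape == (12, 20)
        profile2 = load_pssm(make_pseudo_pssm(seq, seed=3))
        np.testing.assert_array_equal(profile, profile2)

    def test_sequence_mismatch_names_position(self):
        seq = "ACDEFGHIKLMN"
        text = make_pseudo_pssm(seq, seed=3)
        wrong = seq[:4] + "W" + seq[5:]
        with pytest.raises(ValueError, match=r"\[5\]"):
            load_pssm(text, expected_sequence=wrong)

    def test_malformed_text_rejected(self):
        with pytest.raises(ValueError, match="no matrix rows"):
            load_pssm("this is not a PSSM\n")
        bad = "    1 A    1   2   3\n"
        with pytest.raises(ValueError, match="need 20"):
            load_pssm(bad)

    def test_substitution_stub_rows(self):
        """At noise 0 the row for a letter equals the stub's row."""
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        profile = load_pssm(make_pseudo_pssm("AAW", seed=0, noise=0))
        np.testing.assert_array_equal(profile[0], profile[1])
        expected_a = [int(blosum["A"][b]) for b in AA_ORDER]
        np.testing.assert_array_equal(profile[0], expected_a)
        expected_w = [int(blosum["W"][b]) for b in AA_ORDER]
        np.testing.assert_array_equal(profile[2], expected_w)


class TestPropensity:
    @staticmethod
    def stub_complex(surface_types, binding_types):
        residues = []
        for i, aa in enumerate(surface_types):
            residues.append(ResidueModel(
                chain_id="A", seq_index=str(i + 1), aa_type=aa,
                atoms=[AtomRecord("CA", "C", (float(i), 0, 0))],
                sasa=1.0, is_surface=True,
                is_binding=i < len(binding_types) and binding_types[i]))
        return ComplexModel("x", {"A": residues})

    def test_hand_arithmetic(self):
        # 10 surface (5 R, 5 L); interface {4 R, 1 L}; alpha=0
        surface = ["R"] * 5 + ["L"] * 5
        binding = [True] * 4 + [False] + [True] + [False] * 4
        cm = self.stub_complex(surface, binding)
        prop = compute_propensity([cm], alpha=0.0)
        assert prop["R"] == pytest.approx((4 / 5) / (5 / 10))
        assert prop["L"] == pytest.approx((1 / 5) / (5 / 10))

    def test_equal_compositions_give_unity(self):
        cm = self.stub_complex(["A", "R", "A", "R"],
                               [True, True, False, False])
        prop = compute_propensity([cm], alpha=0.0)
        assert prop["A"] == pytest.approx(1.0)
        assert prop["R"] == pytest.approx(1.0)

    def test_smoothing_keeps_absent_types_finite(self):
        cm = self.stub_complex(["A", "A", "R"], [True, False, False])
        prop = compute_propensity([cm], alpha=1.0)
        for aa in AA_ORDER:
            assert np.isfinite(prop[aa]) and prop[aa] > 0

    def test_frequency_weighted_identity(self):
        """alpha=0: interface-frequency-weighted propensities average to 1."""
        rng = np.random.default_rng(0)
        surface = list(rng.choice(list(AA_ORDER), size=60))
        binding = list(rng.random(60) < 0.4)
        cm = self.stub_complex(surface, binding)
        prop = compute_propensity([cm], alpha=0.0)
        n_int = {a: 0 for a in AA_ORDER}
        n_surf = {a: 0 for a in AA_ORDER}
        for aa, b in zip(surface, binding):
            n_surf[aa] += 1
            if b:
                n_int[aa] += 1
        tot_surf = sum(n_surf.values())
        weighted = sum((n_surf[a] / tot_surf) * prop[a] for a in AA_ORDER)
        assert weighted == pytest.approx(1.0, abs=1e-12)

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compute_propensity([])


@pytest.fixture(scope="module")
def small_world():
    spec = FixtureSpec(n_proteins=4, residues_per_protein=22, seed=11)
    complexes, pssms, truths = load_benchmark(spec)
    for cm in complexes:
        annotate_complex(cm)
    return complexes, pssms, truths


class TestAssembly:

    def test_dimensions_and_provenance(self, small_world, rng):
        complexes, pssms, truths = small_world
        reps = small_reps(rng, n3=40, n2=20)
        prop = compute_propensity(complexes)
        frame = assemble_features(complexes, reps, pssms, prop)
        assert len(feature_columns()) == 81
        assert len(STRUCTURAL_COLUMNS) == 60
        assert len(PSSM_COLUMNS) == 20
        assert set(feature_columns()).issubset(frame.columns)
        # 22 residues/protein: 7 triads + 1 lone (featureless, excluded)
        expected = sum(len(t) - (t["role"] == "lone").sum()
                       for t in truths.values())
        assert len(frame) == expected
        keys = frame[["source_id", "chain_id", "seq_index"]]
        assert not keys.duplicated().any()

    def test_pssm_values_injected(self, small_world, rng):
        complexes, pssms, truths = small_world
        reps = small_reps(rng)
        prop = compute_propensity(complexes)
        frame = assemble_features(complexes[:1], reps, pssms, prop)
        sid = complexes[0].source_id
        profile = pssms[(sid, "A")]
        row = frame.iloc[0]
        pos = int(row["seq_index"]) - 1
        np.testing.assert_array_equal(
            row[PSSM_COLUMNS].to_numpy(dtype=float), profile[pos])
        assert row["propensity"] == prop[row["aa_type"]]

    def test_missing_pssm_names_chain(self, small_world, rng):
        complexes, pssms, _ = small_world
        reps = small_reps(rng)
        prop = compute_propensity(complexes)
        with pytest.raises(KeyError, match="'A'"):
            assemble_features(complexes[:1], reps, {}, prop)
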