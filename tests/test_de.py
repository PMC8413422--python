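"""DE engine: probe collapsing, fold changes, de-standardization, ternarization."""

import numpy as np
import pandas as pd
import pytest

from cmapbench.de import (
    collapse_probes,
    compute_fc_profiles,
    compute_mzs_profiles,
    count_de_genes,
    destandardize_mzs,
    select_representative_profiles,
    ternarize,
)
from cmapbench.synth import dose_scaling, generate_ground_truth, simulate_corpus


class TestCollapseProbes:
    def test_max_magnitude_probe_wins_sign_preserved(self):
        mat = pd.DataFrame({"p1": {"a": 0.5, "b": -2.0}}).T
        mat = pd.DataFrame([[0.5], [-2.0]], index=["pA", "pB"], columns=["prof1"])
        out = collapse_probes(mat, {"pA": {"G"}, "pB": {"G"}})
        assert out.loc["G", "prof1"] == -2.0

    def test_selection_is_per_profile(self):
        mat = pd.DataFrame(
            [[3.0, -0.1], [-1.0, 2.5]], index=["pA", "pB"], columns=["prof1", "prof2"]
        )
        out = collapse_probes(mat, {"pA": {"G"}, "pB": {"G"}})
        assert out.loc["G", "prof1"] == 3.0
        assert out.loc["G", "prof2"] == 2.5

    def test_multi_gene_probes_removed(self):
        mat = pd.DataFrame([[9.0], [1.0]], index=["pMulti", "pB"], columns=["prof1"])
        out = collapse_probes(mat, {"pMulti": {"G1", "G2"}, "pB": {"G1"}})
        assert list(out.index) == ["G1"]
        assert out.loc["G1", "prof1"] == 1.0

    def test_one_probe_per_gene_is_identity(self):
        mat = pd.DataFrame(
            np.arange(6.0).reshape(3, 2), index=["p1", "p2", "p3"], columns=["x", "y"]
        )
        out = collapse_probes(mat, {"p1": {"g1"}, "p2": {"g2"}, "p3": {"g3"}})
        np.testing.assert_array_equal(np.sort(out.to_numpy(), axis=0),
                                      np.sort(mat.to_numpy(), axis=0))

    def test_idempotent_under_identity_mapping(self):
        mat = pd.DataFrame(
            [[2.0, -1.0], [0.5, 4.0]], index=["pa", "pb"], columns=["x", "y"]
        )
        once = collapse_probes(mat, {"pa": {"ga"}, "pb": {"gb"}})
        twice = collapse_probes(once, {g: {g} for g in once.index})
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_map_errors(self):
        with pytest.raises(ValueError, match="empty"):
            collapse_probes(pd.DataFrame([[1.0]], index=["p"], columns=["x"]), {})


class TestRepresentativeSelection:
    def test_single_profile_returned(self, profile_factory):
        p = profile_factory([1.0, 2.0, 3.0])
        assert select_representative_profiles([p], seed=0) == [p]

    def test_selection_member_of_duplicates_and_deterministic(self, profile_factory):
        dups = [profile_factory([1, 2, 3], replicate_id=f"r{i}") for i in range(3)]
        for seed in (0, 1, 2):
            sel = select_representative_profiles(dups, seed=seed)
            assert len(sel) == 1 and sel[0] in dups
            again = select_representative_profiles(dups, seed=seed)
            assert sel[0].replicate_id == again[0].replicate_id

    def test_one_per_condition(self, profile_factory):
        ps = [
            profile_factory([1, 2], compound="a", replicate_id="r0"),
            profile_factory([1, 2], compound="a", replicate_id="r1"),
            profile_factory([1, 2], compound="b", replicate_id="r0"),
        ]
        sel = select_representative_profiles(ps, seed=5)
        assert sorted(p.condition.compound for p in sel) == ["a", "b"]


class TestFoldChangeProfiles:
    def test_exact_means(self, noiseless_corpus):
        _, expr = noiseless_corpus
        # hand-build a tiny matrix: treatment (5,5), control (3,3) -> FC 2
        vals = pd.DataFrame(
            [[5.0, 5.0, 3.0, 3.0]],
            index=pd.Index(["g1"], name="gene_id"),
            columns=["t1", "t2", "c1", "c2"],
        )
        meta = pd.DataFrame(
            dict(
                compound=["x", "x", "", ""],
                concentration_uM=[1.0, 1.0, np.nan, np.nan],
                cell_line=["MCF7"] * 4,
                duration_h=[6.0] * 4,
                role=["treatment", "treatment", "control", "control"],
                plate_pool=["P1"] * 4,
                replicate_group=["RG1", "RG1", "CG1", "CG1"],
            ),
            index=pd.Index(["t1", "t2", "c1", "c2"], name="sample_id"),
        )
        from cmapbench.synth import ExpressionMatrix

        em = ExpressionMatrix(values=vals, sample_meta=meta, landmark_ids=vals.index[:0])
        profiles, excl = compute_fc_profiles(em, seed=0)
        assert not excl
        assert profiles[0].values["g1"] == pytest.approx(2.0)
        assert profiles[0].n_contributing_replicates == 2

    def test_group_below_minimum_skipped(self):
        vals = pd.DataFrame(
            [[5.0, 3.0, 3.0]],
            index=pd.Index(["g1"], name="gene_id"),
            columns=["t1", "c1", "c2"],
        )
        meta = pd.DataFrame(
            dict(
                compound=["x", "", ""],
                concentration_uM=[1.0, np.nan, np.nan],
                cell_line=["MCF7"] * 3,
                duration_h=[6.0] * 3,
                role=["treatment", "control", "control"],
                plate_pool=["P1"] * 3,
                replicate_group=["RG1", "CG1", "CG1"],
            ),
            index=pd.Index(["t1", "c1", "c2"], name="sample_id"),
        )
        from cmapbench.synth import ExpressionMatrix

        em = ExpressionMatrix(values=vals, sample_meta=meta, landmark_ids=vals.index[:0])
        profiles, excl = compute_fc_profiles(em, seed=0)
        assert profiles == []
        assert len(excl) == 1 and "below minimum" in excl[0].reason

    def test_oversized_groups_subsampled_to_equal_size(self):
        rng = np.random.default_rng(0)
        n_t, n_c = 25, 4
        cols = [f"t{i}" for i in range(n_t)] + [f"c{i}" for i in range(n_c)]
        vals = pd.DataFrame(
            rng.normal(size=(3, n_t + n_c)),
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
            columns=cols,
        )
        meta = pd.DataFrame(
            dict(
                compound=["x"] * n_t + [""] * n_c,
                concentration_uM=[1.0] * n_t + [np.nan] * n_c,
                cell_line=["MCF7"] * (n_t + n_c),
                duration_h=[6.0] * (n_t + n_c),
                role=["treatment"] * n_t + ["control"] * n_c,
                plate_pool=["P1"] * (n_t + n_c),
                replicate_group=["RG1"] * n_t + ["CG1"] * n_c,
            ),
            index=pd.Index(cols, name="sample_id"),
        )
        from cmapbench.synth import ExpressionMatrix

        em = ExpressionMatrix(values=vals, sample_meta=meta, landmark_ids=vals.index[:0])
        profiles, _ = compute_fc_profiles(em, seed=1)
        assert profiles[0].n_contributing_replicates == 4

    def test_no_plate_matched_control_reported_not_fatal(self):
        vals = pd.DataFrame(
            [[5.0, 5.0]],
            index=pd.Index(["g1"], name="gene_id"),
            columns=["t1", "t2"],
        )
        meta = pd.DataFrame(
            dict(
                compound=["x", "x"],
                concentration_uM=[1.0, 1.0],
                cell_line=["MCF7"] * 2,
                duration_h=[6.0] * 2,
                role=["treatment"] * 2,
                plate_pool=["P1"] * 2,
                replicate_group=["RG1"] * 2,
            ),
            index=pd.Index(["t1", "t2"], name="sample_id"),
        )
        from cmapbench.synth import ExpressionMatrix

        em = ExpressionMatrix(values=vals, sample_meta=meta, landmark_ids=vals.index[:0])
        profiles, excl = compute_fc_profiles(em, seed=0)
        assert profiles == [] and "no plate-matched control" in excl[0].reason

    def test_noiseless_recovery_of_planted_signal(self, noiseless_corpus, noiseless_spec):
        truth, expr = noiseless_corpus
        profiles, excl = compute_fc_profiles(expr, seed=0)
        assert not excl
        for p in profiles:
            c = p.condition
            expected = (
                dose_scaling(c.concentration_uM, truth.ec50[c.compound], truth.hill_coeff[c.compound])
                * truth.responsiveness[(c.compound, c.cell_line)]
                * truth.effect_vectors[(c.compound, c.cell_line)]
            )
            np.testing.assert_allclose(p.values.to_numpy(), expected.to_numpy(), atol=1e-10)


class TestDestandardizeAndTernarize:
    def test_destandardize_arithmetic(self, profile_factory):
        p = profile_factory([1.5, 0.0, -0.5], kind="MZS", n=4)
        out = destandardize_mzs(p)
        np.testing.assert_allclose(out.to_numpy(), [3.0, 0.0, -1.0])

    def test_destandardize_identity_at_n1(self, profile_factory):
        p = profile_factory([1.5, -2.5], kind="MZS", n=1)
        np.testing.assert_allclose(destandardize_mzs(p).to_numpy(), [1.5, -2.5])

    def test_destandardize_rejects_fc(self, profile_factory):
        with pytest.raises(TypeError):
            destandardize_mzs(profile_factory([1.0], kind="FC"))

    def test_fc_ternarize_boundary_included(self, profile_factory):
        p = profile_factory([1.2, -0.5, -1.0])
        t = ternarize(p)
        np.testing.assert_array_equal(t.values.to_numpy(), [1, 0, -1])

    def test_all_zero_profile(self, profile_factory):
        t = ternarize(profile_factory([0.0] * 5))
        assert count_de_genes(t) == 0

    def test_mzs_destandardized_before_threshold(self, profile_factory):
        # z=1.1 at n=4 de-standardizes to 2.2 >= 2.0 -> +1
        p = profile_factory([1.1, 0.9], kind="MZS", n=4)
        t = ternarize(p)
        np.testing.assert_array_equal(t.values.to_numpy(), [1, 0])
        assert t.thresholds_used == (-2.0, 2.0)

    def test_ternarize_commutes_with_destandardization(self, profile_factory):
        rng = np.random.default_rng(42)
        z = rng.normal(scale=1.2, size=200)
        p = profile_factory(z, kind="MZS", n=9)
        t_mzs = ternarize(p)
        scaled = profile_factory(z * 3.0, kind="MZS", n=1)  # z*sqrt(9), n=1 identity
        t_scaled = ternarize(scaled)
        np.testing.assert_array_equal(t_mzs.values.to_numpy(), t_scaled.values.to_numpy())

    def test_count_matches_enumeration(self, profile_factory):
        rng = np.random.default_rng(3)
        vals = rng.choice([-3.0, -1.0, 0.0, 0.5, 1.0, 2.0], size=300)
        t = ternarize(profile_factory(vals))
        brute = sum(1 for v in t.values if v != 0)
        assert count_de_genes(t) == brute


class TestMzsProfiles:
    def test_mzs_sign_matches_fc_and_n_recorded(self, small_corpus):
        _, expr = small_corpus
        fc, _ = compute_fc_profiles(expr, seed=0)
        mzs, _ = compute_mzs_profiles(expr, seed=0)
        assert len(fc) == len(mzs)
        for pf, pz in zip(fc, mzs):
            assert pz.kind == "MZS"
            assert pz.n_contributing_replicates == pf.n_contributing_replicates
            # same subsample draws: z and FC agree in sign wherever FC is large
            big = pf.values.abs() > 0.5
            if big.any():
                assert (
                    np.sign(pz.values[big]) == np.sign(pf.values[big])
                ).mean() > 0.99
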