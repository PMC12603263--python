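import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from plasmaqc import profile as prof
from plasmaqc import quant
from plasmaqc import simulate as sim
from plasmaqc.seqprops import PKA, net_charge, sequence_properties

from conftest import make_matrix

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestRankShift:
    def test_identity_law(self):
        neat = pd.Series([100.0, 10.0, 1.0], index=["A", "B", "C"])
        profile = prof.rank_shift_profile(neat, neat)
        assert np.allclose(profile["log10_ratio"], 0.0)
        assert (profile["class"] == "neither").all()
        assert profile["neat_rank"].tolist() == [1, 2, 3]

    def test_tenfold_scaling(self):
        neat = pd.Series([100.0, 10.0], index=["A", "B"])
        profile = prof.rank_shift_profile(neat, neat * 10)
        assert np.allclose(profile["log10_ratio"], 1.0)

    def test_only_classes(self):
        neat = pd.Series([100.0, np.nan], index=["A", "B"])
        other = pd.Series([np.nan, 5.0], index=["A", "B"])
        with pytest.warns(UserWarning, match="disjoint"):
            profile = prof.rank_shift_profile(neat, other)
        assert profile.loc["A", "class"] == "neat_only"
        assert profile.loc["B", "class"] == "other_only"

    def test_compressing_workflow_enriches_low_abundance(self):
        mneat, _, _ = sim.scenario_dilution_series(
            cv=0.0, lod=0.0, counts=[0.0], n_replicates=1, seed=6)
        msax, _, _ = sim.scenario_dilution_series(
            workflow="sax", cv=0.0, lod=0.0, counts=[0.0], n_replicates=1, seed=6)
        profile = prof.rank_shift_profile(
            mneat.intensities.iloc[:, 0], msax.intensities.iloc[:, 0])
        ok = profile.dropna(subset=["log10_ratio", "neat_rank"])
        rho = stats.spearmanr(ok["neat_rank"], ok["log10_ratio"]).statistic
        assert rho > 0.9  # low-abundance (high rank) proteins gain most


class TestClassification:
    @pytest.mark.parametrize("ratio,expected", [
        (2.0, "enriched"), (0.15, "depleted"), (1.5, "neither"),
        (1.8, "enriched"), (0.2, "depleted"),
    ])
    def test_eighty_percent_rule(self, ratio, expected):
        profile = pd.DataFrame(
            {"log10_ratio": [np.log10(ratio)], "class": ["neither"]},
            index=["X"],
        )
        labels = prof.classify_enriched_depleted(profile, 0.8)
        assert labels["X"] == expected

    def test_enriched_depleted_disjoint(self):
        rng = np.random.default_rng(0)
        profile = pd.DataFrame(
            {"log10_ratio": rng.normal(0, 1, 200), "class": ["neither"] * 200},
            index=[f"p{i}" for i in range(200)],
        )
        labels = prof.classify_enriched_depleted(profile, 0.5)
        assert not (set(labels[labels == "enriched"].index)
                    & set(labels[labels == "depleted"].index))

    def test_bad_threshold_rejected(self):
        profile = pd.DataFrame({"log10_ratio": [0.0], "class": ["neither"]})
        with pytest.raises(ValueError):
            prof.classify_enriched_depleted(profile, 1.5)


class TestSequenceProperties:
    def test_constant_residue_gravy(self):
        assert sequence_properties("AAA").gravy == pytest.approx(1.8)

    def test_aromaticity_fraction(self):
        assert sequence_properties("FWYA").aromaticity == pytest.approx(0.75)

    def test_dipeptide_instability_lookup(self):
        from Bio.SeqUtils.ProtParamData import DIWV

        assert sequence_properties("AA").instability_index == pytest.approx(
            5.0 * DIWV["A"]["A"])

    def test_polyglycine_pi_matches_independent_root(self):
        # oracle: scipy root-finding on an independently written charge model
        def charge(ph):
            pos = 1.0 / (1.0 + 10.0 ** (ph - PKA["nterm"]))
            neg = 1.0 / (1.0 + 10.0 ** (PKA["cterm"] - ph))
            return pos - neg

        expected = optimize.brentq(charge, 0.0, 14.0, xtol=1e-10)
        assert sequence_properties("GGGGG").isoelectric_point == pytest.approx(
            expected, abs=0.01)

    def test_hundred_random_sequences_match_brute_force(self):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 80))
            seq = "".join(rng.choice(list(AA20), n))
            props = sequence_properties(seq)
            oracle = ProteinAnalysis(seq)
            assert props.molecular_weight == pytest.approx(
                oracle.molecular_weight(), rel=1e-9)
            assert props.gravy == pytest.approx(oracle.gravy(), rel=1e-9)
            assert props.aromaticity == pytest.approx(
                oracle.aromaticity(), rel=1e-9)
            assert props.instability_index == pytest.approx(
                oracle.instability_index(), abs=1e-9)
            # independent bisection oracle for pI under our charge model
            expected_pi = optimize.brentq(
                lambda ph: net_charge(seq, ph), 0.0, 14.0, xtol=1e-10)
            assert props.isoelectric_point == pytest.approx(expected_pi, abs=0.01)

    def test_ambiguous_letters_policy(self):
        props = sequence_properties("AXA")
        assert props.length == 3
        assert props.gravy == pytest.approx(1.8)  # X excluded from average
        assert props.aromaticity == pytest.approx(0.0)

    def test_empty_and_invalid_sequences_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sequence_properties("")
        with pytest.raises(ValueError, match="position 2"):
            sequence_properties("A1A")


class TestPropertyTests:
    def _props(self, mw_values):
        frame = pd.DataFrame({p: np.ones(len(mw_values)) for p in prof.PROPERTY_NAMES})
        frame["molecular_weight"] = mw_values
        return frame

    def test_identical_sets_p_one(self):
        frame = self._props([1.0, 2.0, 3.0, 4.0])
        out = prof.property_enrichment_tests(frame, frame).set_index("property")
        assert out.loc["molecular_weight", "p_value"] == pytest.approx(1.0)
        assert out.loc["gravy", "p_value"] == 1.0  # zero variance convention

    def test_smaller_proteins_enriched_detected(self):
        rng = np.random.default_rng(0)
        enriched = self._props(rng.normal(20_000, 2, 50))
        depleted = self._props(rng.normal(80_000, 2, 50))
        out = prof.property_enrichment_tests(enriched, depleted).set_index("property")
        row = out.loc["molecular_weight"]
        assert row["p_value"] < 1e-10
        assert row["direction"] == "depleted higher"

    def test_undersized_side_undefined(self):
        out = prof.property_enrichment_tests(
            self._props([1.0, 2.0]), self._props([1.0, 2.0, 3.0]))
        assert out["p_value"].isna().all()
        assert out["note"].str.contains("fewer than 3").all()


class TestReplicateCV:
    def test_identical_replicates_zero_cv(self):
        m = make_matrix({"r1": [5.0, 2.0], "r2": [5.0, 2.0]}, ["A", "B"])
        cvs, summary = prof.replicate_cv(m, {"g": ["r1", "r2"]})
        assert np.allclose(cvs["g"], 0.0)

    def test_population_sd_closed_form(self):
        m = make_matrix({"r1": [90.0], "r2": [110.0]}, ["A"])
        cvs, _ = prof.replicate_cv(m, {"g": ["r1", "r2"]})
        assert cvs.loc["A", "g"] == pytest.approx(0.1)

    def test_simulated_cv_recovered(self):
        m, samples, _ = sim.scenario_dilution_series(
            cv=0.13, lod=0.0, counts=[0.0], n_replicates=4, seed=2,
            n_plasma=2000,
        )
        groups = {"s": list(m.sample_ids)}
        _, summary = prof.replicate_cv(m, groups)
        assert summary.loc["s", "median_cv"] == pytest.approx(0.13, abs=0.02)

    def test_undersized_group_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="fewer than 2"):
            prof.replicate_cv(toy_matrix, {"g": ["s1"]})


class TestPCA:
    def test_complete_matrix_imputation_identity_and_svd_equality(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.normal(5, 1, (20, 6)),
                            index=[f"p{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(6)])
        m = quant.QuantMatrix(data, scale="log10")
        res = prof.pca_with_imputation(m, 3)
        assert np.allclose(res.imputed.to_numpy(), data.T.to_numpy())
        centred = data.T - data.T.mean(axis=0)
        u, s, vt = np.linalg.svd(centred.to_numpy(), full_matrices=False)
        assert np.allclose(np.abs(res.scores["PC1"]), np.abs(u[:, 0] * s[0]))

    def test_collinear_samples_put_all_variance_on_pc1(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        data = pd.DataFrame(
            {"f1": 1 + 2 * t, "f2": 5 - t, "f3": 2 + 0.5 * t},
        ).T
        data.columns = [f"s{i}" for i in range(4)]
        m = quant.QuantMatrix(data, scale="log10")
        res = prof.pca_with_imputation(m, 2)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_pc1_separates_contamination_status(self):
        m, samples, _ = sim.scenario_dilution_series(
            counts=[0.0, 1e5], n_replicates=8, workflow="sax", seed=1)
        res = prof.pca_with_imputation(quant.log10_transform(m), 3)
        status = (samples.set_index("sample_id")["cell_count"] > 0).astype(float)
        r = np.corrcoef(res.scores["PC1"],
                        status.reindex(res.scores.index))[0, 1]
        assert abs(r) > 0.9

    def test_variance_fractions_sample_order_invariant(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(0, 1, (15, 6)),
                            columns=[f"s{i}" for i in range(6)])
        data.index = [f"p{i}" for i in range(15)]
        m = quant.QuantMatrix(data, scale="log10")
        a = prof.pca_with_imputation(m, 3).variance_fractions
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        b = prof.pca_with_imputation(
            quant.QuantMatrix(data[perm], scale="log10"), 3).variance_fractions
        assert np.allclose(a, b)

    def test_too_many_neighbors_rejected(self):
        data = pd.DataFrame(np.ones((4, 3)), columns=["a", "b", "c"],
                            index=[f"p{i}" for i in range(4)])
        with pytest.raises(ValueError, match="k_neighbors"):
            prof.pca_with_imputation(quant.QuantMatrix(data, scale="log10"), 3)


def test_properties_from_fasta(tmp_path):
    fasta = tmp_path / "seqs.fasta"
    fasta.write_text(">sp|P1|ALBU test protein\nMKWVTFISLLFLFSSAYS\n>P2\nGGGGG\n")
    frame = prof.properties_from_fasta(fasta)
    assert list(frame.index) == ["sp|P1|ALBU", "P2"]
    assert frame.loc["P2", "length"] == 5
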