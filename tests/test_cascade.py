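"""Probe z-scores, differential-binding tests, seed selection and motifs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfabt.cascade import (
    BASES,
    N_REPLICATES,
    ORIENTATIONS,
    PROBE_LEN,
    beta_schedule,
    delta_z_matrix,
    fisher_combine,
    ppm_from_z,
    refalt_analysis,
    refalt_test,
    select_seed,
    zscore_transform,
)
from tfabt.simulate import SimulationConfig, simulate_cascade_probes


class TestZScore:
    def test_background_self_standardizes(self):
        rng = np.random.default_rng(0)
        bg = np.exp(rng.normal(7, 0.5, 200))
        z = zscore_transform(bg, bg)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_geometric_mean_is_zero(self):
        rng = np.random.default_rng(1)
        bg = np.exp(rng.normal(7, 0.5, 100))
        gm = np.exp(np.log(bg).mean())
        assert zscore_transform(np.array([gm]), bg)[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_sd_above_log_mean(self):
        rng = np.random.default_rng(2)
        bg = np.exp(rng.normal(7, 0.5, 5000))
        mu, sd = np.log(bg).mean(), np.log(bg).std(ddof=1)
        v = np.exp(mu + 2 * sd)
        assert zscore_transform(np.array([v]), bg)[0] == pytest.approx(2.0, abs=1e-9)

    def test_nonpositive_values_flagged(self):
        bg = np.exp(np.random.default_rng(3).normal(7, 0.5, 50))
        with pytest.warns(UserWarning, match="non-positive"):
            z = zscore_transform(np.array([-1.0, 100.0]), bg)
        assert math.isnan(z[0]) and not math.isnan(z[1])

    def test_too_few_background_probes(self):
        with pytest.raises(ValueError):
            zscore_transform(np.array([1.0]), np.ones(5))


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0] * 6) == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.5, 0.01, 1e-6):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-9)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            ps = rng.uniform(1e-6, 1, size=6)
            expected = stats.combine_pvalues(ps, method="fisher").pvalue
            assert fisher_combine(ps) == pytest.approx(expected, rel=1e-9)

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = fisher_combine([0.0, 0.5])
        assert 0 < p < 1e-100


def probe_frame(ref_z, alt_z, sd, rng, locus="L1", cof="C1", exp="exp1"):
    rows = []
    for allele, mean in (("ref", ref_z), ("alt", alt_z)):
        for reg in (-5, 0, 5):
            for ori in ORIENTATIONS:
                for rep in range(N_REPLICATES):
                    rows.append((locus, allele, reg, ori, rep + 1, exp, cof,
                                 mean + rng.normal(0, sd)))
    return pd.DataFrame(rows, columns=["locus_id", "allele", "register", "orientation",
                                       "replicate", "experiment", "cof", "z"])


class TestRefAltTest:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(5)
        df = probe_frame(3.0, 3.0, 0.5, rng)
        res = refalt_test(df)
        assert abs(res.delta_z) < 1.0
        assert res.aggregate_p > 1e-3
        assert not res.passes

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        df = probe_frame(5.0, 2.0, 0.5, rng)
        res = refalt_test(df)
        assert res.delta_z == pytest.approx(3.0, abs=0.5)
        assert res.aggregate_p < 1e-3 and res.passes

    def test_swapping_alleles_negates_delta_and_keeps_p(self):
        rng = np.random.default_rng(7)
        df = probe_frame(5.0, 2.0, 0.5, rng)
        swapped = df.copy()
        swapped["allele"] = swapped["allele"].map({"ref": "alt", "alt": "ref"})
        a, b = refalt_test(df), refalt_test(swapped)
        assert a.delta_z == pytest.approx(-b.delta_z, abs=1e-9)
        assert a.aggregate_p == pytest.approx(b.aggregate_p, rel=1e-9)

    def test_missing_replicates_rejected(self):
        rng = np.random.default_rng(8)
        df = probe_frame(3.0, 3.0, 0.5, rng).iloc[:-1]
        with pytest.raises(ValueError, match="replicates"):
            refalt_test(df)

    def test_vectorized_analysis_matches_single_locus_path(self):
        """Dual route: the batch pipeline must agree with refalt_test."""
        cfg = SimulationConfig(seed=42, n_loci=6, n_planted_loci=3)
        probes, backgrounds, _ = simulate_cascade_probes(cfg, sv_seed_motif=None)
        summary = refalt_analysis(probes, backgrounds)
        for (locus, exp), row in summary.set_index(["locus_id", "experiment"]).iterrows():
            sub = probes[(probes["locus_id"] == locus) & (probes["experiment"] == exp)].copy()
            sub["z"] = zscore_transform(sub["value"].to_numpy(), backgrounds[exp])
            ref = refalt_test(sub)
            assert row["delta_z"] == pytest.approx(ref.delta_z, rel=1e-9)
            assert row["aggregate_p"] == pytest.approx(ref.aggregate_p, rel=1e-6)
            assert row["passes"] == ref.passes

    def test_bmvar_requires_both_experiments(self):
        rng = np.random.default_rng(9)
        df1 = probe_frame(5.0, 2.0, 0.5, rng, exp="exp1")
        df2 = probe_frame(3.0, 3.0, 0.5, rng, exp="exp2")  # no effect in replicate 2
        probes = pd.concat([df1, df2], ignore_index=True)
        probes["value"] = np.exp(7 + probes["z"] * 0.8)
        bg = {e: np.exp(np.random.default_rng(1).normal(7, 0.8, 200)) for e in ("exp1", "exp2")}
        summary = refalt_analysis(probes, bg)
        assert not summary["bmvar"].any()
        assert summary.loc[summary["experiment"] == "exp1", "passes"].all()


class TestSelectSeed:
    def test_dominant_cell_chosen(self):
        rng = np.random.default_rng(10)
        df = probe_frame(3.0, 3.0, 0.3, rng)
        boost = (df["register"] == 5) & (df["orientation"] == "rev") & (df["allele"] == "ref")
        df.loc[boost, "z"] += 4.0
        allele, reg, ori = select_seed(df)
        assert (allele, reg, ori) == ("ref", 5, "rev")

    def test_exact_tie_prefers_fwd_then_register0(self):
        rows = []
        for reg in (-5, 0, 5):
            for ori in ORIENTATIONS:
                for allele, mean in (("ref", 4.0), ("alt", 1.0)):
                    for rep in range(N_REPLICATES):
                        # identical replicate patterns in every cell: exact tie
                        rows.append(("L", allele, reg, ori, rep + 1, "e", "c",
                                     mean + 0.1 * rep))
        df = pd.DataFrame(rows, columns=["locus_id", "allele", "register", "orientation",
                                         "replicate", "experiment", "cof", "z"])
        allele, reg, ori = select_seed(df)
        assert (allele, reg, ori) == ("ref", 0, "fwd")

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        df = probe_frame(3.5, 2.5, 1.0, rng)
        best_t, best_cell = -1, None
        for reg in (-5, 0, 5):
            for ori in ORIENTATIONS:
                cell = df[(df["register"] == reg) & (df["orientation"] == ori)]
                t = abs(stats.ttest_ind(
                    cell[cell["allele"] == "ref"]["z"], cell[cell["allele"] == "alt"]["z"],
                    equal_var=True).statistic)
                if t > best_t + 1e-12:
                    best_t, best_cell = t, (reg, ori)
        _, reg, ori = select_seed(df)
        assert (reg, ori) == best_cell


class TestDeltaZMatrix:
    def test_constant_row_centered_to_zero(self):
        seed = "A" * PROBE_LEN
        sv = {(i, b): 2.0 for i in range(1, PROBE_LEN + 1) for b in "CGT"}
        m = delta_z_matrix(seed, 2.0, sv)
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    def test_single_preferred_base(self):
        seed = "A" * PROBE_LEN
        sv = {(i, b): 1.0 for i in range(1, PROBE_LEN + 1) for b in "CGT"}
        m = delta_z_matrix(seed, 5.0, sv)
        # values (5, 1, 1, 1): median 1 -> delta (4, 0, 0, 0)
        np.testing.assert_allclose(m.values[:, 0], 4.0, atol=1e-12)
        np.testing.assert_allclose(m.values[:, 1:], 0.0, atol=1e-12)

    def test_row_median_zero_invariant(self):
        rng = np.random.default_rng(12)
        seed = "".join(rng.choice(list(BASES), PROBE_LEN))
        sv = {
            (i, b): float(rng.normal(2, 1))
            for i in range(1, PROBE_LEN + 1)
            for b in BASES
            if b != seed[i - 1]
        }
        m = delta_z_matrix(seed, float(rng.normal(4, 1)), sv)
        med = np.median(m.values, axis=1)
        np.testing.assert_allclose(med, 0.0, atol=1e-12)

    def test_missing_variant_marks_position_undefined(self):
        seed = "A" * PROBE_LEN
        sv = {(i, b): 1.0 for i in range(1, PROBE_LEN + 1) for b in "CGT"}
        del sv[(3, "G")]
        m = delta_z_matrix(seed, 5.0, sv)
        assert np.isnan(m.values[2]).all()
        assert not np.isnan(m.values[3]).any()


class TestPPM:
    def test_beta_schedule_values_and_continuity(self):
        assert beta_schedule(-2.0) == 4.0
        assert beta_schedule(0.0) == 4.0
        assert beta_schedule(6.0) == 1.0
        assert beta_schedule(8.0) == 1.0
        assert beta_schedule(2.0) == pytest.approx(3.0)
        eps = 1e-9
        assert beta_schedule(-eps) == pytest.approx(beta_schedule(eps), abs=1e-6)
        assert beta_schedule(6 - eps) == pytest.approx(beta_schedule(6 + eps), abs=1e-6)

    def test_beta_non_increasing(self):
        zs = np.linspace(-3, 10, 40)
        betas = [beta_schedule(z) for z in zs]
        assert all(a >= b - 1e-12 for a, b in zip(betas, betas[1:]))

    def test_equal_z_gives_uniform_row(self):
        z = np.full((4, 4), 1.7)
        ppm = ppm_from_z(z, z_seed=3.0)
        np.testing.assert_allclose(ppm.probs, 0.25, atol=1e-12)

    def test_softmax_example(self):
        # z_seed = 2 -> beta = 3; row (1, 0, 0, 0) -> P(A) = e^3 / (e^3 + 3)
        z = np.array([[1.0, 0.0, 0.0, 0.0]])
        ppm = ppm_from_z(z, z_seed=2.0)
        assert ppm.beta == pytest.approx(3.0)
        assert ppm.probs[0, 0] == pytest.approx(math.exp(3) / (math.exp(3) + 3), rel=1e-9)
        assert ppm.probs[0, 0] == pytest.approx(0.870, abs=1e-3)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(13)
        z = rng.normal(0, 2, size=(PROBE_LEN, 4))
        ppm = ppm_from_z(z, z_seed=4.0)
        np.testing.assert_allclose(ppm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_motif_recovered_from_sv_scan(self):
        cfg = SimulationConfig(seed=99, n_loci=2, n_planted_loci=0)
        seed_motif = "GCAGGATGTTCCGGAAGTCACTGCAT"
        probes, backgrounds, truth = simulate_cascade_probes(cfg, sv_seed_motif=seed_motif)
        sub = probes[(probes["locus_id"] == "SVLOCUS") & (probes["experiment"] == "exp1")].copy()
        sub["z"] = zscore_transform(sub["value"].to_numpy(), backgrounds["exp1"])
        z_seed = float(sub.loc[sub["allele"] == "seed", "z"].mean())
        sv_z = {
            (int(a[2:4]), a[4]): float(g["z"].mean())
            for a, g in sub[sub["allele"].str.startswith("sv")].groupby("allele")
        }
        m = delta_z_matrix(seed_motif, z_seed, sv_z)
        ppm = ppm_from_z(m.values, z_seed)
        core = truth["sv"]["core_positions"]
        for i in core:
            assert BASES[int(np.argmax(ppm.probs[i]))] == seed_motif[i]
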