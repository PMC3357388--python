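import numpy as np
import pandas as pd
import pytest

from diurnal import (
    ConfigError,
    GeneratorConfig,
    HormoneConfig,
    ToleranceConfig,
    fit_cosinor,
    generate_gene_sets,
    generate_hormone_profile,
    generate_tolerance_test,
    generate_transcriptome,
)


def wave(t, m, a, phi, period=24.0):
    return m + a * np.cos(2 * np.pi * (t - phi) / period)


class TestTranscriptome:
    def test_noiseless_values_equal_generative_waveform(self, noiseless_dataset):
        matrix, samples, truth = noiseless_dataset
        cond1, cond2 = truth.config.conditions
        for _, g in truth.genes.sample(25, random_state=0).iterrows():
            for cond in (cond1, cond2):
                cols = samples.loc[samples["condition"] == cond, "sample_id"]
                t = samples.loc[samples["condition"] == cond, "zt"].to_numpy()
                a = g[f"amplitude_{cond}"]
                expected = (
                    wave(t, g[f"baseline_{cond}"], a, g[f"acrophase_{cond}"])
                    if a > 0
                    else np.full(t.size, g[f"baseline_{cond}"])
                )
                np.testing.assert_allclose(
                    matrix.loc[g["gene"], cols].to_numpy(), expected, atol=1e-12
                )

    def test_single_class_one_gene_peak_value(self):
        # noiseless class-I gene peaking at ZT13: samples at ZT13 sit at m + A
        gen = GeneratorConfig(n_genes=1, noise_sd=0.0, class_proportions={"I": 1.0})
        matrix, samples, truth = generate_transcriptome(gen, seed=0)
        g = truth.genes.iloc[0]
        cols = samples.loc[samples["zt"] == 13.0, "sample_id"]
        expected = wave(13.0, g["baseline_control"], g["amplitude_control"], g["acrophase_control"])
        np.testing.assert_allclose(matrix.loc[g["gene"], cols], expected, atol=1e-12)

    def test_all_nc_is_flat(self):
        gen = GeneratorConfig(n_genes=40, noise_sd=0.0, class_proportions={"NC": 1.0})
        matrix, samples, truth = generate_transcriptome(gen, seed=1)
        assert (truth.genes["true_class"] == "NC").all()
        assert (truth.genes[["amplitude_control", "amplitude_TSR"]] == 0).all().all()
        np.testing.assert_allclose(matrix.to_numpy().std(axis=1), 0.0, atol=1e-12)

    def test_same_seed_reproducible(self):
        gen = GeneratorConfig(n_genes=30)
        m1, _, _ = generate_transcriptome(gen, seed=9)
        m2, _, _ = generate_transcriptome(gen, seed=9)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seed_same_truth_structure(self):
        gen = GeneratorConfig(n_genes=60)
        _, _, t1 = generate_transcriptome(gen, seed=1)
        m2, _, t2 = generate_transcriptome(gen, seed=2)
        assert (
            t1.genes["true_class"].value_counts().to_dict()
            == t2.genes["true_class"].value_counts().to_dict()
        )
        m1, _, _ = generate_transcriptome(gen, seed=1)
        assert not np.allclose(m1.to_numpy(), m2.to_numpy())

    def test_gene_streams_stable_under_n_genes(self):
        # counter-based streams: gene i draws the same randomness whether
        # 20 or 60 genes are generated
        _, _, small = generate_transcriptome(GeneratorConfig(n_genes=20, noise_sd=0.0), seed=4)
        _, _, big = generate_transcriptome(GeneratorConfig(n_genes=60, noise_sd=0.0), seed=4)
        # baselines are the first draw of each stream, independent of class
        np.testing.assert_allclose(
            small.genes["baseline_control"].to_numpy(),
            big.genes["baseline_control"].to_numpy()[:20],
        )

    def test_class_labels_consistent_with_amplitudes(self, noisy_dataset):
        _, _, truth = noisy_dataset
        g = truth.genes
        assert (g.loc[g["true_class"] == "III", "amplitude_control"] > 0).all()
        assert (g.loc[g["true_class"] == "III", "amplitude_TSR"] == 0).all()
        assert (g.loc[g["true_class"] == "VI", "amplitude_control"] == 0).all()
        assert (g.loc[g["true_class"] == "VI", "amplitude_TSR"] > 0).all()
        flat = g["true_class"].isin(["IV", "V", "NC"])
        assert (g.loc[flat, ["amplitude_control", "amplitude_TSR"]] == 0).all().all()

    def test_planted_bimodality_of_tsr_phases(self):
        gen = GeneratorConfig(n_genes=600)
        _, _, truth = generate_transcriptome(gen, seed=13)
        phases = truth.genes.loc[
            truth.genes["amplitude_TSR"] > 0, "acrophase_TSR"
        ].to_numpy()
        centers = np.array([1.0, 7.0, 13.0, 19.0])
        d = np.abs(phases[:, None] - centers[None, :])
        counts = np.bincount(
            np.argmin(np.minimum(d, 24 - d), axis=1), minlength=4
        )
        assert set(np.argsort(counts)[-2:]) == {0, 2}  # ZT1 and ZT13 bins

    def test_bad_proportions_rejected(self):
        with pytest.raises(ConfigError, match="proportions"):
            GeneratorConfig(class_proportions={"I": 0.5, "NC": 0.6})


class TestGeneSets:
    def test_infinite_odds_pure_class(self, noisy_dataset):
        _, _, truth = noisy_dataset
        sets = generate_gene_sets(truth, {"S": ("III", float("inf"), 30)}, seed=0)
        members = sets["S"]
        assert len(members) == 30
        class3 = set(truth.genes.loc[truth.genes["true_class"] == "III", "gene"])
        assert set(members) <= class3

    def test_unit_odds_binomial_expectation(self):
        # with odds=1 the expected class-III overlap equals prevalence*size
        gen = GeneratorConfig(n_genes=200)
        _, _, truth = generate_transcriptome(gen, seed=3)
        class3 = set(truth.genes.loc[truth.genes["true_class"] == "III", "gene"])
        prevalence = len(class3) / 200
        size = 30
        overlaps = []
        for rep in range(1000):
            sets = generate_gene_sets(truth, {"S": ("III", 1.0, size)}, seed=rep)
            overlaps.append(len(class3.intersection(sets["S"])))
        expected = prevalence * size
        sd = np.sqrt(size * prevalence * (1 - prevalence))
        assert abs(np.mean(overlaps) - expected) < 4 * sd / np.sqrt(1000)

    def test_empty_planting(self, noisy_dataset):
        _, _, truth = noisy_dataset
        assert generate_gene_sets(truth, {}, seed=0) == {}

    def test_oversized_set_rejected(self, noisy_dataset):
        _, _, truth = noisy_dataset
        with pytest.raises(ConfigError, match="size"):
            generate_gene_sets(truth, {"S": ("III", 1.0, 10_000)}, seed=0)

    def test_membership_recorded_on_truth(self, noiseless_dataset):
        _, _, truth = noiseless_dataset
        sets = generate_gene_sets(truth, {"Q": ("NC", 1.0, 10)}, seed=0)
        assert truth.gene_sets["Q"] == sets["Q"]


class TestHormoneProfile:
    def test_noiseless_control_peaks_at_zt12(self):
        cfg = HormoneConfig(noise_fraction=0.0)
        profile = generate_hormone_profile(cfg, seed=0)
        sub = profile[profile["condition"] == "control"].groupby("zt")["value"].mean()
        assert sub.idxmax() == 12.0
        fit = fit_cosinor(sub.index.to_numpy(float), sub.to_numpy())
        assert fit.acrophase == pytest.approx(12.0, abs=1e-9)

    def test_conditions_differ_only_in_acrophase(self):
        cfg = HormoneConfig(noise_fraction=0.0)
        profile = generate_hormone_profile(cfg, seed=0)
        ctrl = profile[profile["condition"] == "control"].groupby("zt")["value"].mean()
        tsr = profile[profile["condition"] == "TSR"].groupby("zt")["value"].mean()
        # TSR waveform is the control waveform advanced by 6 h
        shifted = ctrl.reindex((tsr.index + 6) % 24).to_numpy()
        np.testing.assert_allclose(tsr.to_numpy(), shifted, atol=1e-9)

    def test_seed_reproducible(self):
        p1 = generate_hormone_profile(seed=5)
        p2 = generate_hormone_profile(seed=5)
        pd.testing.assert_frame_equal(p1, p2)

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigError):
            HormoneConfig(noise_fraction=-0.1)


class TestToleranceTest:
    def test_zero_pulse_zero_noise_flat(self):
        cfg = ToleranceConfig(
            pulse_height={"control": 0.0, "TSR": 0.0}, noise_sd=0.0
        )
        series = generate_tolerance_test(cfg, seed=0)
        np.testing.assert_allclose(series["value"], cfg.baseline)

    def test_pulse_height_orders_auc(self):
        from diurnal import tolerance_auc

        cfg = ToleranceConfig(noise_sd=0.0)
        series = generate_tolerance_test(cfg, seed=0)
        aucs = {}
        for cond, sub in series.groupby("condition"):
            one = sub[sub["replicate"] == 1].sort_values("minutes")
            aucs[cond] = tolerance_auc(one["minutes"], one["value"]).baseline_corrected_auc
        assert aucs["control"] > aucs["TSR"]

    def test_seed_reproducible(self):
        pd.testing.assert_frame_equal(
            generate_tolerance_test(seed=2), generate_tolerance_test(seed=2)
        )

    def test_bad_grid_rejected(self):
        with pytest.raises(ConfigError):
            ToleranceConfig(minutes=(0.0, 30.0, 30.0))
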