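"""Generator contracts: determinism, degenerate limits, planted truth."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from susceptigene import synthdata as sd


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        sd.SimConfig(seed=1, n_genes=0)
    with pytest.raises(ValueError):
        sd.SimConfig(seed=1, censoring_rate=1.5)
    with pytest.raises(ValueError):
        sd.SimConfig(seed=1, n_genes=10, planted_essential=frozenset({"NOPE"}))
    with pytest.raises(ValueError):
        sd.SimConfig(seed=1, nb_dispersion=-0.1)


def test_generators_are_deterministic():
    cfg = sd.planted_screen_config(42, n_genes=50, n_planted=5, n_other_lines=20,
                                   n_tumor=40, n_reference=20, n_samples_survival=40,
                                   n_promoters=30, n_peaks=60)
    a_dep, b_dep = sd.gen_dependency(cfg), sd.gen_dependency(cfg)
    pd.testing.assert_frame_equal(a_dep.scores, b_dep.scores)
    a_e, b_e = sd.gen_expression(cfg), sd.gen_expression(cfg)
    pd.testing.assert_frame_equal(a_e.tpm, b_e.tpm)
    a_s, b_s = sd.gen_survival(cfg, a_e), sd.gen_survival(cfg, b_e)
    pd.testing.assert_series_equal(a_s.time, b_s.time)
    pd.testing.assert_series_equal(a_s.event, b_s.event)
    a_c, b_c = sd.gen_counts(cfg), sd.gen_counts(cfg)
    pd.testing.assert_frame_equal(a_c.counts, b_c.counts)
    (a_pr, a_pk), (b_pr, b_pk) = sd.gen_genome(cfg), sd.gen_genome(cfg)
    pd.testing.assert_frame_equal(a_pr, b_pr)
    pd.testing.assert_frame_equal(a_pk, b_pk)


def test_substreams_independent_of_other_generators():
    """Drawing one dataset never perturbs another generator's stream."""
    cfg = sd.SimConfig(seed=3, n_genes=20, n_other_lines=10)
    direct = sd.gen_counts(cfg)
    sd.gen_dependency(cfg)  # interleaved draw from a different stream
    again = sd.gen_counts(cfg)
    pd.testing.assert_frame_equal(direct.counts, again.counts)


def test_dependency_zero_noise_means_exact():
    cfg = sd.SimConfig(
        seed=1, n_genes=10, n_other_lines=5,
        planted_essential=frozenset({"G00002"}), essential_effect=-1.0, noise_sd=0.0,
    )
    dep = sd.gen_dependency(cfg)
    target_cols = dep.group.index[dep.group == "target"]
    other_cols = dep.group.index[dep.group == "other"]
    assert dep.scores.loc["G00002", target_cols].mean() == pytest.approx(-1.0)
    assert dep.scores.loc["G00002", other_cols].mean() == pytest.approx(0.0)
    assert dep.scores.loc["G00000"].abs().max() == 0.0


def test_dependency_planted_mean_sampling_distribution():
    """Target-line means of planted genes concentrate around the effect at
    the normal-theory rate (3 sigma of the mean over 13 lines)."""
    hits = total = 0
    for seed in range(200):
        cfg = sd.SimConfig(
            seed=seed, n_genes=5, n_other_lines=5,
            planted_essential=frozenset({"G00000"}),
            essential_effect=-0.8, noise_sd=0.1,
        )
        dep = sd.gen_dependency(cfg)
        target_cols = dep.group.index[dep.group == "target"]
        m = dep.scores.loc["G00000", target_cols].mean()
        hits += abs(m - (-0.8)) <= 3 * 0.1 / np.sqrt(13)
        total += 1
    assert hits / total >= 0.99


def test_expression_null_and_degenerate_folds():
    null_cfg = sd.SimConfig(seed=5, n_genes=40, n_tumor=200, n_reference=200)
    expr = sd.gen_expression(null_cfg)
    t = expr.tpm.loc[:, expr.sample_group == "tumor"].median(axis=1)
    r = expr.tpm.loc[:, expr.sample_group == "reference"].median(axis=1)
    # shared background: medians agree within sampling error on the log scale
    assert np.abs(np.log(t / r)).median() < 0.15

    exact_cfg = sd.SimConfig(
        seed=5, n_genes=10, planted_overexpressed=frozenset({"G00003"}),
        overexpression_fold=8.0, expr_log_sd=0.0, n_tumor=10, n_reference=10,
    )
    e2 = sd.gen_expression(exact_cfg)
    tm = e2.tpm.loc["G00003", e2.sample_group == "tumor"].mean()
    rm = e2.tpm.loc["G00003", e2.sample_group == "reference"].mean()
    assert tm / rm == pytest.approx(8.0)
    assert (e2.tpm.to_numpy() >= 0).all()


def test_expression_planted_fold_recovered_within_band():
    ok = total = 0
    for seed in range(60):
        cfg = sd.SimConfig(
            seed=seed, n_genes=20, planted_overexpressed=frozenset({"G00000"}),
            overexpression_fold=4.0, n_tumor=100, n_reference=100,
        )
        expr = sd.gen_expression(cfg)
        tm = expr.tpm.loc["G00000", expr.sample_group == "tumor"].mean()
        rm = expr.tpm.loc["G00000", expr.sample_group == "reference"].mean()
        ok += 3.0 <= tm / rm <= 5.0
        total += 1
    assert ok / total >= 0.95


def test_survival_censoring_contract():
    cfg = sd.SimConfig(seed=2, n_genes=10, n_tumor=400, n_samples_survival=400,
                       censoring_rate=0.0)
    expr = sd.gen_expression(cfg)
    surv = sd.gen_survival(cfg, expr)
    assert (surv.event == 1).all()
    assert (surv.time > 0).all()

    cens = replace(cfg, censoring_rate=0.4)
    surv2 = sd.gen_survival(cens, sd.gen_expression(cens))
    frac = 1.0 - surv2.event.mean()
    assert 0.3 <= frac <= 0.5  # approximate by construction


def test_survival_requires_enough_tumor_samples():
    cfg = sd.SimConfig(seed=2, n_genes=5, n_tumor=10, n_samples_survival=50)
    with pytest.raises(ValueError, match="tumor samples"):
        sd.gen_survival(cfg, sd.gen_expression(cfg))


def test_counts_poisson_limit_and_noiseless_fold():
    cfg = sd.SimConfig(seed=9, n_genes=500, nb_dispersion=0.0, n_replicates=50)
    cm = sd.gen_counts(cfg)
    ctrl = cm.counts.loc[:, cm.condition == "control"].mean(axis=1)
    ko = cm.counts.loc[:, cm.condition == "knockout"].mean(axis=1)
    # fold 1, Poisson: difference of means within ~4 SE of zero for most genes
    se = np.sqrt(ctrl / 50 + ko / 50)
    assert ((ko - ctrl).abs() <= 4 * se + 1e-9).mean() > 0.97

    exact = sd.SimConfig(seed=9, n_genes=10, planted_de={"G00001": 4.0})
    cm2 = sd.gen_counts(exact, noiseless=True)
    ctrl2 = cm2.counts.loc["G00001", cm2.condition == "control"].mean()
    ko2 = cm2.counts.loc["G00001", cm2.condition == "knockout"].mean()
    assert ko2 / ctrl2 == pytest.approx(4.0)
    assert (cm2.counts.to_numpy() >= 0).all()


def test_genome_overlap_fraction_limits():
    from susceptigene.regulatory import classify_peaks

    for frac, n_prom_peaks in ((1.0, 200), (0.0, 0)):
        cfg = sd.SimConfig(seed=4, n_genes=300, n_peaks=200,
                           promoter_overlap_fraction=frac)
        promoters, peaks = sd.gen_genome(cfg)
        cls = classify_peaks(peaks, promoters)
        assert len(cls.promoter_peaks) == n_prom_peaks


def test_genome_fraction_within_binomial_interval():
    from scipy import stats
    from susceptigene.regulatory import classify_peaks

    cfg = sd.SimConfig(seed=8, n_genes=300, n_peaks=1000,
                       promoter_overlap_fraction=0.3)
    promoters, peaks = sd.gen_genome(cfg)
    n_prom = len(classify_peaks(peaks, promoters).promoter_peaks)
    lo, hi = stats.binom.interval(0.99, 1000, 0.3)
    assert lo <= n_prom <= hi


def test_genome_too_small_raises():
    cfg = sd.SimConfig(seed=1, n_genes=2000, chrom_sizes={"chr1": 10_000},
                       n_promoters=500)
    with pytest.raises(ValueError, match="too small"):
        sd.gen_genome(cfg)


def test_truth_sidecar_roundtrip(tmp_path):
    import json

    cfg = sd.planted_screen_config(1, n_genes=50, n_planted=5, n_other_lines=10)
    path = tmp_path / "truth.json"
    sd.write_truth(cfg, path)
    truth = json.loads(path.read_text())
    assert truth["planted_essential"] == sorted(cfg.planted_essential)
    assert truth["log_hr"] == pytest.approx(cfg.log_hr)
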