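"""Synthetic cohort generator: counterbalancing, IBI control, trials, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest

import vagalflex as vf
from vagalflex.cohort import (CONDITIONS, HIGH_EMOTION, CohortSpec,
                              expected_rmssd, generate_condition_order,
                              generate_ibi_series, generate_trials,
                              valid_condition_orders)
from vagalflex.metrics import rt_interference


# ------------------------------------------------- condition counterbalancing

def _brute_force_valid_orders():
    """Independent enumeration of the adjacency constraint."""
    he, hs = {"HELS", "HEHS"}, {"LEHS", "HEHS"}
    ok = []
    for p in itertools.permutations(CONDITIONS):
        pairs = list(zip(p, p[1:]))
        if any(set(pair) == he or set(pair) == hs for pair in pairs):
            continue
        ok.append(p)
    return set(ok)


def test_condition_orders_match_brute_force_enumeration():
    assert set(valid_condition_orders()) == _brute_force_valid_orders()


def test_condition_order_draws_are_valid_uniformish_and_deterministic():
    seen = {generate_condition_order(seed) for seed in range(200)}
    valid = _brute_force_valid_orders()
    assert seen == valid  # all drawn orders valid, every valid order reachable
    assert generate_condition_order(7) == generate_condition_order(7)
    for order in seen:  # the two high-emotion conditions never adjacent
        for u, v in zip(order, order[1:]):
            assert {u, v} != {"HELS", "HEHS"}
            assert {u, v} != {"LEHS", "HEHS"}


# ----------------------------------------------------------- IBI generator

def test_zero_tone_series_is_constant():
    s = generate_ibi_series(120, 850, vagal_tone=0.0, rsa_freq_hz=0.25, seed=0)
    assert np.ptp(s.intervals) == 0
    assert vf.compute_rmssd(s) == 0.0


def test_ibi_duration_and_shift():
    s = generate_ibi_series(120, 850, 1.0, 0.25, shift_ms=100, seed=1)
    assert s.duration_s == pytest.approx(120, rel=0.10)
    assert s.intervals.mean() == pytest.approx(950, rel=0.05)


@pytest.mark.parametrize("kwargs", [
    dict(duration_s=0.0),
    dict(duration_s=-5.0),
    dict(duration_s=60, mean_ibi_ms=250.0),
    dict(duration_s=60, mean_ibi_ms=2500.0),
    dict(duration_s=60, vagal_tone=-1.0),
])
def test_ibi_generator_rejects_bad_arguments(kwargs):
    with pytest.raises(ValueError):
        generate_ibi_series(**kwargs)


def test_rmssd_monotone_in_vagal_tone():
    tones = (1.0, 2.0, 3.0)
    means = []
    for tone in tones:
        vals = [vf.compute_rmssd(generate_ibi_series(120, 850, tone, 0.25, seed=k))
                for k in range(20)]
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_analytic_rmssd_matches_simulation():
    for tone in (0.5, 1.0, 2.0):
        obs = np.mean([vf.compute_rmssd(
            generate_ibi_series(300, 850, tone, 0.25, seed=k)) for k in range(10)])
        assert obs == pytest.approx(
            expected_rmssd(tone, 0.25, 850), rel=0.05)


# -------------------------------------------------------------- Stroop trials

def test_trials_structure_and_counts():
    tr = generate_trials("LELS", 0.0, CohortSpec(), seed=0)
    assert len(tr) == 64
    assert (tr["congruency"] == "congruent").sum() == 32
    assert (tr["congruency"] == "incongruent").sum() == 32
    assert (tr["rt_ms"].dropna() <= 5000).all()


def test_trials_null_effect_when_interference_zero():
    spec = CohortSpec(interference_ms=0.0, emotion_distraction_ms=0.0)
    vals = [rt_interference(generate_trials("HEHS", 0.0, spec, seed=k))
            for k in range(50)]
    # mean over 50 sessions within ~3 standard errors of zero
    assert abs(np.mean(vals)) < 21.0


def test_trials_law_of_large_numbers_interference():
    spec = CohortSpec(interference_ms=120.0, emotion_distraction_ms=0.0)
    tr = generate_trials("LELS", 0.0, spec, seed=0, n_trials=10_000)
    assert rt_interference(tr) == pytest.approx(120.0, abs=5.0)


def test_trials_emotion_distraction_with_zero_flex_scaling():
    spec = CohortSpec(interference_ms=100.0, emotion_distraction_ms=60.0,
                      flex_attenuation=0.0)
    he = rt_interference(generate_trials("HELS", 0.0, spec, seed=1, n_trials=20_000))
    le = rt_interference(generate_trials("LELS", 0.0, spec, seed=2, n_trials=20_000))
    assert he - le == pytest.approx(60.0, abs=8.0)


def test_trials_distraction_shrinks_with_flexibility():
    spec = CohortSpec(interference_ms=100.0, emotion_distraction_ms=60.0)
    low = rt_interference(generate_trials("HELS", -1.5, spec, seed=3, n_trials=20_000))
    high = rt_interference(generate_trials("HELS", 1.5, spec, seed=4, n_trials=20_000))
    assert low > high + 20


def test_trials_censoring_records_missing_rt_as_incorrect():
    spec = CohortSpec(base_rt_ms=4900.0, rt_tau_ms=400.0)
    tr = generate_trials("LELS", 0.0, spec, seed=0, n_trials=2000)
    censored = tr["rt_ms"].isna()
    assert censored.any()
    assert not tr.loc[censored, "correct"].any()


def test_trials_invalid_condition():
    with pytest.raises(ValueError):
        generate_trials("XXXX", 0.0, CohortSpec(), seed=0)


# ------------------------------------------------------------- full cohort

def test_cohort_structure_and_counterbalancing(small_cohort):
    sessions, truth = small_cohort
    valid = _brute_force_valid_orders()
    for s in sessions:
        assert len(s.segments) == 9
        assert s.condition_order in valid  # exhaustive adjacency check
        assert s.segments["rest_baseline"].duration_s == pytest.approx(300, rel=0.10)
        for c in CONDITIONS:
            assert s.segments[f"{c}_baseline"].duration_s == pytest.approx(120, rel=0.10)
        assert len(s.trials) == 256
        counts = s.trials.groupby(["condition", "congruency"]).size()
        assert (counts == 32).all()


def test_cohort_latent_equations_consistent(small_cohort):
    _, truth = small_cohort
    spec = truth.spec
    sd_m, sd_y = spec.resolved_noise_sds()
    lat = truth.latents
    e_m = lat["F"] - spec.path_a * lat["T"]
    e_y = lat["S"] - spec.path_b * lat["F"] - spec.path_c_prime * lat["T"]
    # stored latents are exactly the structural equations plus residuals
    assert np.isfinite(e_m).all() and np.isfinite(e_y).all()
    n = len(lat)
    assert e_m.std(ddof=1) == pytest.approx(sd_m, rel=4.0 / np.sqrt(n))
    assert e_y.std(ddof=1) == pytest.approx(sd_y, rel=4.0 / np.sqrt(n))


def test_cohort_determinism_byte_identical_files(tmp_path):
    spec = vf.CohortSpec(n_subjects=4, seed=99)
    for sub in ("a", "b"):
        sessions, truth = vf.generate_cohort(spec)
        vf.write_cohort(sessions, tmp_path / sub, truth)
    files_a = sorted((tmp_path / "a").iterdir())
    files_b = sorted((tmp_path / "b").iterdir())
    assert [f.name for f in files_a] == [f.name for f in files_b]
    for fa, fb in zip(files_a, files_b):
        assert fa.read_bytes() == fb.read_bytes()


def test_monotone_encoding_of_resting_trait():
    """Across subjects the latent trait T drives measured resting RMSSD."""
    sessions, truth = vf.generate_cohort(vf.CohortSpec(n_subjects=300, seed=77))
    rmssd = np.array([vf.compute_rmssd(s.segments["rest_baseline"])
                      for s in sessions])
    rho = np.corrcoef(truth.latents["T"].to_numpy(), rmssd)[0, 1]
    assert rho > 0.7


def test_spec_validation_errors():
    with pytest.raises(ValueError):
        vf.CohortSpec(n_subjects=3).validate()
    with pytest.raises(ValueError):
        vf.CohortSpec(rsa_freq_hz=0.5).validate()
    with pytest.raises(ValueError):
        vf.CohortSpec(accuracy_base=1.5).validate()
    with pytest.raises(ValueError):
        vf.CohortSpec(path_a=1.2).validate()  # cannot standardize mediator
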