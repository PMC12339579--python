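"""Rasch model: probabilities, estimation, fit statistics, reliability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from vocabcat.rasch import (
    CalibrationConfig,
    ExtremeResponsePatternError,
    ResponseMatrix,
    calibrate_items,
    estimate_ability,
    fit_statistics,
    item_response_curve,
    response_probability,
    separation_reliability,
)

finite = st.floats(-30, 30, allow_nan=False)


# ---------------------------------------------------------------------------
# response probability


def test_probability_is_half_when_ability_equals_difficulty():
    assert response_probability(1.2, 1.2) == pytest.approx(0.5, abs=1e-15)


def test_probability_closed_form_value():
    # expit(2.197224577) = 0.9 to high precision
    assert response_probability(0.0, -2.197224577) == pytest.approx(0.9, abs=1e-6)


def test_probability_monotone_and_limits():
    thetas = np.linspace(-5, 5, 41)
    p = response_probability(thetas, 0.0)
    assert np.all(np.diff(p) > 0)
    assert response_probability(40.0, 0.0) > 1 - 1e-15


def test_probability_rejects_non_finite():
    with pytest.raises(ValueError):
        response_probability(float("nan"), 0.0)


@settings(derandomize=True, max_examples=100)
@given(b=finite, d=st.floats(0, 20, allow_nan=False))
def test_probability_point_symmetry_about_half(b, d):
    # P(b+d, b) + P(b-d, b) = 1 for all offsets d
    assert response_probability(b + d, b) + response_probability(b - d, b) == (
        pytest.approx(1.0, abs=1e-12)
    )


# ---------------------------------------------------------------------------
# ability estimation


def test_ml_symmetric_pattern_roots_at_common_difficulty():
    theta, se = estimate_ability([(0.0, 1), (0.0, 0)], method="ml")
    assert theta == pytest.approx(0.0, abs=1e-9)
    assert se == pytest.approx(1.0 / np.sqrt(0.5), rel=1e-9)


def test_ml_raises_on_extreme_pattern():
    with pytest.raises(ExtremeResponsePatternError):
        estimate_ability([(0.0, 1), (1.0, 1)], method="ml")


def test_eap_finite_and_shrunk_for_all_correct_pattern():
    bs = [0.0, 1.0, 2.0]
    theta, se = estimate_ability([(b, 1) for b in bs], method="eap", prior=(0.0, 3.0))
    assert np.isfinite(theta) and theta > max(bs) * 0  # finite, positive
    assert theta > 0
    assert se < 3.0  # posterior sd below the prior sd


def test_eap_order_invariance():
    resp = [(-1.0, 1), (0.5, 0), (1.5, 1), (0.0, 0)]
    a = estimate_ability(resp, method="eap")
    b = estimate_ability(list(reversed(resp)), method="eap")
    assert a == pytest.approx(b, abs=1e-12)


def test_eap_error_consistent_with_reported_se():
    """Over replications at a fixed true ability, the RMSE of the EAP
    estimate should match the mean reported posterior SD within 20%."""
    rng = np.random.default_rng(11)
    true_theta, n_items, reps = 1.0, 30, 1000
    bs = np.full(n_items, true_theta)  # difficulty-matched items
    errors, ses = [], []
    for _ in range(reps):
        x = (rng.random(n_items) < expit(true_theta - bs)).astype(int)
        if x.min() == x.max():
            continue
        theta, se = estimate_ability(list(zip(bs, x)), method="eap", prior=(0.0, 3.0))
        errors.append(theta - true_theta)
        ses.append(se)
    rmse = float(np.sqrt(np.mean(np.square(errors))))
    assert rmse == pytest.approx(np.mean(ses), rel=0.2)


# ---------------------------------------------------------------------------
# fit statistics


def _brute_force_fit(matrix, difficulties, abilities, axis):
    """Independent double-loop oracle for outfit/infit and their z forms."""
    ids = matrix.item_ids if axis == "item" else matrix.person_ids
    out = {}
    for k, eid in enumerate(ids):
        z2s, r2s, ws, cs, cw2 = [], [], [], [], []
        for i, pid in enumerate(matrix.person_ids):
            for j, iid in enumerate(matrix.item_ids):
                if (axis == "item" and iid != eid) or (axis == "person" and pid != eid):
                    continue
                x = matrix.scores[i, j]
                if np.isnan(x):
                    continue
                p = 1 / (1 + np.exp(-(abilities[pid] - difficulties[iid])))
                w = p * (1 - p)
                z2s.append((x - p) ** 2 / w)
                r2s.append((x - p) ** 2)
                ws.append(w)
                c = p * (1 - p) ** 4 + (1 - p) * p**4
                cs.append(c)
                cw2.append(c / w**2)
        if not z2s:
            continue
        n = len(z2s)
        outfit = sum(z2s) / n
        infit = sum(r2s) / sum(ws)
        q2o = max(sum(cw2) / n**2 - 1 / n, 0.0)
        q2i = max((sum(cs) - sum(w**2 for w in ws)) / sum(ws) ** 2, 0.0)

        def wh(mse, q2):
            if q2 <= 0:
                return 0.0
            q = np.sqrt(q2)
            return (mse ** (1 / 3) - 1) * (3 / q) + q / 3

        out[eid] = (outfit, infit, wh(outfit, q2o), wh(infit, q2i))
    return out


def test_outfit_hand_example_single_person():
    # one person, two items with P = 0.5 and 0.8, scores 1 and 0:
    # z^2 = 1 and 4, so the person outfit is 2.5 exactly
    matrix = ResponseMatrix(("p",), ("a", "b"), np.array([[1.0, 0.0]]))
    diffs = {"a": 0.0, "b": -float(np.log(4.0))}  # P(0, b) = 0.8
    fit = fit_statistics(matrix, diffs, {"p": 0.0}, axis="person")
    assert fit[0].outfit_mse == pytest.approx(2.5, abs=1e-12)


@pytest.mark.parametrize("axis", ["item", "person"])
def test_fit_statistics_match_brute_force_oracle(axis):
    rng = np.random.default_rng(3)
    for trial in range(5):
        scores = rng.integers(0, 2, (10, 10)).astype(float)
        scores[rng.random((10, 10)) < 0.2] = np.nan
        # ensure every row/column keeps at least one scored cell
        scores[:, 0] = rng.integers(0, 2, 10)
        scores[0, :] = rng.integers(0, 2, 10)
        matrix = ResponseMatrix(
            tuple(f"p{i}" for i in range(10)), tuple(f"i{j}" for j in range(10)), scores
        )
        diffs = {f"i{j}": float(rng.normal(0, 1.5)) for j in range(10)}
        abils = {f"p{i}": float(rng.normal(0, 1.5)) for i in range(10)}
        got = {f.entity_id: f for f in fit_statistics(matrix, diffs, abils, axis)}
        want = _brute_force_fit(matrix, diffs, abils, axis)
        assert set(got) == set(want)
        for eid, (o, i_, zo, zi) in want.items():
            assert got[eid].outfit_mse == pytest.approx(o, abs=1e-12)
            assert got[eid].infit_mse == pytest.approx(i_, abs=1e-12)
            assert got[eid].std_outfit == pytest.approx(zo, abs=1e-12)
            assert got[eid].std_infit == pytest.approx(zi, abs=1e-12)


def test_fit_statistics_near_one_under_the_model():
    rng = np.random.default_rng(21)
    n, m = 5000, 100
    b = np.linspace(-3, 3, m)
    theta = rng.normal(0, 2, n)
    X = (rng.random((n, m)) < expit(theta[:, None] - b[None, :])).astype(float)
    matrix = ResponseMatrix(
        tuple(f"p{i}" for i in range(n)), tuple(f"i{j}" for j in range(m)), X
    )
    fit = fit_statistics(
        matrix,
        {f"i{j}": b[j] for j in range(m)},
        {f"p{i}": theta[i] for i in range(n)},
        axis="item",
    )
    outfits = np.array([f.outfit_mse for f in fit])
    infits = np.array([f.infit_mse for f in fit])
    assert 0.97 < outfits.mean() < 1.03
    assert 0.97 < infits.mean() < 1.03


def test_guttman_pattern_overfits():
    # deterministic responses (correct iff the item is below the person)
    # are less noisy than the model expects: outfit below 1
    grid = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    X = (grid[None, :] < grid[:, None]).astype(float)
    matrix = ResponseMatrix(
        tuple(f"p{i}" for i in range(5)), tuple(f"i{j}" for j in range(5)), X
    )
    fit = fit_statistics(
        matrix,
        {f"i{j}": grid[j] for j in range(5)},
        {f"p{i}": grid[i] for i in range(5)},
        axis="person",
    )
    assert np.mean([f.outfit_mse for f in fit]) < 1.0


def test_fit_statistics_requires_parameters_for_every_cell():
    matrix = ResponseMatrix(("p",), ("a",), np.array([[1.0]]))
    with pytest.raises(ValueError, match="difficulty"):
        fit_statistics(matrix, {}, {"p": 0.0}, axis="item")


# ---------------------------------------------------------------------------
# calibration


def test_calibration_recovers_known_difficulties():
    rng = np.random.default_rng(42)
    n, m = 2000, 200
    b = np.linspace(-4, 4, m)
    theta = rng.normal(0, 2, n)
    X = (rng.random((n, m)) < expit(theta[:, None] - b[None, :])).astype(float)
    matrix = ResponseMatrix(
        tuple(f"p{i}" for i in range(n)), tuple(f"i{j}" for j in range(m)), X
    )
    res = calibrate_items(matrix)
    assert res.converged
    est = np.array([res.item_difficulties[f"i{j}"][0] for j in range(m)])
    rmse = float(np.sqrt(np.mean((est - b) ** 2)))
    assert rmse < 0.15
    # estimated latent sd close to the generating sd
    assert res.prior_sd == pytest.approx(2.0, abs=0.15)


def test_symmetric_items_get_symmetric_difficulties():
    # item A correct iff item B incorrect, balanced across persons
    n = 100
    X = np.zeros((n, 2))
    X[: n // 2, 0] = 1.0
    X[n // 2:, 1] = 1.0
    matrix = ResponseMatrix(
        tuple(f"p{i}" for i in range(n)), ("A", "B"), X
    )
    res = calibrate_items(matrix)
    bA = res.item_difficulties["A"][0]
    bB = res.item_difficulties["B"][0]
    assert bA == pytest.approx(-bB, abs=1e-6)


def test_all_correct_item_reported_non_estimable():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 2, (50, 3)).astype(float)
    X[:, 2] = 1.0
    matrix = ResponseMatrix(
        tuple(f"p{i}" for i in range(50)), ("a", "b", "allcorrect"), X
    )
    res = calibrate_items(matrix)
    assert "allcorrect" in res.non_estimable
    assert "allcorrect" not in res.item_difficulties


def test_recovery_error_shrinks_with_sample_size():
    rng = np.random.default_rng(9)
    m = 60
    b = np.linspace(-3, 3, m)
    rmses = []
    for n in (250, 500, 1000):
        theta = rng.normal(0, 2, n)
        X = (rng.random((n, m)) < expit(theta[:, None] - b[None, :])).astype(float)
        matrix = ResponseMatrix(
            tuple(f"p{i}" for i in range(n)), tuple(f"i{j}" for j in range(m)), X
        )
        res = calibrate_items(matrix)
        est = np.array(
            [res.item_difficulties.get(f"i{j}", (np.nan,))[0] for j in range(m)]
        )
        ok = np.isfinite(est)
        rmses.append(float(np.sqrt(np.mean((est[ok] - b[ok]) ** 2))))
    assert rmses[0] >= rmses[1] >= rmses[2]


# ---------------------------------------------------------------------------
# separation reliability


def test_reliability_one_when_ses_are_zero():
    rel, G, strata = separation_reliability([(0.0, 0.0), (1.0, 0.0), (2.5, 0.0)])
    assert rel == 1.0
    assert np.isinf(G)


def test_reliability_zero_when_spread_is_all_noise():
    # sample variance of {0, 2} is 2; mean error variance 2 as well
    rel, G, strata = separation_reliability([(0.0, np.sqrt(2)), (2.0, np.sqrt(2))])
    assert rel == 0.0
    assert G == 0.0
    assert strata == pytest.approx(1.0 / 3.0)


def test_reliability_095_implies_G_and_strata():
    # var 20, mean se^2 = 1 -> R = 19/20 = .95
    estimates = [(0.0, 1.0), (np.sqrt(40.0), 1.0)]
    rel, G, strata = separation_reliability(estimates)
    assert rel == pytest.approx(0.95, abs=1e-12)
    assert G == pytest.approx(4.3589, abs=1e-4)
    assert strata == pytest.approx(6.145, abs=1e-3)


@settings(derandomize=True, max_examples=50)
@given(
    values=st.lists(st.floats(-5, 5), min_size=3, max_size=12),
    ses=st.lists(st.floats(0.01, 2), min_size=12, max_size=12),
)
def test_reliability_identity_R_equals_G2_over_1_plus_G2(values, ses):
    estimates = list(zip(values, ses))
    if np.var(values, ddof=1) == 0:
        return
    rel, G, _ = separation_reliability(estimates)
    if np.isinf(G):
        return
    assert rel == pytest.approx(G**2 / (1 + G**2), abs=1e-9)


# ---------------------------------------------------------------------------
# item response curves


def test_curve_expected_column_is_monotone():
    rng = np.random.default_rng(2)
    n = 500
    theta = rng.normal(0, 2, n)
    scores = (rng.random(n) < expit(theta - 0.5)).astype(float)
    matrix = ResponseMatrix(
        tuple(f"p{i}" for i in range(n)), ("it",), scores[:, None]
    )
    curve = item_response_curve(
        matrix, "it", 0.5, {f"p{i}": theta[i] for i in range(n)}, n_bins=8
    )
    assert len(curve) == 8
    assert curve["expected"].is_monotonic_increasing


def test_curve_empirical_within_binomial_bands():
    rng = np.random.default_rng(14)
    n = 2000
    theta = rng.normal(0, 2, n)
    b = 0.0
    scores = (rng.random(n) < expit(theta - b)).astype(float)
    matrix = ResponseMatrix(
        tuple(f"p{i}" for i in range(n)), ("it",), scores[:, None]
    )
    curve = item_response_curve(
        matrix, "it", b, {f"p{i}": theta[i] for i in range(n)}, n_bins=10
    )
    from scipy.stats import binom

    for _, row in curve.iterrows():
        k = row["observed"] * row["count"]
        lo, hi = binom.interval(0.99, row["count"], row["expected"])
        assert lo - 1e-9 <= k <= hi + 1e-9


def test_curve_collapses_for_identical_abilities():
    matrix = ResponseMatrix(
        ("p1", "p2", "p3", "p4"), ("it",), np.array([[1.0], [0.0], [1.0], [1.0]])
    )
    with pytest.warns(UserWarning, match="reduced"):
        curve = item_response_curve(
            matrix, "it", 0.0, {p: 0.3 for p in matrix.person_ids}, n_bins=4
        )
    assert len(curve) == 1
    assert curve.loc[0, "observed"] == pytest.approx(0.75)
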