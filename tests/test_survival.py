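"""Dose-response survival statistics and rank correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from phrscan.simulate import PAPER_DOSES, gen_survival
from phrscan.survival import (
    genotype_phenotype_correlation,
    percent_survival,
    photoreactivation_benefit,
    rank_strains,
    spearman_rho,
    summarize_strain,
)


def _records(strain, cond, doses, counts, dilution=1.0, replicate=1):
    return pd.DataFrame(
        {
            "strain": strain,
            "condition": cond,
            "dose_J_per_m2": doses,
            "replicate": replicate,
            "dilution": dilution,
            "cfu": counts,
        }
    )


def test_flat_counts_give_flat_curve():
    df = _records("s", "light", [0, 24, 48], [500, 500, 500])
    sd = percent_survival(df)
    assert np.allclose(sd.curve("s", "light").percent_survival, 100.0)


def test_dose_zero_only_curve():
    sd = percent_survival(_records("s", "dark", [0], [300]))
    curve = sd.curve("s", "dark")
    assert len(curve) == 1 and curve.percent_survival.iloc[0] == 100.0


def test_missing_dose_zero_or_negative_counts_rejected():
    with pytest.raises(ValueError, match="dose-0"):
        percent_survival(_records("s", "light", [24, 48], [10, 5]))
    with pytest.raises(ValueError, match="negative"):
        percent_survival(_records("s", "light", [0, 24], [10, -1]))


def test_survival_invariant_to_uniform_count_rescaling():
    base = _records("s", "light", [0, 24, 48], [1000, 400, 150])
    scaled = base.assign(cfu=base.cfu * 17)
    a = percent_survival(base).curve("s", "light").percent_survival
    b = percent_survival(scaled).curve("s", "light").percent_survival
    assert np.allclose(a, b)


def test_zero_count_floored_and_censored():
    df = _records("s", "dark", [0, 24, 48], [1000, 10, 0], dilution=100.0)
    sd = percent_survival(df)
    curve = sd.curve("s", "dark")
    assert bool(curve[curve.dose == 48].censored.iloc[0])
    s48 = curve[curve.dose == 48].percent_survival.iloc[0]
    assert 0 < s48 < curve[curve.dose == 24].percent_survival.iloc[0]
    assert np.isfinite(np.log10(s48))


def test_noiseless_slope_recovery_is_exact():
    k = 0.03
    counts, _, truth = gen_survival(seed=0, kill_rates={"s": {"light": k, "dark": k}}, cv=0.0, n0=1e7)
    sd = percent_survival(counts)
    summ = summarize_strain(sd, "s", "light")
    assert summ.slope == pytest.approx(-k / math.log(10), rel=1e-3)
    assert summ.d10 == pytest.approx(math.log(10) / k, rel=1e-3)


def test_slope_recovery_median_error_under_noise():
    """Median |slope error| < 10% of truth across 100 simulated strains at CV 20%."""
    rng = np.random.default_rng(42)
    rates = {f"s{i:03d}": {"light": float(k), "dark": float(k)} for i, k in enumerate(rng.uniform(0.01, 0.06, size=100))}
    counts, _, truth = gen_survival(seed=42, kill_rates=rates, cv=0.2, n0=1e7)
    sd = percent_survival(counts)
    errors = []
    for s, ks in rates.items():
        est = summarize_strain(sd, s, "light").slope
        expected = truth["expected_log10_slope"][s]["light"]
        errors.append(abs(est - expected) / abs(expected))
    assert np.median(errors) < 0.10


def test_benefit_zero_for_identical_conditions():
    df = pd.concat([_records("s", c, [0, 24, 48], [1000, 500, 250]) for c in ("light", "dark")])
    _, mean_benefit = photoreactivation_benefit(percent_survival(df), "s")
    assert mean_benefit == pytest.approx(0.0)


def test_benefit_closed_form_for_double_dark_kill():
    kl, kd = 0.02, 0.04
    counts, _, _ = gen_survival(seed=0, kill_rates={"s": {"light": kl, "dark": kd}}, cv=0.0, n0=1e7)
    table, _ = photoreactivation_benefit(percent_survival(counts), "s")
    expected = (kd - kl) / math.log(10)
    for row in table.itertuples(index=False):
        assert row.benefit == pytest.approx(expected * row.dose, rel=2e-3, abs=1e-6)


def test_benefit_antisymmetric_under_condition_swap():
    counts, _, _ = gen_survival(seed=1, kill_rates={"s": {"light": 0.01, "dark": 0.05}}, cv=0.0)
    swapped = counts.assign(condition=counts.condition.map({"light": "dark", "dark": "light"}))
    t1, m1 = photoreactivation_benefit(percent_survival(counts), "s")
    t2, m2 = photoreactivation_benefit(percent_survival(swapped), "s")
    assert np.allclose(t1.benefit, -t2.benefit)
    assert m1 == pytest.approx(-m2)


def test_missing_condition_is_an_error():
    sd = percent_survival(_records("s", "light", [0, 24], [100, 50]))
    with pytest.raises(KeyError, match="dark"):
        photoreactivation_benefit(sd, "s")


def test_planted_ranking_recovered():
    rates = {
        "best": {"light": 0.005, "dark": 0.03},
        "mid": {"light": 0.02, "dark": 0.04},
        "worst": {"light": 0.06, "dark": 0.06},
    }
    counts, _, _ = gen_survival(seed=5, kill_rates=rates, cv=0.1, n0=1e7)
    ranking = rank_strains(percent_survival(counts))
    assert list(ranking.strain) == ["best", "mid", "worst"]


def test_tied_strains_break_lexicographically_and_flag():
    df = pd.concat(
        [_records(s, c, [0, 24], [1000, 500]) for s in ("b_strain", "a_strain") for c in ("light", "dark")]
    )
    ranking = rank_strains(percent_survival(df))
    assert list(ranking.strain) == ["a_strain", "b_strain"]
    assert ranking.tied.all()


@pytest.mark.parametrize("ranks,expected", [([1, 2, 3, 4, 5], 1.0), ([5, 4, 3, 2, 1], -1.0)])
def test_spearman_perfect_concordance(ranks, expected):
    x = {f"s{i}": float(i) for i in range(1, 6)}
    y = {f"s{i}": float(r) for i, r in zip(range(1, 6), ranks)}
    res = genotype_phenotype_correlation(x, y)
    assert res["rho"] == pytest.approx(expected)


def test_spearman_matches_scipy():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert spearman_rho(x, y) == pytest.approx(scipy.stats.spearmanr(x, y).statistic)


def test_permutation_p_equals_exhaustive_enumeration_n6():
    """The reported p equals an independent brute-force enumeration over all 720 permutations."""
    x = {f"s{i}": v for i, v in enumerate([0.0, -1.0, -2.0, -5.0, -3.0, -9.0])}
    y = {f"s{i}": v for i, v in enumerate([90.0, 75.0, 60.0, 20.0, 35.0, 5.0])}
    res = genotype_phenotype_correlation(x, y)
    xs = np.array([x[f"s{i}"] for i in range(6)])
    ys = np.array([y[f"s{i}"] for i in range(6)])
    obs = scipy.stats.spearmanr(xs, ys).statistic
    hits = sum(
        1
        for perm in itertools.permutations(range(6))
        if abs(scipy.stats.spearmanr(xs, ys[list(perm)]).statistic) >= abs(obs) - 1e-12
    )
    assert res["exact"]
    assert res["p_value"] == pytest.approx(hits / math.factorial(6))
    assert -1.0 <= res["rho"] <= 1.0
    assert 0.0 < res["p_value"] <= 1.0


def test_correlation_needs_four_strains():
    with pytest.raises(ValueError):
        genotype_phenotype_correlation({"a": 1, "b": 2, "c": 3}, {"a": 1, "b": 2, "c": 3})


def test_paper_shaped_preset_orders_habitat_groups():
    counts, _, truth = gen_survival(seed=9, preset="paper-shaped")
    ranking = rank_strains(percent_survival(counts))
    order = list(ranking.strain)
    subsurface = {"BOL5-1", "BOL5-4", "BOL6-1"}
    assert set(order[-3:]) == subsurface
    assert order.index("Hla") == len(order) - 4  # sediment isolate just above subsurface
    assert set(PAPER_DOSES) == {0.0, 24.0, 48.0, 96.0, 144.0}
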