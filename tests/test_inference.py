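"""Factorial ANOVA, pooled-bootstrap p values, bootstrap tests, FDR, ANCOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from meglat import (
    GROUP_CTR,
    GROUP_LT,
    GROUP_RT,
    BootstrapSpec,
    SynthConfig,
    bh_fdr,
    bootstrap_f_pvalues,
    bootstrap_one_sample,
    bootstrap_two_sample,
    generate_source_image_cohort,
    make_toy_forward,
    mass_univariate_ancova,
    two_way_anova,
)
from meglat.inference import EFFECTS, TypeIIIDesign

REGIONS4 = ("frontal", "temporal", "parietal", "occipital")


def _long(groups, regions, values):
    return pd.DataFrame({"group": groups, "region": regions, "li": values})


def _balanced_table(rng, n_per_cell=6, group_shift=0.5, noise=0.2):
    rows = []
    for g, shift in (("LtMTLE", group_shift), ("RtMTLE", 0.0)):
        for r in REGIONS4:
            for _ in range(n_per_cell):
                rows.append((g, r, shift + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["group", "region", "li"])


def _balanced_oracle(df):
    """Textbook sums-of-squares decomposition on a balanced 2x4 table."""
    y = df["li"].to_numpy()
    grand = y.mean()
    n = len(y)
    cells = df.groupby(["group", "region"])["li"]
    n_cell = cells.size().iloc[0]
    g_means = df.groupby("group")["li"].mean()
    r_means = df.groupby("region")["li"].mean()
    ss_g = (n // 2) * ((g_means - grand) ** 2).sum()
    ss_r = (n // 4) * ((r_means - grand) ** 2).sum()
    cell_means = cells.mean()
    ss_cells = n_cell * ((cell_means - grand) ** 2).sum()
    ss_i = ss_cells - ss_g - ss_r
    ss_e = ((y - df.groupby(["group", "region"])["li"].transform("mean")) ** 2).sum()
    df_e = n - 8
    return {
        "group_main": (ss_g / 1) / (ss_e / df_e),
        "region_main": (ss_r / 3) / (ss_e / df_e),
        "interaction": (ss_i / 3) / (ss_e / df_e),
    }


def test_two_way_anova_matches_hand_ss_on_balanced_data():
    rng = np.random.default_rng(0)
    df = _balanced_table(rng)
    res = two_way_anova(df)
    oracle = _balanced_oracle(df)
    for effect in EFFECTS:
        assert res[effect].F == pytest.approx(oracle[effect], rel=1e-9)
    # additive group shift only: interaction F below the group main effect F
    assert res["interaction"].F < res["group_main"].F


def test_two_way_anova_degenerate_constant():
    groups = ["LtMTLE"] * 8 + ["RtMTLE"] * 8
    regions = list(REGIONS4) * 4
    df = _long(groups, regions, np.full(16, 0.7))
    res = two_way_anova(df)
    for effect in EFFECTS:
        assert res[effect].F == 0.0
        assert res[effect].degenerate


def test_two_way_anova_input_validation():
    df = _balanced_table(np.random.default_rng(1))
    with pytest.raises(ValueError, match="two groups"):
        two_way_anova(df[df["group"] == "LtMTLE"])
    with pytest.raises(ValueError, match="cell"):
        two_way_anova(df[~((df["group"] == "LtMTLE") & (df["region"] == "parietal"))])


def test_fast_type3_path_equals_statsmodels_on_unbalanced_data():
    rng = np.random.default_rng(2)
    rows = []
    for g, n in (("LtMTLE", 16), ("RtMTLE", 19)):
        for r in REGIONS4:
            for _ in range(n):
                rows.append((g, r, rng.normal(0.2 if g == "LtMTLE" else 0.0, 0.3)))
    df = pd.DataFrame(rows, columns=["group", "region", "li"])
    ref = two_way_anova(df)
    design = TypeIIIDesign(df["group"].to_numpy(), df["region"].to_numpy())
    fast = design.f_stats(df["li"].to_numpy())
    for effect in EFFECTS:
        assert fast[effect][0] == pytest.approx(ref[effect].F, rel=1e-9)


def test_bootstrap_f_matches_per_resample_anova_oracle():
    """Tail counts agree with recomputing the full ANOVA per resample using the
    same resample draws (statsmodels route, inclusive tails)."""
    rng = np.random.default_rng(3)
    df = _balanced_table(rng, n_per_cell=3, group_shift=0.3)
    n = len(df)
    seed, B = 99, 40
    res = two_way_anova(df)
    p = bootstrap_f_pvalues(df, res, BootstrapSpec(n_resamples=B, seed=seed))
    idx = np.random.default_rng(seed).integers(0, n, size=(B, n))
    y = df["li"].to_numpy()
    ge = {e: 0 for e in EFFECTS}
    le = {e: 0 for e in EFFECTS}
    for b in range(B):
        redealt = df.copy()
        redealt["li"] = y[idx[b]]
        r_b = two_way_anova(redealt)
        for e in EFFECTS:
            ge[e] += r_b[e].F >= res[e].F
            le[e] += r_b[e].F <= res[e].F
    for e in EFFECTS:
        assert p[e] == pytest.approx(min(ge[e], le[e]) / B)


def test_bootstrap_f_strong_effect_is_significant():
    """A strong group effect in theta-band LIs yields p_boot below 0.001,
    mirroring the qualitative group main effect of the laterality analysis."""
    cfg = SynthConfig(n_ctr=2, n_lt=16, n_rt=19, effect_delta=1.0, seed=5)
    from meglat import generate_power_cohort, li_table

    li = li_table(generate_power_cohort(cfg))
    theta = li[(li["band"] == "theta") & (li["group"] != GROUP_CTR)]
    res = two_way_anova(theta)
    p = bootstrap_f_pvalues(theta, res, BootstrapSpec(n_resamples=5000, seed=0))
    assert p["group_main"] <= 0.001


def test_one_sample_constant_sign_and_degenerate():
    spec = BootstrapSpec(n_resamples=500, seed=0)
    assert bootstrap_one_sample(np.full(5, 0.2), spec) == 0.0
    assert bootstrap_one_sample(np.zeros(5), spec) == 0.5
    with pytest.raises(ValueError):
        bootstrap_one_sample(np.array([1.0]), spec)


def _enum_one_sample(values):
    """Exact smaller-tail probability by enumerating all n^n resamples."""
    n = len(values)
    pos = neg = 0
    for combo in itertools.product(range(n), repeat=n):
        m = np.mean([values[i] for i in combo])
        pos += m > 0
        neg += m < 0
    total = n**n
    return min(pos, neg) / total


def test_one_sample_matches_exhaustive_enumeration():
    values = np.array([0.1, -0.1, 0.3])
    exact = _enum_one_sample(values)  # = 4/27
    assert exact == pytest.approx(4 / 27)
    B = 20_000
    p = bootstrap_one_sample(values, BootstrapSpec(n_resamples=B, seed=7))
    assert abs(p - exact) <= 3 * np.sqrt(exact * (1 - exact) / B)


def test_one_sample_symmetric_values_enumeration():
    """Symmetric +-a samples: the exact smaller tail is (1 - P(mean*=0))/2,
    slightly below one half because the resampled mean has an atom at zero."""
    values = np.array([0.2, -0.2, 0.2, -0.2])
    exact = _enum_one_sample(values)
    B = 20_000
    p = bootstrap_one_sample(values, BootstrapSpec(n_resamples=B, seed=8))
    assert abs(p - exact) <= 3 * np.sqrt(exact * (1 - exact) / B)
    assert 0.3 < p < 0.5  # near, but strictly below, one half


def _enum_two_sample(a, b):
    """Exact smaller-tail probability over the joint resample distribution."""
    na, nb = len(a), len(b)
    pos = neg = 0
    for ca in itertools.product(range(na), repeat=na):
        ma = np.mean([a[i] for i in ca])
        for cb in itertools.product(range(nb), repeat=nb):
            d = ma - np.mean([b[j] for j in cb])
            pos += d > 0
            neg += d < 0
    total = na**na * nb**nb
    return min(pos, neg) / total


def test_two_sample_separated_and_enumeration():
    spec = BootstrapSpec(n_resamples=2000, seed=0)
    assert bootstrap_two_sample(np.ones(4), np.zeros(4), spec) == 0.0
    a = np.array([0.5, -0.1])
    b = np.array([0.2, 0.05])
    exact = _enum_two_sample(a, b)
    B = 20_000
    p = bootstrap_two_sample(a, b, BootstrapSpec(n_resamples=B, seed=4))
    assert abs(p - exact) <= 3 * np.sqrt(exact * (1 - exact) / B)


def test_bootstrap_order_invariance_and_reproducibility():
    rng = np.random.default_rng(10)
    x = rng.normal(0.1, 1.0, 12)
    spec = BootstrapSpec(n_resamples=3000, seed=21)
    assert bootstrap_one_sample(x, spec) == bootstrap_one_sample(x, spec)
    # resampling indexes i.i.d. uniformly, so value order cannot matter
    assert bootstrap_one_sample(x, spec) == bootstrap_one_sample(x[::-1].copy(), spec)


def _bh_oracle(p):
    """Literal step-up rule: find largest k with p_(k) <= k/m * q."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return adj


def test_bh_fdr_hand_example_and_edge_cases():
    out = bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(out["p_fdr"], 0.04)
    assert bh_fdr([0.2])["p_fdr"].iloc[0] == 0.2
    np.testing.assert_allclose(bh_fdr([0.5] * 6)["p_fdr"], 0.5)
    with pytest.raises(ValueError):
        bh_fdr([0.1, 1.2])


def test_bh_fdr_matches_bruteforce_on_random_families():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
        out = bh_fdr(p)
        np.testing.assert_allclose(out["p_fdr"], _bh_oracle(p), rtol=1e-12)
        np.testing.assert_array_equal(out["significant"], _bh_oracle(p) <= 0.05)


@pytest.fixture(scope="module")
def small_fm():
    return make_toy_forward(n_sensors=24, sources_per_cell=4, seed=1)


def test_ancova_null_familywise_error_controlled(small_fm):
    """Three identical groups: the max-statistic FWE correction keeps the
    family-wise false-positive rate near the nominal 5% level."""
    reps, n_perm = 150, 199
    rng = np.random.default_rng(12)
    cfg_kwargs = dict(n_ctr=10, n_lt=8, n_rt=8, effect_delta=0.0, baseline_li_mean=0.0)
    hits = 0
    for _ in range(reps):
        cfg = SynthConfig(seed=int(rng.integers(2**31)), **cfg_kwargs)
        images, groups, ages = generate_source_image_cohort(small_fm, "theta", cfg)
        res = mass_univariate_ancova(
            images, groups, ages, n_perm=n_perm, seed=int(rng.integers(2**31)),
            contrasts=("omnibus",),
        )
        hits += bool(res["omnibus"].significant.any())
    rate = hits / reps
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def test_ancova_detects_left_parietal_theta_elevation(small_fm):
    """An ipsilateral parietal theta elevation in left-focus patients produces
    detections concentrated (>= 80%) in left-parietal sources."""
    delta = pd.DataFrame(
        0.0, index=["delta", "theta", "alpha", "beta", "low_gamma", "high_gamma", "hfo"],
        columns=list(REGIONS4),
    )
    delta.loc["theta", "parietal"] = 0.8
    cfg = SynthConfig(n_ctr=40, n_lt=16, n_rt=2, effect_delta=delta, noise_cv=0.2, seed=13)
    images, groups, ages = generate_source_image_cohort(small_fm, "theta", cfg)
    res = mass_univariate_ancova(
        images, groups, ages, n_perm=300, seed=0, contrasts=("Lt_vs_CTR",)
    )["Lt_vs_CTR"]
    sig = res.significant
    assert sig.sum() >= 1
    in_target = (
        (small_fm.region_labels == "parietal") & (small_fm.hemisphere_labels == "L") & sig
    ).sum()
    assert in_target / sig.sum() >= 0.8


def test_ancova_age_covariate_absorbs_age_gradient(small_fm):
    """A pure age-driven power gradient with identical group means yields no
    excess detections once age is included as a nuisance covariate."""
    reps, hits = 40, 0
    rng = np.random.default_rng(14)
    for _ in range(reps):
        cfg = SynthConfig(
            n_ctr=12, n_lt=8, n_rt=8, effect_delta=0.0, baseline_li_mean=0.0,
            seed=int(rng.integers(2**31)),
        )
        images, groups, ages = generate_source_image_cohort(
            small_fm, "theta", cfg, age_slope=0.02
        )
        res = mass_univariate_ancova(
            images, groups, ages, n_perm=99, seed=int(rng.integers(2**31)),
            contrasts=("omnibus",),
        )
        hits += bool(res["omnibus"].significant.any())
    assert hits / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


def test_ancova_validates_design():
    images = np.random.default_rng(0).normal(size=(6, 5)) ** 2
    groups = np.array([GROUP_LT] * 2 + [GROUP_RT] * 2 + [GROUP_CTR] * 2)
    ages = np.arange(6.0)
    with pytest.raises(ValueError, match="fewer than 2"):
        mass_univariate_ancova(images[:5], groups[:5], ages[:5], n_perm=10)
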