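"""Group statistics for laterality indices and source images.

Four pieces of machinery:

* a 2 (group) x 4 (region) factorial ANOVA on baseline-corrected laterality
  indices, fitted per frequency band with Type III sums of squares and
  sum-to-zero coding (each subject contributes four region rows treated as
  independent cells);
* a pooled-bootstrap null for the ANOVA F statistics: all observations are
  resampled with replacement irrespective of group and region, redealt into
  the original design cells, and the smaller tail proportion of the resampled
  F distribution around the observed F is reported as the significance level;
* one-sample (against zero) and two-sample (left vs right patients)
  bootstrap tests on per-cell laterality indices, again with the smaller-tail
  rule;
* Benjamini-Hochberg FDR over the 28 band x region tests of each family, and
  a mass-univariate one-way ANCOVA across source locations with age as a
  nuisance covariate and family-wise error control by max-statistic
  permutation of group labels.

The smaller-tail rule is implemented literally (the minimum of the two tail
proportions, not doubled); a conventional two-sided value is simply twice the
returned p. Tail comparisons follow each test's definition: inclusive
(>= / <=) for the F bootstrap, strict (> / <) against zero for the one- and
two-sample tests. On continuous data ties occur with probability zero either
way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .bands import GROUP_CTR, GROUP_LT, GROUP_RT

__all__ = [
    "AnovaResult",
    "BootstrapSpec",
    "MassUnivariateResult",
    "two_way_anova",
    "bootstrap_f_pvalues",
    "bootstrap_one_sample",
    "bootstrap_two_sample",
    "bh_fdr",
    "mass_univariate_ancova",
    "laterality_stats",
]

EFFECTS = ("group_main", "region_main", "interaction")

_RESID_TOL = 1e-12


@dataclass
class AnovaResult:
    """One factorial-ANOVA effect: F, effect mean square, and p values."""

    effect: str
    F: float
    MS: float
    df_num: int
    df_den: int
    p_parametric: float
    p_boot: float | None = None
    degenerate: bool = False


@dataclass
class BootstrapSpec:
    """Resampling parameters; the smaller-tail rule is the only tail rule."""

    n_resamples: int = 20_000
    seed: int = 0
    tail_rule: str = "smaller_tail"

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.tail_rule != "smaller_tail":
            raise ValueError("only the smaller-tail rule is supported")


class TypeIIIDesign:
    """Fixed 2 x 4 sum-to-zero design with precomputed projection matrices.

    Because the pooled bootstrap redeals resampled values into the original
    cells, the design (and hence every hat matrix) is constant across
    resamples; F statistics for all three effects reduce to quadratic forms
    in the resampled response, evaluated here as one matrix product per model.
    """

    def __init__(self, groups: np.ndarray, regions: np.ndarray) -> None:
        groups = np.asarray(groups)
        regions = np.asarray(regions)
        g_cols = self._sum_coding(groups)
        r_cols = self._sum_coding(regions)
        inter = np.einsum("ni,nj->nij", g_cols, r_cols).reshape(len(groups), -1)
        ones = np.ones((len(groups), 1))
        self.n = len(groups)
        blocks = {"intercept": ones, "group_main": g_cols, "region_main": r_cols,
                  "interaction": inter}
        full = np.hstack(list(blocks.values()))
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError("design is rank deficient (empty group x region cell?)")
        self.df = {k: blocks[k].shape[1] for k in EFFECTS}
        self.df_resid = self.n - full.shape[1]
        if self.df_resid < 1:
            raise ValueError("no residual degrees of freedom")
        self._hats = {"full": self._hat(full)}
        for effect in EFFECTS:
            reduced = np.hstack([v for k, v in blocks.items() if k != effect])
            self._hats[effect] = self._hat(reduced)

    @staticmethod
    def _sum_coding(labels: np.ndarray) -> np.ndarray:
        levels = sorted(pd.unique(labels))
        if len(levels) < 2:
            raise ValueError("factor needs at least two levels")
        cols = [
            (labels == lev).astype(float) - (labels == levels[-1]).astype(float)
            for lev in levels[:-1]
        ]
        return np.column_stack(cols)

    @staticmethod
    def _hat(X: np.ndarray) -> np.ndarray:
        return X @ np.linalg.pinv(X)

    def f_stats(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Type III F statistics for columns of Y (shape (n,) or (n, B))."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T  # ensure (n, B)
        sse = {k: np.sum((Y - H @ Y) ** 2, axis=0) for k, H in self._hats.items()}
        out = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            for effect in EFFECTS:
                num = (sse[effect] - sse["full"]) / self.df[effect]
                den = sse["full"] / self.df_resid
                f = np.where(sse["full"] < _RESID_TOL, 0.0, num / den)
                out[effect] = f
        return out


def two_way_anova(data: pd.DataFrame) -> dict[str, AnovaResult]:
    """2 x 4 factorial ANOVA (Type III, sum-to-zero) on a long LI table.

    ``data`` needs columns (group, region, li) with exactly two groups and the
    four regions; every group x region cell must be non-empty. With zero
    residual variance (e.g., a constant response) all F values are reported
    as 0 with the ``degenerate`` flag set.
    """
    for col in ("group", "region", "li"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    counts = data.groupby(["group", "region"], observed=True).size()
    if data["group"].nunique() != 2:
        raise ValueError("exactly two groups required")
    if (counts < 1).any() or len(counts) != 2 * data["region"].nunique():
        raise ValueError("every group x region cell needs at least one observation")

    model = smf.ols("li ~ C(group, Sum) * C(region, Sum)", data=data).fit()
    label = {
        "C(group, Sum)": "group_main",
        "C(region, Sum)": "region_main",
        "C(group, Sum):C(region, Sum)": "interaction",
    }
    degenerate = model.ssr < _RESID_TOL
    table = sm.stats.anova_lm(model, typ=3)
    results: dict[str, AnovaResult] = {}
    for row_name, effect in label.items():
        row = table.loc[row_name]
        df_num = int(row["df"])
        ms = float(row["sum_sq"]) / df_num
        if degenerate:
            f_val, p_val = 0.0, 1.0
        else:
            f_val, p_val = float(row["F"]), float(row["PR(>F)"])
        results[effect] = AnovaResult(
            effect=effect,
            F=f_val,
            MS=ms,
            df_num=df_num,
            df_den=int(table.loc["Residual", "df"]),
            p_parametric=p_val,
            degenerate=degenerate,
        )
    return results


def bootstrap_f_pvalues(
    data: pd.DataFrame,
    f_original: dict[str, float] | dict[str, AnovaResult],
    spec: BootstrapSpec,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Pooled-bootstrap significance of the factorial F statistics.

    All n observations are resampled with replacement ignoring group and
    region, redealt into the original cells, and the three F statistics are
    recomputed per resample. For each effect the smaller of the two inclusive
    tail proportions #(F* >= F_orig)/B and #(F* <= F_orig)/B is returned.
    """
    f0 = {
        k: (v.F if isinstance(v, AnovaResult) else float(v)) for k, v in f_original.items()
    }
    design = TypeIIIDesign(data["group"].to_numpy(), data["region"].to_numpy())
    y = data["li"].to_numpy(dtype=float)
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    B = spec.n_resamples
    ge = {k: 0 for k in f0}
    le = {k: 0 for k in f0}
    chunk = max(1, min(B, int(4e6 / design.n)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, design.n, size=(b, design.n))
        stats = design.f_stats(y[idx].T)
        for effect, f_obs in f0.items():
            ge[effect] += int(np.count_nonzero(stats[effect] >= f_obs))
            le[effect] += int(np.count_nonzero(stats[effect] <= f_obs))
        done += b
    return {k: min(ge[k], le[k]) / B for k in f0}


def _resampled_means(
    values: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    # draws are i.i.d. from the empirical distribution; sorting first makes
    # the result exactly invariant to the caller's observation order
    values = np.sort(values)
    n = len(values)
    idx = rng.integers(0, n, size=(B, n))
    return values[idx].mean(axis=1)


def bootstrap_one_sample(
    values: np.ndarray,
    spec: BootstrapSpec,
    rng: np.random.Generator | None = None,
    two_sided: bool = False,
) -> float:
    """Bootstrap test of a mean against zero, smaller-tail rule.

    Values are resampled with replacement ``n_resamples`` times; the smaller
    of the strict tail proportions #(mean* > 0)/B and #(mean* < 0)/B is the
    significance level. Note the smaller tail is reported as-is, i.e. as a
    one-sided level: under the null it rejects at roughly twice the threshold.
    ``two_sided=True`` doubles it (capped at 1) for a conventionally
    calibrated two-sided p. An all-zero sample is degenerate and returns 0.5.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if np.all(values == 0):
        return 0.5
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    means = _resampled_means(values, spec.n_resamples, rng)
    p = min(np.mean(means > 0), np.mean(means < 0))
    return min(1.0, 2.0 * p) if two_sided else p


def bootstrap_two_sample(
    group_a: np.ndarray,
    group_b: np.ndarray,
    spec: BootstrapSpec,
    rng: np.random.Generator | None = None,
    two_sided: bool = False,
) -> float:
    """Bootstrap test of a difference in group means, smaller-tail rule.

    Each group is resampled with replacement independently; per iteration the
    difference of group means is formed and the smaller strict tail proportion
    around zero is returned (one-sided; see :func:`bootstrap_one_sample` for
    the ``two_sided`` calibration note).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    diffs = _resampled_means(a, spec.n_resamples, rng) - _resampled_means(
        b, spec.n_resamples, rng
    )
    p = min(np.mean(diffs > 0), np.mean(diffs < 0))
    return min(1.0, 2.0 * p) if two_sided else p


def bh_fdr(p_values, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment over one test family.

    Returns a DataFrame with columns (p_raw, p_fdr, significant); significance
    means adjusted p <= alpha. Input order and index are preserved.
    """
    p = pd.Series(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or p.isna().any():
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.to_numpy(), alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"p_raw": p.to_numpy(), "p_fdr": p_adj, "significant": reject}, index=p.index
    )


@dataclass
class MassUnivariateResult:
    """Per-source F map with max-statistic permutation FWE correction."""

    contrast: str
    F: np.ndarray
    p_fwe: np.ndarray
    significant: np.ndarray
    df_num: int
    df_den: int
    n_perm: int
    alpha: float = 0.05
    max_f_null: np.ndarray = field(repr=False, default=None)


def _f_map(Y: np.ndarray, groups: np.ndarray, ages: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Per-column F for the group factor after regressing out age."""
    n = len(groups)
    levels = sorted(pd.unique(groups))
    dummies = np.column_stack([(groups == lev).astype(float) for lev in levels[:-1]])
    age_c = (ages - ages.mean())[:, None]
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, dummies, age_c])
    X_red = np.hstack([ones, age_c])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design (age confounded with group?)")
    df_num = dummies.shape[1]
    df_den = n - X_full.shape[1]
    if df_den < 1:
        raise ValueError("no residual degrees of freedom")

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        r = Y - X @ beta
        return np.sum(r * r, axis=0)

    sse_f, sse_r = sse(X_full), sse(X_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
    return np.where(sse_f < _RESID_TOL, 0.0, F), df_num, df_den


def mass_univariate_ancova(
    images: np.ndarray,
    groups: np.ndarray,
    ages: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    contrasts: tuple[str, ...] | None = None,
) -> dict[str, MassUnivariateResult]:
    """Mass-univariate one-way ANCOVA across sources with permutation FWE.

    ``images`` is (n_subjects, n_sources) power; ``groups`` holds the three
    labels LtMTLE / RtMTLE / CTR; age is removed as a nuisance covariate.
    The omnibus group F and the three pairwise contrasts are each corrected
    family-wise by the max-statistic distribution over ``n_perm`` label
    permutations (p = (1 + #(max F* >= F)) / (n_perm + 1)).
    """
    images = np.asarray(images, dtype=float)
    groups = np.asarray(groups)
    ages = np.asarray(ages, dtype=float)
    if images.shape[0] != len(groups) or len(groups) != len(ages):
        raise ValueError("images, groups, and ages must align on subjects")
    for lev, cnt in zip(*np.unique(groups, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pair_names = {
        "Lt_vs_CTR": (GROUP_LT, GROUP_CTR),
        "Rt_vs_CTR": (GROUP_RT, GROUP_CTR),
        "Lt_vs_Rt": (GROUP_LT, GROUP_RT),
    }
    wanted = contrasts if contrasts is not None else ("omnibus", *pair_names)
    rng = np.random.default_rng(seed)
    results: dict[str, MassUnivariateResult] = {}
    for name in wanted:
        if name == "omnibus":
            mask = np.ones(len(groups), dtype=bool)
        else:
            a, b = pair_names[name]
            mask = np.isin(groups, (a, b))
        Y, g, age = images[mask], groups[mask], ages[mask]
        F, df_num, df_den = _f_map(Y, g, age)
        max_null = np.empty(n_perm)
        for p_i in range(n_perm):
            perm = rng.permutation(len(g))
            F_p, _, _ = _f_map(Y, g[perm], age)
            max_null[p_i] = F_p.max()
        p_fwe = (1 + (max_null[:, None] >= F[None, :]).sum(axis=0)) / (n_perm + 1)
        results[name] = MassUnivariateResult(
            contrast=name,
            F=F,
            p_fwe=p_fwe,
            significant=p_fwe <= alpha,
            df_num=df_num,
            df_den=df_den,
            n_perm=n_perm,
            alpha=alpha,
            max_f_null=max_null,
        )
    return results


def laterality_stats(
    li_corrected: pd.DataFrame,
    spec: BootstrapSpec,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full laterality evaluation on a baseline-corrected patient LI table.

    Per band: the 2 x 4 factorial ANOVA with pooled-bootstrap p values.
    Per band x region: one-sample bootstrap tests of each patient group's LI
    against zero (i.e., against the control baseline) and the two-sample
    bootstrap comparison of the groups, each family of 28 adjusted with
    Benjamini-Hochberg separately.

    Returns ``(anova_table, region_tests)``: the first shaped like a
    frequency x effect summary (F, MS, parametric p, bootstrap p), the second
    keyed by band x region with raw and adjusted p per test family.
    """
    pat = li_corrected[li_corrected["group"].isin((GROUP_LT, GROUP_RT))]
    if pat.empty:
        raise ValueError("no patient-group rows in LI table")
    bands = list(pd.unique(pat["band"]))
    regions = list(pd.unique(pat["region"]))
    ss = np.random.SeedSequence(spec.seed)
    children = iter(ss.spawn(len(bands) + 3 * len(bands) * len(regions)))

    anova_rows = []
    for band in bands:
        sub = pat[pat["band"] == band]
        res = two_way_anova(sub)
        p_boot = bootstrap_f_pvalues(
            sub, res, spec, rng=np.random.default_rng(next(children))
        )
        for effect in EFFECTS:
            r = res[effect]
            anova_rows.append(
                {
                    "band": band,
                    "effect": effect,
                    "F": r.F,
                    "MS": r.MS,
                    "p": r.p_parametric,
                    "p_boot": p_boot[effect],
                }
            )
    anova_table = pd.DataFrame(anova_rows)

    region_rows = []
    for band in bands:
        for region in regions:
            cell = pat[(pat["band"] == band) & (pat["region"] == region)]
            lt = cell.loc[cell["group"] == GROUP_LT, "li"].to_numpy()
            rt = cell.loc[cell["group"] == GROUP_RT, "li"].to_numpy()
            region_rows.append(
                {
                    "band": band,
                    "region": region,
                    "mean_li_lt": lt.mean(),
                    "mean_li_rt": rt.mean(),
                    "p_lt_vs_zero": bootstrap_one_sample(
                        lt, spec, rng=np.random.default_rng(next(children))
                    ),
                    "p_rt_vs_zero": bootstrap_one_sample(
                        rt, spec, rng=np.random.default_rng(next(children))
                    ),
                    "p_lt_vs_rt": bootstrap_two_sample(
                        lt, rt, spec, rng=np.random.default_rng(next(children))
                    ),
                }
            )
    region_tests = pd.DataFrame(region_rows)
    for col in ("p_lt_vs_zero", "p_rt_vs_zero", "p_lt_vs_rt"):
        adj = bh_fdr(region_tests[col], alpha=alpha)
        region_tests[f"{col}_fdr"] = adj["p_fdr"].to_numpy()
        region_tests[f"{col}_sig"] = adj["significant"].to_numpy()
    return anova_table, region_tests
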