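"""Nonparametric statistical layer for the block-design contrasts.

Single-unit quantities are compared with rank-based tests: a two-factor
Scheirer-Ray-Hare test (rank analogue of two-way ANOVA with chi-squared
references), Kruskal-Wallis, sign-flip permutation tests on per-unit paired
differences, and Pearson chi-squared on change-class proportions.  Family-wise
error over many correlated frequency bins is controlled by a *partial*
Bonferroni correction: alpha is divided by the number of principal components
needed to explain >95% of the variance of the tested variable family, rather
than by the raw bin count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io_core import ValidationError

__all__ = [
    "StatReport", "scheirer_ray_hare", "kruskal_wallis", "permutation_test",
    "chi_squared_proportions", "partial_bonferroni_factor", "cohens_d",
    "baseline_contrast", "posthoc_wilcoxon",
]


@dataclass
class StatReport:
    """Uniform container for one statistical test result."""

    test: str
    statistic: float | dict[str, float]
    df: float | dict[str, float] | None
    p_value: float | dict[str, float]
    effect_size: float | None = None
    correction: dict = field(default_factory=lambda: {"method": "none",
                                                      "factor": 1,
                                                      "alpha_corrected": 0.05})
    groups: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic, "df": self.df,
            "p_value": self.p_value, "effect_size": self.effect_size,
            "correction": self.correction, "groups": self.groups,
            "flags": self.flags,
        }


def scheirer_ray_hare(values, factor_a, factor_b) -> StatReport:
    """Scheirer-Ray-Hare test: two-way fixed-effects ANOVA on ranks.

    All observations are rank-transformed jointly (ties get average ranks);
    sums of squares for each main effect and the interaction are computed on
    the ranks and divided by the total mean square ``MS_total = SS_total /
    (n - 1)``, giving H statistics referred to chi-squared distributions with
    the usual factorial degrees of freedom.  The interaction sum of squares is
    ``SS_cells - SS_A - SS_B``.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(values) == len(fa) == len(fb)):
        raise ValidationError("values and factors must have equal length")
    levels_a, ia = np.unique(fa, return_inverse=True)
    levels_b, ib = np.unique(fb, return_inverse=True)
    a, b = len(levels_a), len(levels_b)
    if a < 2 and b < 2:
        raise ValidationError("at least one factor needs 2 or more levels")
    # a constant factor degrades SRH to the one-way rank test (Kruskal-Wallis
    # with tie correction) on the remaining factor
    if a < 2 or b < 2:
        name, idx, k = (("B", ib, b) if a < 2 else ("A", ia, a))
        r = sp_stats.rankdata(values)
        grand = r.mean()
        ss_total = float(np.sum((r - grand) ** 2))
        sums = np.bincount(idx, weights=r, minlength=k)
        counts = np.bincount(idx, minlength=k)
        ss_eff = float(np.sum(sums ** 2 / counts) - len(values) * grand ** 2)
        h = ss_eff / (ss_total / (len(values) - 1)) if ss_total > 0 else 0.0
        return StatReport(
            test="scheirer_ray_hare",
            statistic={name: float(h)}, df={name: k - 1},
            p_value={name: float(sp_stats.chi2.sf(h, k - 1))},
            flags=["one factor constant; reduces to Kruskal-Wallis"],
        )
    cell_count = np.zeros((a, b), dtype=int)
    np.add.at(cell_count, (ia, ib), 1)
    if (cell_count == 0).any():
        raise ValidationError("empty cell in the two-way design")
    n = len(values)
    r = sp_stats.rankdata(values)
    grand = r.mean()
    ss_total = float(np.sum((r - grand) ** 2))
    if ss_total == 0:
        zero = {"A": 0.0, "B": 0.0, "AxB": 0.0}
        return StatReport(
            test="scheirer_ray_hare", statistic=zero,
            df={"A": a - 1, "B": b - 1, "AxB": (a - 1) * (b - 1)},
            p_value={"A": 1.0, "B": 1.0, "AxB": 1.0},
            groups=[str(l) for l in levels_a] + [str(l) for l in levels_b],
            flags=["all values tied"],
        )
    ms_total = ss_total / (n - 1)

    def ss_between(idx, k):
        sums = np.bincount(idx, weights=r, minlength=k)
        counts = np.bincount(idx, minlength=k)
        return float(np.sum(sums ** 2 / counts) - n * grand ** 2)

    ss_a = ss_between(ia, a)
    ss_b = ss_between(ib, b)
    cell_idx = ia * b + ib
    ss_cells = ss_between(cell_idx, a * b)
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)

    h = {"A": ss_a / ms_total, "B": ss_b / ms_total, "AxB": ss_ab / ms_total}
    df = {"A": a - 1, "B": b - 1, "AxB": (a - 1) * (b - 1)}
    p = {k: float(sp_stats.chi2.sf(h[k], df[k])) for k in h}
    return StatReport(
        test="scheirer_ray_hare", statistic={k: float(v) for k, v in h.items()},
        df=df, p_value=p,
        groups=[str(l) for l in levels_a] + [str(l) for l in levels_b],
    )


def kruskal_wallis(values, groups) -> StatReport:
    """Kruskal-Wallis H test (tie-corrected), via scipy."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = sp_stats.kruskal(*samples)
    return StatReport(test="kruskal_wallis", statistic=float(h),
                      df=len(levels) - 1, p_value=float(p),
                      groups=[str(g) for g in levels])


def permutation_test(deltas, n_permutations: int = 10000, tail: str = "two",
                     rng: np.random.Generator | None = None) -> StatReport:
    """Sign-flip permutation test on paired differences.

    The statistic is the mean difference. Under the paired null each unit's
    difference is symmetric around zero, so signs are flipped independently;
    p = (1 + #{permuted as or more extreme}) / (B + 1).  ``tail`` is ``"two"``,
    ``"less"`` or ``"greater"``. For n <= 12 all 2^n sign patterns are
    enumerated exactly instead of sampled.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if n < 5:
        raise ValidationError("permutation test needs n >= 5 paired differences")
    if tail not in ("two", "less", "greater"):
        raise ValidationError(f"unknown tail {tail!r}")
    t_obs = float(np.mean(deltas))
    flags = []
    if np.all(deltas == 0):
        return StatReport(test="permutation_sign_flip", statistic=0.0, df=None,
                          p_value=1.0, flags=["all differences zero"])
    if n <= 12:
        # exhaustive enumeration of all sign patterns
        patterns = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2 ** n)],
            dtype=float,
        )
        t_perm = patterns @ deltas / n
        denom = len(t_perm)
        if tail == "two":
            p = np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12) / denom
        elif tail == "less":
            p = np.sum(t_perm <= t_obs + 1e-12) / denom
        else:
            p = np.sum(t_perm >= t_obs - 1e-12) / denom
        flags.append("exact enumeration")
    else:
        rng = np.random.default_rng(rng)
        signs = rng.choice((-1.0, 1.0), size=(n_permutations, n))
        t_perm = signs @ deltas / n
        if tail == "two":
            extreme = np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12)
        elif tail == "less":
            extreme = np.sum(t_perm <= t_obs + 1e-12)
        else:
            extreme = np.sum(t_perm >= t_obs - 1e-12)
        p = (1 + extreme) / (n_permutations + 1)
    return StatReport(test="permutation_sign_flip", statistic=t_obs, df=None,
                      p_value=float(min(p, 1.0)), flags=flags)


def chi_squared_proportions(table, condition_labels: list[str] | None = None,
                            posthoc: bool = False, alpha: float = 0.05) -> StatReport:
    """Pearson chi-squared on a k x m contingency table of change-class counts.

    With ``posthoc=True``, every pair of rows (conditions) is re-tested on its
    2 x m sub-table with Bonferroni correction over the number of pairs.
    Expected cells below 1 trigger a warning flag suggesting an exact test.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValidationError("contingency table must be 2-D")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has an all-zero row or column")
    chi2, p, df, expected = sp_stats.chi2_contingency(table, correction=False)
    flags = []
    if (expected < 1).any():
        flags.append("expected cell < 1; consider an exact test")
    labels = condition_labels or [f"row{i}" for i in range(table.shape[0])]
    report = StatReport(test="chi_squared", statistic=float(chi2), df=float(df),
                        p_value=float(p), groups=labels, flags=flags)
    if posthoc and table.shape[0] > 2:
        pairs = [(i, j) for i in range(table.shape[0]) for j in range(i + 1, table.shape[0])]
        sub_reports = {}
        for i, j in pairs:
            sub = table[[i, j]]
            keep = sub.sum(axis=0) > 0
            c2, pp, dd, _ = sp_stats.chi2_contingency(sub[:, keep], correction=False)
            sub_reports[f"{labels[i]} vs {labels[j]}"] = {
                "chi2": float(c2), "df": float(dd), "p": float(pp),
                "significant": bool(pp < alpha / len(pairs)),
            }
        report.correction = {"method": "bonferroni", "factor": len(pairs),
                             "alpha_corrected": alpha / len(pairs)}
        report.posthoc = sub_reports  # type: ignore[attr-defined]
    return report


def partial_bonferroni_factor(X, standardize: bool = False,
                              variance_threshold: float = 0.95) -> int:
    """Alpha correction factor from PCA of a correlated variable family.

    PCA (covariance form on column-centred data; ``standardize=True`` switches
    to correlation form) is applied to the observations x variables matrix and
    the factor is the smallest number of leading components whose cumulative
    explained variance exceeds the threshold.  Frequency-resolved LFP measures
    are heavily correlated across bins, so this is far less conservative than
    dividing by the bin count.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 observations")
    if not np.all(np.isfinite(X)):
        raise ValidationError("variables must be finite")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    var = sv ** 2
    total = var.sum()
    if total <= 0:
        raise ValidationError("zero total variance")
    cum = np.cumsum(var) / total
    factor = int(np.searchsorted(cum, variance_threshold, side="right") + 1)
    return min(factor, min(X.shape))


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled (n-1 weighted) standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("Cohen's d needs >= 2 observations per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValidationError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def baseline_contrast(baseline_drug, post_drug, baseline_saline, post_saline) -> dict:
    """Post/baseline change ratios and the drug-vs-vehicle percent difference.

    ``change = mean(post) / mean(baseline)`` per condition; the drug change is
    divided by the saline change and expressed as
    ``percent_diff = 100 * (change_drug / change_saline - 1)``.
    Computed separately for rest and task by the caller.
    """
    out = {}
    for name, base, post in (("drug", baseline_drug, post_drug),
                             ("saline", baseline_saline, post_saline)):
        base_m = float(np.mean(np.asarray(base, dtype=float)))
        if base_m == 0:
            raise ValidationError(f"zero baseline average for {name}")
        out[f"change_{name}"] = float(np.mean(np.asarray(post, dtype=float))) / base_m
    if out["change_saline"] == 0:
        raise ValidationError("zero saline change ratio")
    out["percent_diff"] = 100.0 * (out["change_drug"] / out["change_saline"] - 1.0)
    return out


def posthoc_wilcoxon(values, groups, paired: bool = False, alpha: float = 0.05,
                     correction_factor: int | None = None) -> list[StatReport]:
    """Pairwise Wilcoxon tests over all group pairs with Bonferroni-type alpha.

    ``paired=True`` uses the signed-rank test (groups must be equal-sized and
    matched in order); otherwise the rank-sum (Mann-Whitney) test.  The
    corrected alpha is ``alpha / factor`` where factor defaults to the number
    of pairs (classical Bonferroni) or can be supplied from
    :func:`partial_bonferroni_factor`.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(np.unique(groups))
    pairs = [(g1, g2) for i, g1 in enumerate(levels) for g2 in levels[i + 1:]]
    factor = correction_factor if correction_factor is not None else max(len(pairs), 1)
    method = "partial_bonferroni" if correction_factor is not None else "bonferroni"
    reports = []
    for g1, g2 in pairs:
        x = values[groups == g1]
        y = values[groups == g2]
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(f"group {g1!r} or {g2!r} has fewer than 2 values")
        if paired:
            if len(x) != len(y):
                raise ValidationError("paired test requires equal group sizes")
            diffs = x - y
            if np.all(diffs == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = sp_stats.wilcoxon(x, y)
            name = "wilcoxon_signed_rank"
        else:
            stat, p = sp_stats.ranksums(x, y)
            name = "wilcoxon_rank_sum"
        reports.append(StatReport(
            test=name, statistic=float(stat), df=None, p_value=float(p),
            correction={"method": method, "factor": factor,
                        "alpha_corrected": alpha / factor},
            groups=[str(g1), str(g2)],
        ))
    return reports
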