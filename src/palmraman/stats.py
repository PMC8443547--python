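"""Statistical feature screening.

Per feature the procedure runs a median-centered Levene homogeneity test;
classic one-way ANOVA plus its Welch and Brown-Forsythe robust variants;
and pairwise post hoc comparisons — Gabriel's test (suited to the unequal
group sizes 14/20/12; p-values from the studentized maximum modulus
distribution) when variances are homogeneous, Games-Howell (studentized
range on Welch-type statistics) when they are not.  Features are then
tiered:

* ``main`` — ANOVA significant and all three pairwise comparisons
  significant;
* ``reserved`` — ANOVA significant and 1-2 pairwise comparisons
  significant;
* ``excluded`` — everything else.

Both ANOVA/post hoc branches are always computed and reported; the branch
selected by the homogeneity test is the authoritative one for tiering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import DegenerateDataError, ValidationError
from .io import FEATURE_NAMES, RipenessLabel, validate_feature_table

__all__ = [
    "StatTestResult",
    "PairwiseResult",
    "SignificanceLedger",
    "levene_homogeneity",
    "oneway_anova",
    "welch_anova",
    "brown_forsythe_anova",
    "gabriel_posthoc",
    "games_howell_posthoc",
    "studentized_max_modulus_sf",
    "classify_tier",
    "build_significance_ledger",
    "reference_ledger",
]


@dataclass(frozen=True)
class StatTestResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float


@dataclass(frozen=True)
class PairwiseResult:
    """One post hoc comparison; ``pair`` is ordered but the result is symmetric."""

    pair: tuple[str, str]
    mean_difference: float
    statistic: float
    df: float
    p_value: float
    significant: bool


def _check_groups(groups, min_n: int = 2, need_variance: bool = False):
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if a.size < min_n:
            raise ValidationError(f"group {i} has fewer than {min_n} observations")
        if not np.all(np.isfinite(a)):
            raise ValidationError(f"group {i} contains non-finite values")
        if need_variance and np.var(a, ddof=1) == 0:
            raise ValidationError(f"group {i} has zero variance")
    return arrays


def levene_homogeneity(groups) -> StatTestResult:
    """Levene's test with median centering (the Brown-Forsythe robust form)."""
    arrays = _check_groups(groups)
    k, n_total = len(arrays), sum(a.size for a in arrays)
    stat, p = sps.levene(*arrays, center="median")
    return StatTestResult("levene-median", float(stat), (k - 1, n_total - k), float(p))


def _ss_between_within(arrays):
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    return ssb, ssw


def oneway_anova(groups) -> StatTestResult:
    """Classic one-way ANOVA: F = MSB/MSW with df (k-1, N-k)."""
    arrays = _check_groups(groups)
    k, n_total = len(arrays), sum(a.size for a in arrays)
    ssb, ssw = _ss_between_within(arrays)
    if ssw == 0 and ssb == 0:
        raise DegenerateDataError("all observations identical; F undefined")
    stat, p = sps.f_oneway(*arrays)
    return StatTestResult("oneway-anova", float(stat), (k - 1, n_total - k), float(p))


def welch_anova(groups) -> StatTestResult:
    """Welch's heteroscedastic one-way ANOVA (Welch-Satterthwaite df)."""
    arrays = _check_groups(groups, need_variance=True)
    k = len(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    w = n / v
    w_sum = w.sum()
    grand = (w * m).sum() / w_sum
    a_term = ((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = ((1 - w / w_sum) ** 2 / (n - 1)).sum()
    b_term = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f_star = a_term / b_term
    df2 = (k**2 - 1) / (3 * lam)
    p = float(sps.f.sf(f_star, k - 1, df2))
    return StatTestResult("welch-anova", float(f_star), (k - 1, df2), p)


def brown_forsythe_anova(groups) -> StatTestResult:
    """Brown-Forsythe F*: SSB over sum (1 - n_i/N) s_i^2, Satterthwaite df."""
    arrays = _check_groups(groups, need_variance=True)
    k = len(arrays)
    n = np.array([a.size for a in arrays], dtype=float)
    n_total = n.sum()
    v = np.array([a.var(ddof=1) for a in arrays])
    ssb, _ = _ss_between_within(arrays)
    denom_terms = (1 - n / n_total) * v
    denom = denom_terms.sum()
    if denom == 0:
        raise DegenerateDataError("zero denominator in Brown-Forsythe statistic")
    f_star = ssb / denom
    c = denom_terms / denom
    df2 = 1.0 / ((c**2 / (n - 1)).sum())
    p = float(sps.f.sf(f_star, k - 1, df2))
    return StatTestResult("brown-forsythe-anova", float(f_star), (k - 1, df2), p)


# ---------------------------------------------------------------------------
# studentized maximum modulus distribution (for Gabriel's test)


def studentized_max_modulus_sf(q: float, m: int, df: float) -> float:
    """P(max_i |T_i| > q) for m independent studentized normal deviates.

    T_i = Z_i / U with Z_i iid standard normal and U = S/sigma the shared
    root-mean chi factor on ``df`` degrees of freedom.  Evaluated by
    numerical quadrature over the density of U; absolute accuracy ~1e-6.
    """
    if q <= 0:
        return 1.0
    sqrt_df = np.sqrt(df)

    def integrand(u: float) -> float:
        return (2.0 * sps.norm.cdf(q * u) - 1.0) ** m * sps.chi.pdf(u * sqrt_df, df) * sqrt_df

    cdf, _ = quad(integrand, 0.0, np.inf, epsabs=1e-9, epsrel=1e-9, limit=200)
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def studentized_max_modulus_crit(alpha: float, m: int, df: float) -> float:
    """Upper-``alpha`` critical value of the studentized maximum modulus."""
    return float(brentq(lambda q: studentized_max_modulus_sf(q, m, df) - alpha, 1e-6, 50.0))


def _pair_labels(k: int, labels) -> list[str]:
    if labels is None:
        return [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValidationError("labels length must match number of groups")
    return [str(lab) for lab in labels]


def gabriel_posthoc(groups, alpha: float = 0.05, labels=None) -> list[PairwiseResult]:
    """Gabriel's pairwise comparison for unequal group sizes.

    Each mean gets the interval half-width m * sqrt(MSW / (2 n_i)); two
    means differ when their intervals do not overlap, i.e. the statistic
    |mean_i - mean_j| / (sqrt(MSW) * (1/sqrt(2 n_i) + 1/sqrt(2 n_j)))
    exceeds the studentized-maximum-modulus point m with k means and N-k
    df.  For equal n this is the ordinary two-sample-style t statistic, so
    the familywise error stays near the nominal level.
    """
    arrays = _check_groups(groups)
    k, n_total = len(arrays), sum(a.size for a in arrays)
    names = _pair_labels(k, labels)
    _, ssw = _ss_between_within(arrays)
    df = n_total - k
    msw = ssw / df
    if msw == 0:
        raise DegenerateDataError("zero within-group mean square; Gabriel test undefined")
    results = []
    for i, j in combinations(range(k), 2):
        diff = arrays[i].mean() - arrays[j].mean()
        se = np.sqrt(msw) * (
            1.0 / np.sqrt(2 * arrays[i].size) + 1.0 / np.sqrt(2 * arrays[j].size)
        )
        stat = abs(diff) / se
        p = studentized_max_modulus_sf(stat, k, df)
        results.append(
            PairwiseResult((names[i], names[j]), float(diff), float(stat), float(df), p, p < alpha)
        )
    return results


def games_howell_posthoc(groups, alpha: float = 0.05, labels=None) -> list[PairwiseResult]:
    """Games-Howell pairwise comparison for unequal variances.

    Welch-type t per pair with Welch-Satterthwaite df; p from the
    studentized range with k groups at q = |t| * sqrt(2).
    """
    arrays = _check_groups(groups, need_variance=True)
    k = len(arrays)
    names = _pair_labels(k, labels)
    results = []
    for i, j in combinations(range(k), 2):
        ni, nj = arrays[i].size, arrays[j].size
        vi, vj = arrays[i].var(ddof=1), arrays[j].var(ddof=1)
        diff = arrays[i].mean() - arrays[j].mean()
        se2 = vi / ni + vj / nj
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        results.append(
            PairwiseResult((names[i], names[j]), float(diff), float(t), float(df), p, p < alpha)
        )
    return results


# ---------------------------------------------------------------------------
# significance ledger

_TIERS = ("main", "reserved", "excluded")


def classify_tier(anova_significant: bool, pairwise_significant) -> str:
    """Tier a feature from its authoritative ANOVA and 3 pairwise outcomes."""
    flags = list(pairwise_significant)
    if not anova_significant:
        return "excluded"
    if all(flags):
        return "main"
    if any(flags):
        return "reserved"
    return "excluded"


@dataclass(frozen=True)
class SignificanceLedger:
    """Per-feature test outcomes and main/reserved/excluded tiers.

    ``table`` is indexed by feature name and includes every computed test
    (both homogeneity branches) plus the authoritative branch name, the
    three gated pairwise p-values, and the tier.
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def __post_init__(self) -> None:
        bad = set(self.table["tier"]) - set(_TIERS)
        if bad:
            raise ValidationError(f"unknown tiers: {bad}")

    def features(self, tier: str) -> list[str]:
        if tier not in _TIERS:
            raise ValidationError(f"tier must be one of {_TIERS}")
        return [f for f in self.table.index if self.table.loc[f, "tier"] == tier]

    @property
    def main(self) -> list[str]:
        return self.features("main")

    @property
    def reserved(self) -> list[str]:
        return self.features("reserved")

    @property
    def excluded(self) -> list[str]:
        return self.features("excluded")

    @property
    def retained(self) -> list[str]:
        return [f for f in self.table.index if self.table.loc[f, "tier"] != "excluded"]

    @classmethod
    def from_tiers(cls, tiers: dict[str, str], alpha: float = 0.05) -> "SignificanceLedger":
        """Build a ledger from an externally supplied tier assignment."""
        missing = [f for f in FEATURE_NAMES if f not in tiers]
        if missing:
            raise ValidationError(f"tiers missing for features: {missing}")
        table = pd.DataFrame({"tier": [tiers[f] for f in FEATURE_NAMES]}, index=list(FEATURE_NAMES))
        return cls(table=table, alpha=alpha)


_PAIR_KEYS = (
    ("UNDER_RIPE", "RIPE"),
    ("UNDER_RIPE", "OVER_RIPE"),
    ("RIPE", "OVER_RIPE"),
)


def build_significance_ledger(table: pd.DataFrame, alpha: float = 0.05) -> SignificanceLedger:
    """Run the full screening on a labeled feature table.

    For each of the 15 features: Levene homogeneity; if variances are
    unequal at ``alpha`` the authoritative branch is Welch ANOVA +
    Games-Howell, otherwise classic ANOVA + Gabriel.  All branches are
    computed and reported.
    """
    table = validate_feature_table(table)
    class_names = [lab.name for lab in RipenessLabel]
    rows = []
    for feature in FEATURE_NAMES:
        groups = [
            table.loc[table["label"] == lab, feature].to_numpy(dtype=float)
            for lab in RipenessLabel
        ]
        if any(g.size < 2 for g in groups):
            raise ValidationError("every ripeness class needs at least 2 samples")
        lev = levene_homogeneity(groups)
        equal_var = lev.p_value >= alpha
        anova = oneway_anova(groups)
        welch = welch_anova(groups)
        bf = brown_forsythe_anova(groups)
        gabriel = gabriel_posthoc(groups, alpha=alpha, labels=class_names)
        gh = games_howell_posthoc(groups, alpha=alpha, labels=class_names)
        auth_anova = anova if equal_var else welch
        auth_pairs = gabriel if equal_var else gh
        pair_p = {pr.pair: pr.p_value for pr in auth_pairs}
        flags = [pair_p[key] < alpha for key in _PAIR_KEYS]
        tier = classify_tier(auth_anova.p_value < alpha, flags)
        rows.append(
            {
                "feature": feature,
                "levene_W": lev.statistic,
                "levene_p": lev.p_value,
                "equal_variances": equal_var,
                "anova_F": anova.statistic,
                "anova_p": anova.p_value,
                "welch_F": welch.statistic,
                "welch_p": welch.p_value,
                "brown_forsythe_F": bf.statistic,
                "brown_forsythe_p": bf.p_value,
                "authoritative": auth_anova.test_name
                + "/"
                + ("gabriel" if equal_var else "games-howell"),
                "p_under_ripe": pair_p[_PAIR_KEYS[0]],
                "p_under_over": pair_p[_PAIR_KEYS[1]],
                "p_ripe_over": pair_p[_PAIR_KEYS[2]],
                "tier": tier,
            }
        )
    frame = pd.DataFrame.from_records(rows).set_index("feature")
    return SignificanceLedger(table=frame, alpha=alpha)


def reference_ledger(alpha: float = 0.05) -> SignificanceLedger:
    """The published 15 -> 9 screening outcome for the original field data.

    2 main features (beta-carotene and lutein sub-band intensities) plus 7
    reserved (lycopene/neoxanthin intensities, lutein/neoxanthin positions,
    lycopene/beta-carotene/neoxanthin FWHM); ratios and the remaining
    features excluded.  Used to mirror the reported feature-policy ladder
    when re-running the classifier search on synthetic data, whose own
    screening is typically stronger than the field data's.
    """
    tiers = {name: "excluded" for name in FEATURE_NAMES}
    tiers["int_nu1b"] = "main"
    tiers["int_nu1c"] = "main"
    for name in ("int_nu1a", "int_nu1d", "pos_nu1c", "pos_nu1d", "fwhm_nu1a", "fwhm_nu1b", "fwhm_nu1d"):
        tiers[name] = "reserved"
    return SignificanceLedger.from_tiers(tiers, alpha=alpha)
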