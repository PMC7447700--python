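"""Cultivar trait comparison: percent differences, t-tests, two-way
cultivar × year ANOVA with LSD letter groupings, and the agronomic indices
(harvest index, organ dry-matter partitioning, productive tiller
percentage).

The comparison convention throughout is test cultivar vs reference
cultivar, with the reference in the denominator of percent differences:
a +20.04% difference means the test cultivar's mean exceeds the
reference's by 20.04% of the reference mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ricephys.errors import InputDataError

__all__ = [
    "TraitTable",
    "ComparisonResult",
    "percent_difference",
    "round_half_up",
    "t_test_two_sample",
    "anova_two_way",
    "lsd_groups",
    "harvest_index",
    "organ_partition",
    "productive_tiller_pct",
    "compare_cultivars",
]

TRAIT_COLUMNS = ("cultivar", "year", "replicate", "trait", "value", "unit")


@dataclass
class TraitTable:
    """Replicated cultivar × year × trait observations.

    Thin wrapper over a DataFrame with columns
    ``cultivar, year, replicate, trait, value, unit``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputDataError(f"TraitTable missing columns: {missing}")
        self.df = self.df.copy()
        self.df["value"] = pd.to_numeric(self.df["value"])

    def subset(self, trait: str, year=None) -> pd.DataFrame:
        out = self.df[self.df["trait"] == trait]
        if year is not None:
            out = out[out["year"] == year]
        return out

    def is_balanced(self, trait: str) -> bool:
        counts = (
            self.subset(trait).groupby(["cultivar", "year"], observed=True)["value"].count()
        )
        return len(counts) > 0 and counts.nunique() == 1


@dataclass
class ComparisonResult:
    """Two-cultivar comparison for one trait in one year."""

    trait: str
    mean_test: float
    mean_reference: float
    percent_diff: float
    t_statistic: float | None
    df: float | None
    p_value: float | None
    significant_at: str  # "ns", "0.05" or "0.01"

    @property
    def stars(self) -> str:
        return {"ns": "", "0.05": "*", "0.01": "**"}[self.significant_at]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero, as printed in trial
    tables (numpy/python banker's rounding would turn 0.125 into 0.12)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def percent_difference(mean_test: float, mean_reference: float) -> float:
    """100·(test − reference)/reference. Raises on a zero reference.

    Returned at full precision; use :func:`round_half_up` for the 2-decimal
    display convention.
    """
    if mean_reference == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_test - mean_reference) / mean_reference


def _significance(p: float) -> str:
    if p < 0.01:
        return "0.01"
    if p < 0.05:
        return "0.05"
    return "ns"


def t_test_two_sample(sample_a, sample_b, variant: str = "pooled"):
    """Two-sided two-sample t-test.

    ``variant="pooled"`` assumes equal variances (df = n_a + n_b − 2);
    ``"welch"`` uses the Welch–Satterthwaite df. Returns
    ``(t, df, p_value)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputDataError("each sample needs at least 2 values")
    if variant == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    return float(res.statistic), float(df), float(res.pvalue)


def anova_two_way(table: TraitTable, trait: str, factor_a: str = "cultivar",
                  factor_b: str = "year"):
    """Classical fixed-effects two-way ANOVA with interaction on a balanced
    complete design.

    Returns a DataFrame indexed by effect (``A``, ``B``, ``A×B``,
    ``error``, ``total``) with columns ``ss, df, ms, F, p``. The sums of
    squares satisfy SS_total = SS_A + SS_B + SS_AB + SS_E exactly up to
    floating point. With a single replicate per cell the error stratum is
    empty and F/p are reported as NaN (degenerate).
    """
    sub = table.subset(trait)
    if sub.empty:
        raise InputDataError(f"no rows for trait {trait!r}")
    return _anova_two_way_arrays(
        sub[factor_a].to_numpy(), sub[factor_b].to_numpy(), sub["value"].to_numpy(float)
    )


def _anova_two_way_arrays(a_labels, b_labels, values) -> pd.DataFrame:
    a_levels, a_idx = np.unique(a_labels, return_inverse=True)
    b_levels, b_idx = np.unique(b_labels, return_inverse=True)
    na, nb = len(a_levels), len(b_levels)
    counts = np.zeros((na, nb))
    np.add.at(counts, (a_idx, b_idx), 1)
    if np.any(counts == 0):
        raise InputDataError("incomplete design: empty cultivar×year cell")
    if counts.min() != counts.max():
        raise InputDataError("unbalanced design: unequal replicates per cell")
    r = int(counts[0, 0])
    sums = np.zeros((na, nb))
    np.add.at(sums, (a_idx, b_idx), values)
    cell_means = sums / r
    grand = values.mean()
    mean_a = cell_means.mean(axis=1)
    mean_b = cell_means.mean(axis=0)
    ss_a = nb * r * np.sum((mean_a - grand) ** 2)
    ss_b = na * r * np.sum((mean_b - grand) ** 2)
    ss_ab = r * np.sum(
        (cell_means - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_e = np.sum((values - cell_means[a_idx, b_idx]) ** 2)
    ss_t = np.sum((values - grand) ** 2)
    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_e = na * nb * (r - 1)
    rows = {}
    ms_e = ss_e / df_e if df_e > 0 else np.nan
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("A×B", ss_ab, df_ab)):
        if df > 0 and df_e > 0 and ms_e > 0:
            f = (ss / df) / ms_e
            p = float(stats.f.sf(f, df, df_e))
        else:
            f, p = np.nan, np.nan
        rows[name] = (ss, df, ss / df if df > 0 else np.nan, f, p)
    rows["error"] = (ss_e, df_e, ms_e, np.nan, np.nan)
    rows["total"] = (ss_t, len(values) - 1, np.nan, np.nan, np.nan)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["ss", "df", "ms", "F", "p"]
    )


def lsd_groups(cell_means, ms_error: float, df_error: int, n_per_cell: int,
               alpha: float = 0.05) -> list:
    """Fisher's LSD letter groupings for a set of cell means.

    LSD = t(1 − α/2, df_error) · sqrt(2·MS_error / n); two means whose
    absolute difference is below the LSD share a letter. Letters are
    assigned greedily over means sorted in descending order; the returned
    list of letter strings matches the input order.
    """
    if df_error <= 0:
        raise InputDataError("df_error must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    means = np.asarray(cell_means, dtype=float)
    lsd = stats.t.ppf(1.0 - alpha / 2.0, df_error) * math.sqrt(
        2.0 * ms_error / n_per_cell
    )
    order = np.argsort(-means)
    sorted_means = means[order]
    m = len(means)
    # maximal runs of means within one LSD of the run's largest member
    runs = []
    i = 0
    while i < m:
        j = i
        while j + 1 < m and sorted_means[i] - sorted_means[j + 1] < lsd:
            j += 1
        if not runs or j > runs[-1][1]:
            runs.append((i, j))
        if j + 1 >= m:
            break
        i += 1
    letters = ["" for _ in range(m)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, (lo, hi) in zip(alphabet, runs):
        for idx in range(lo, hi + 1):
            letters[idx] += letter
    out = ["" for _ in range(m)]
    for pos, orig in enumerate(order):
        out[orig] = letters[pos]
    return out


def harvest_index(grain_weight: float, aboveground_biomass: float,
                  *, flag: list | None = None) -> float:
    """Grain weight / aboveground biomass (both g). Values above 1 are
    physically suspect and appended to ``flag`` when a list is passed."""
    if aboveground_biomass <= 0:
        raise ValueError("aboveground biomass must be positive")
    if grain_weight < 0:
        raise ValueError("grain weight must be nonnegative")
    hi = grain_weight / aboveground_biomass
    if hi > 1 and flag is not None:
        flag.append("harvest_index>1")
    return hi


def organ_partition(leaf: float, sheath: float, stem: float, panicle: float):
    """Dry-matter partitioning: each organ as % of their sum.

    The last component is closed (100 minus the others) so the four ratios
    sum to exactly 100.
    """
    organs = (leaf, sheath, stem, panicle)
    if any(o < 0 for o in organs):
        raise ValueError("organ weights must be nonnegative")
    total = sum(organs)
    if total <= 0:
        raise ValueError("total organ weight must be positive")
    ratios = [100.0 * o / total for o in organs[:3]]
    ratios.append(100.0 - sum(ratios))
    return tuple(ratios)


def productive_tiller_pct(panicles_at_yrs: float, max_tillers_at_ts: float,
                          *, flag: list | None = None) -> float:
    """Productive panicles per hill at yellow-ripe stage as % of the
    maximum tiller number per hill at tillering stage."""
    if max_tillers_at_ts <= 0:
        raise ValueError("max tiller number must be positive")
    if panicles_at_yrs < 0:
        raise ValueError("panicle number must be nonnegative")
    pct = 100.0 * panicles_at_yrs / max_tillers_at_ts
    if pct > 100 and flag is not None:
        flag.append("productive_tillers>100%")
    return pct


def compare_cultivars(
    table: TraitTable,
    trait: str,
    year,
    cultivar_test: str,
    cultivar_reference: str,
    variant: str = "pooled",
) -> ComparisonResult:
    """Compare two cultivars on one trait in one year.

    Percent difference uses the reference cultivar's mean as denominator;
    the t-test is two-sided (pooled by default). With single-replicate
    cells the percent difference is still reported but the test is marked
    unavailable (``t_statistic``/``p_value`` None, significance ``"ns"``).
    """
    sub = table.subset(trait, year)
    a = sub[sub["cultivar"] == cultivar_test]["value"].to_numpy(float)
    b = sub[sub["cultivar"] == cultivar_reference]["value"].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise InputDataError(
            f"missing cell for trait {trait!r}, year {year!r}: "
            f"{cultivar_test if len(a) == 0 else cultivar_reference}"
        )
    pdiff = percent_difference(a.mean(), b.mean())
    if len(a) >= 2 and len(b) >= 2:
        t, df, p = t_test_two_sample(a, b, variant)
        sig = _significance(p)
    else:
        t = df = p = None
        sig = "ns"
    return ComparisonResult(
        trait=trait,
        mean_test=float(a.mean()),
        mean_reference=float(b.mean()),
        percent_diff=pdiff,
        t_statistic=t,
        df=df,
        p_value=p,
        significant_at=sig,
    )
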