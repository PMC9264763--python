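"""Group-comparison statistics for the paired three-tissue cohort.

The battery mirrors a standard non-parametric repeated-measures workflow:
Shapiro--Wilk normality and Levene variance diagnostics, a Conover-style
ranked two-way repeated-measures ANOVA (factors: tissue type and diffusion
metric, patient as the repeated unit), and post hoc paired Wilcoxon
signed-rank tests with Bonferroni correction (family size 3: the three
tissue pairs within each metric).

The signed-rank test uses the exact null distribution for n <= 25 pairs
(zero differences dropped, mid-ranks for ties, two-sided p by tail
doubling) and a normal approximation with continuity and tie correction
above.  The exact distribution is computed by dynamic programming over the
doubled ranks, so mid-ranks (multiples of 1/2) stay integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "StatsError",
    "shapiro_wilk",
    "levene",
    "wilcoxon_signed_rank",
    "pairwise_wilcoxon_bonferroni",
    "ranked_rm_anova",
]

ALPHA = 0.05
TISSUE_PAIRS = (("malignant", "benign"), ("malignant", "healthy"), ("benign", "healthy"))


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


@dataclass
class TestReport:
    """One hypothesis-test result with optional multiplicity adjustment."""

    test: str
    comparison: str
    statistic: float
    p_raw: float
    df: tuple[float, ...] | None = None
    p_adjusted: float | None = None
    family_size: int | None = None
    alpha: float = ALPHA

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "comparison": self.comparison,
            "statistic": self.statistic,
            "df": list(self.df) if self.df is not None else None,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "family_size": self.family_size,
            "alpha": self.alpha,
        }


def shapiro_wilk(values: Sequence[float], comparison: str = "") -> TestReport:
    """Shapiro--Wilk normality test (3 <= n <= 5000, non-constant sample)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise StatsError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise StatsError(f"Shapiro-Wilk is unreliable for n > 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise StatsError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return TestReport("shapiro_wilk", comparison, float(w), float(p))


def levene(
    groups: Sequence[Sequence[float]],
    center: str = "median",
    comparison: str = "",
) -> TestReport:
    """Levene homogeneity-of-variance test (Brown-Forsythe with median center)."""
    if len(groups) < 2:
        raise StatsError("Levene's test needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise StatsError("every group needs n >= 2")
    w, p = sps.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return TestReport(
        "levene", comparison, float(w), float(p), df=(float(k - 1), float(n - k))
    )


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic with mid-ranks.

    Dynamic programming over doubled ranks: the null distribution of
    2*W+ is the convolution of point masses at {0, 2*r_i}.
    """
    r2 = np.round(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt
    pmf /= 2.0 ** len(r2)
    w2 = int(round(2.0 * w_plus))
    cdf = pmf[: w2 + 1].sum()
    sf = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    zero_method: str = "wilcox",
    exact_cutoff: int = 25,
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns ``(W_plus, p)``.  Differences of zero are dropped before
    ranking (``zero_method='wilcox'``, default) or kept in the ranking and
    then dropped from the statistic (``'pratt'``).  The exact null
    distribution is used for n <= ``exact_cutoff`` retained pairs; above
    that, a normal approximation with continuity and tie correction.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if zero_method not in ("wilcox", "pratt"):
        raise StatsError(f"unknown zero method {zero_method!r}")

    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            raise StatsError("all paired differences are zero")
        ranks = sps.rankdata(np.abs(d))
    else:
        if not np.any(d != 0):
            raise StatsError("all paired differences are zero")
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]

    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_cutoff:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        mean = ranks.sum() / 2.0
        # variance from the rank set itself (valid with ties and pratt zeros)
        var = float((ranks**2).sum()) / 4.0
        dev = w_plus - mean
        cc = 0.5 * np.sign(dev) if dev != 0 else 0.0
        z = (dev - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return w_plus, p


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p_raw)."""
    return float(min(1.0, m * p_raw))


def pairwise_wilcoxon_bonferroni(
    table: pd.DataFrame,
    metric: str,
    family_size: int = 3,
    zero_method: str = "wilcox",
    exact_cutoff: int = 25,
) -> list[TestReport]:
    """Post hoc paired Wilcoxon tests between tissue pairs for one metric.

    The cohort table must hold one median per patient per tissue for the
    metric.  Family size defaults to the three tissue pairs per metric.
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise StatsError(f"metric {metric!r} not present in the cohort table")
    wide = sub.pivot(index="patient_id", columns="tissue", values="median")
    reports = []
    for a, b in TISSUE_PAIRS:
        if a not in wide.columns or b not in wide.columns:
            raise StatsError(f"tissue {a!r} or {b!r} missing for metric {metric!r}")
        paired = wide[[a, b]].dropna()
        w, p = wilcoxon_signed_rank(
            paired[a].to_numpy(),
            paired[b].to_numpy(),
            zero_method=zero_method,
            exact_cutoff=exact_cutoff,
        )
        reports.append(
            TestReport(
                "wilcoxon_signed_rank",
                f"{metric}: {a} vs {b}",
                w,
                p,
                p_adjusted=bonferroni(p, family_size),
                family_size=family_size,
            )
        )
    return reports


def _check_balanced(table: pd.DataFrame, within: Sequence[str]) -> None:
    counts = table.groupby(["patient_id", *within], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index.tolist()[:5]
        raise StatsError(f"cohort table is not balanced; offending cells: {bad}")
    patients = table["patient_id"].unique()
    cells = table.groupby(list(within), observed=True)["patient_id"].nunique()
    if (cells != len(patients)).any():
        missing = cells[cells != len(patients)].index.tolist()[:5]
        raise StatsError(f"missing patients in cells: {missing}")


def ranked_rm_anova(
    table: pd.DataFrame,
    within: Sequence[str] = ("tissue", "metric"),
) -> list[TestReport]:
    """Ranked repeated-measures ANOVA over the cohort table.

    All ``median`` values in the (sub)table are jointly rank-transformed
    (mid-ranks for ties, Conover style) and a repeated-measures ANOVA on
    the ranks is run with the patient as the repeated unit.  With two
    within factors the two main effects and their interaction are
    reported; with one factor, the single main effect (the marginal
    analyses of a single metric or a single tissue use this form on the
    corresponding sub-table).

    A table in which all values are identical yields the degenerate
    no-effect result (statistic 0, p = 1) rather than an error.
    """
    import pingouin as pg

    within = list(within)
    if not 1 <= len(within) <= 2:
        raise StatsError("ranked_rm_anova supports one or two within factors")
    required = {"patient_id", "median", *within}
    if not required.issubset(table.columns):
        raise StatsError(f"cohort table must have columns {sorted(required)}")
    _check_balanced(table, within)

    data = table.copy()
    data["rank"] = sps.rankdata(data["median"].to_numpy())
    sources = within if len(within) == 1 else [*within, f"{within[0]} * {within[1]}"]
    if np.ptp(data["rank"].to_numpy()) == 0:
        return [
            TestReport("ranked_rm_anova", src, 0.0, 1.0, df=None) for src in sources
        ]

    import warnings

    with warnings.catch_warnings():
        # epsilon sphericity estimates are not used (p_unc is reported)
        warnings.simplefilter("ignore", UserWarning)
        aov = pg.rm_anova(
            data=data,
            dv="rank",
            within=within if len(within) > 1 else within[0],
            subject="patient_id",
            detailed=True,
        )
    reports = []
    for src in sources:
        row = aov[aov["Source"] == src]
        if row.empty:
            raise StatsError(f"ANOVA source {src!r} missing from result")
        row = row.iloc[0]
        f = float(row["F"])
        p = float(row["p_unc"])
        if "ddof1" in aov.columns:
            df = (float(row["ddof1"]), float(row["ddof2"]))
        else:  # one-way detailed layout: Source row + Error row with DF
            err = aov[aov["Source"] == "Error"]
            df_err = float(err.iloc[0]["DF"]) if not err.empty else np.nan
            df = (float(row["DF"]), df_err)
        if not np.isfinite(f):  # all-tie degenerate cell structure
            f, p = 0.0, 1.0
        reports.append(TestReport("ranked_rm_anova", str(src), f, p, df=df))
    return reports
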