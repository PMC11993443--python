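"""Contingency analyses of pathological complete response (pCR).

2×2 tables of predicted group (Gp-R/Gp-NR) × outcome (pCR/non-pCR), per-group
rates with integer percent rendering, Fisher / chi-square tests with an
expected-cell rule for choosing between them, Woolf odds-ratio intervals with
the Haldane–Anscombe zero-cell correction, cell-wise pooling across datasets,
fixed-effect Mantel–Haenszel meta-analysis (DerSimonian–Laird random effects
behind a flag), and the univariate predictor screen at the conventional
clinical cutoffs.
"""

from __future__ import annotations

import dataclasses
import decimal
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable

from .io import ClinicalTable
from .signature import SampleScores

__all__ = [
    "ContingencyTable2x2",
    "MetaResult",
    "CutoffConfig",
    "make_table",
    "rates",
    "percent",
    "fisher_exact",
    "chi_square",
    "auto_test",
    "odds_ratio",
    "pool_tables",
    "mh_meta",
    "dichotomize_covariate",
    "univariate_screen",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Group × outcome counts: a=Gp-R&pCR, b=Gp-R&non-pCR, c=Gp-NR&pCR, d=Gp-NR&non-pCR."""

    a: int
    b: int
    c: int
    d: int
    group_labels: tuple[str, str] = ("Gp-R", "Gp-NR")
    outcome_labels: tuple[str, str] = ("pCR", "non-pCR")
    dataset: str = ""

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {value}")
            object.__setattr__(self, name, int(value))
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swap_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.c, self.d, self.a, self.b,
            group_labels=(self.group_labels[1], self.group_labels[0]),
            outcome_labels=self.outcome_labels,
            dataset=self.dataset,
        )


def make_table(
    groups: Sequence,
    outcomes: Sequence,
    positive_group: str = "Gp-R",
    negative_group: str = "Gp-NR",
    dataset: str = "",
) -> ContingencyTable2x2:
    """Tally paired group/outcome values; unknown outcomes are excluded with a log entry."""
    groups = pd.Series(list(groups))
    outcomes = pd.Series(list(outcomes))
    if len(groups) != len(outcomes):
        raise ValueError("groups and outcomes must be paired")
    keep = outcomes.notna() & groups.notna()
    excluded = int((~keep).sum())
    if excluded:
        logger.info(
            "make_table[%s]: excluded %d cases with unknown outcome or group",
            dataset or "-", excluded,
        )
    groups, outcomes = groups[keep], outcomes[keep].astype(bool)
    if groups.empty:
        raise ValueError("no cases left after excluding unknown outcomes")
    in_pos = groups == positive_group
    return ContingencyTable2x2(
        a=int((in_pos & outcomes).sum()),
        b=int((in_pos & ~outcomes).sum()),
        c=int((~in_pos & outcomes).sum()),
        d=int((~in_pos & ~outcomes).sum()),
        group_labels=(positive_group, negative_group),
        dataset=dataset,
    )


def percent(fraction: float, decimals: int = 0) -> float:
    """Render a proportion as a percentage, rounding half up (display convention)."""
    quantum = decimal.Decimal(1).scaleb(-decimals)
    value = decimal.Decimal(repr(float(fraction) * 100.0)).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(value)


def rates(table: ContingencyTable2x2) -> tuple[float, float]:
    """Per-group outcome proportions a/(a+b), c/(c+d)."""
    r1, r2 = table.row_margins
    if r1 == 0 or r2 == 0:
        raise ValueError("empty group margin; rates undefined")
    return table.a / r1, table.c / r2


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    return float(sps.fisher_exact(table.to_array(), alternative="two-sided")[1])


def chi_square(table: ContingencyTable2x2, continuity: bool = True) -> tuple[float, float]:
    """Pearson chi-square (optional Yates correction), df=1."""
    if min(table.row_margins) == 0 or min(table.col_margins) == 0:
        raise ValueError("zero margin: chi-square undefined, use Fisher's exact test")
    stat, p, _, _ = sps.chi2_contingency(table.to_array(), correction=continuity)
    return float(stat), float(p)


def expected_cells(table: ContingencyTable2x2) -> np.ndarray:
    rows = np.array(table.row_margins, dtype=float)
    cols = np.array(table.col_margins, dtype=float)
    return np.outer(rows, cols) / table.n


def auto_test(table: ContingencyTable2x2) -> tuple[float, str]:
    """Fisher when any expected cell < 5, else Yates-corrected chi-square."""
    if min(table.row_margins) == 0 or min(table.col_margins) == 0:
        return fisher_exact(table), "fisher"
    if expected_cells(table).min() < 5:
        return fisher_exact(table), "fisher"
    return chi_square(table, continuity=True)[1], "chi-square-yates"


def odds_ratio(
    table: ContingencyTable2x2, haldane: bool = True
) -> tuple[float, tuple[float, float]]:
    """OR = ad/bc with the Woolf 95% CI.

    With ``haldane`` (default) a zero cell adds 0.5 to every cell before
    computing both the estimate and the interval.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError("zero cell: odds ratio undefined without Haldane correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci = (math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se))
    return or_, ci


def pool_tables(tables: Iterable[ContingencyTable2x2]) -> ContingencyTable2x2:
    """Cell-wise sum of per-dataset tables (labels must agree)."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to pool")
    first = tables[0]
    for t in tables[1:]:
        if t.group_labels != first.group_labels or t.outcome_labels != first.outcome_labels:
            raise ValueError("cannot pool tables with mismatched labels")
    return ContingencyTable2x2(
        a=sum(t.a for t in tables),
        b=sum(t.b for t in tables),
        c=sum(t.c for t in tables),
        d=sum(t.d for t in tables),
        group_labels=first.group_labels,
        outcome_labels=first.outcome_labels,
        dataset="pooled",
    )


@dataclasses.dataclass
class MetaResult:
    """Fixed-effect meta-analysis of per-study 2×2 tables."""

    studies: pd.DataFrame  # dataset, or, ci_low, ci_high, weight
    pooled_or: float
    pooled_ci: tuple[float, float]
    method: str = "mantel-haenszel"

    def __post_init__(self) -> None:
        if not self.pooled_ci[0] <= self.pooled_or <= self.pooled_ci[1]:
            raise ValueError("pooled CI does not bracket the estimate")


def mh_meta(tables: Sequence[ContingencyTable2x2], method: str = "mh") -> MetaResult:
    """Combine per-study tables into a pooled odds ratio.

    ``mh``: Mantel–Haenszel fixed effect with the Robins–Breslow–Greenland
    variance for the CI.  ``dl``: DerSimonian–Laird random effects on log
    odds ratios (inverse-variance, Haldane-corrected).  Per-study rows carry
    Haldane-corrected ORs with Woolf CIs for forest-plot export.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables")
    rows = []
    for i, t in enumerate(tables):
        or_, (lo, hi) = odds_ratio(t, haldane=True)
        rows.append(
            {
                "dataset": t.dataset or f"study{i + 1}",
                "n": t.n,
                "or": or_,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    studies = pd.DataFrame(rows)

    if method == "mh":
        if len(tables) == 1:
            pooled, ci = odds_ratio(tables[0], haldane=True)
        else:
            strat = StratifiedTable([t.to_array() for t in tables])
            pooled = float(strat.oddsratio_pooled)
            lo, hi = strat.oddsratio_pooled_confint(alpha=0.05)
            ci = (float(lo), float(hi))
        # MH weights: b_i * c_i / n_i (relative contribution of each stratum)
        weights = np.array([t.b * t.c / t.n for t in tables], dtype=float)
    elif method == "dl":
        log_or = np.log(studies["or"].to_numpy())
        se = (np.log(studies["ci_high"]) - np.log(studies["ci_low"])).to_numpy() / (2 * Z_95)
        var = se**2
        w_fixed = 1 / var
        mu_fixed = (w_fixed * log_or).sum() / w_fixed.sum()
        q = float((w_fixed * (log_or - mu_fixed) ** 2).sum())
        df = len(tables) - 1
        c = w_fixed.sum() - (w_fixed**2).sum() / w_fixed.sum()
        tau2 = max(0.0, (q - df) / c) if df > 0 and c > 0 else 0.0
        weights = 1 / (var + tau2)
        mu = float((weights * log_or).sum() / weights.sum())
        se_mu = math.sqrt(1 / weights.sum())
        pooled = math.exp(mu)
        ci = (math.exp(mu - Z_95 * se_mu), math.exp(mu + Z_95 * se_mu))
    else:
        raise ValueError(f"unknown meta-analysis method {method!r}")

    total = weights.sum()
    studies["weight"] = weights / total if total > 0 else np.nan
    return MetaResult(
        studies=studies,
        pooled_or=pooled,
        pooled_ci=ci,
        method={"mh": "mantel-haenszel", "dl": "dersimonian-laird"}[method],
    )


# ---------------------------------------------------------------------------
# univariate predictor screen
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CutoffConfig:
    """Clinical dichotomisation cutoffs and their comparison directions."""

    is_threshold: float = 0.0      # Gp-R: IS > 0
    is_low: float = -25.0          # low-sensitivity stratum: IS <= -25
    rs: float = 25.0               # Oncotype RS > 25
    ki67: float = 20.0             # Ki67 >= 20%
    tils: float = 20.0             # TILs > 20%
    hrd: float = 42.0              # HRD >= 42
    tmb: float = 2.0               # TMB >= 2 mutations/Mb
    age: float = 50.0              # age > 50 years


def dichotomize_covariate(
    values: pd.Series, cutoff: float, direction: str = ">="
) -> pd.Series:
    """Binary high/low labels at a cutoff; missing values stay missing."""
    values = pd.to_numeric(pd.Series(values), errors="coerce")
    if values.notna().sum() == 0:
        raise ValueError("all covariate values missing")
    if direction == ">=":
        high = values >= cutoff
    elif direction == ">":
        high = values > cutoff
    else:
        raise ValueError(f"direction must be '>=' or '>', got {direction!r}")
    out = pd.Series(pd.NA, index=values.index, dtype="boolean")
    out[values.notna()] = high[values.notna()]
    return out


def _status_factor(series: pd.Series, positive_when: str) -> pd.Series:
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    known = series.isin(["positive", "negative"])
    out[known] = series[known] == positive_when
    return out


def univariate_screen(
    clinical: ClinicalTable,
    scores: SampleScores,
    cutoffs: CutoffConfig = CutoffConfig(),
) -> pd.DataFrame:
    """Univariate pCR odds ratios for the signature group and clinical factors.

    Each factor is dichotomised at its configured cutoff, cross-tabulated
    against pCR, and reported with the Haldane-corrected OR, Woolf 95% CI,
    the expected-cell-rule p-value and its test name.  Factors lacking both
    levels are skipped with a log entry; rows are sorted by descending OR.
    """
    data = clinical.data.set_index("sample_id")
    if "pcr" not in data.columns:
        raise ValueError("clinical table lacks a 'pcr' column")
    common = [s for s in scores.sample_ids if s in data.index]
    data = data.loc[common]
    group = scores.group.reindex(common)

    factors: dict[str, pd.Series] = {
        "IRSN Gp-R": pd.Series(group == "Gp-R", index=common, dtype="boolean"),
    }
    if "er" in data.columns:
        factors["ER-negative"] = _status_factor(data["er"], "negative")
    if "pgr" in data.columns:
        factors["PgR-negative"] = _status_factor(data["pgr"], "negative")
    if "her2" in data.columns:
        factors["HER2-positive"] = _status_factor(data["her2"], "positive")
    numeric_specs = [
        ("rs", f"RS>{cutoffs.rs:g}", cutoffs.rs, ">"),
        ("hrd", f"HRD>={cutoffs.hrd:g}", cutoffs.hrd, ">="),
        ("ki67", f"Ki67>={cutoffs.ki67:g}%", cutoffs.ki67, ">="),
        ("tils", f"TILs>{cutoffs.tils:g}%", cutoffs.tils, ">"),
        ("tmb", f"TMB>={cutoffs.tmb:g}", cutoffs.tmb, ">="),
        ("age", f"age>{cutoffs.age:g}", cutoffs.age, ">"),
    ]
    for col, name, cutoff, direction in numeric_specs:
        if col in data.columns and data[col].notna().any():
            factors[name] = dichotomize_covariate(data[col], cutoff, direction)

    rows = []
    outcome = data["pcr"]
    for name, flag in factors.items():
        keep = flag.notna() & outcome.notna()
        if keep.sum() == 0 or flag[keep].nunique() < 2:
            logger.info("univariate_screen: factor %r lacks both levels; skipped", name)
            continue
        table = make_table(
            np.where(flag[keep].astype(bool), "high", "low"),
            outcome[keep].astype(bool),
            positive_group="high",
            negative_group="low",
            dataset=name,
        )
        or_, (lo, hi) = odds_ratio(table, haldane=True)
        p, test = auto_test(table)
        rows.append(
            {
                "factor": name,
                "n": table.n,
                "or": or_,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
                "test": test,
            }
        )
    if not rows:
        raise ValueError("no evaluable factors")
    return (
        pd.DataFrame(rows).sort_values("or", ascending=False).reset_index(drop=True)
    )
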