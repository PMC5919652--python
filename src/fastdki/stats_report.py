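"""Statistical comparisons over volume tables: Shapiro-Wilk normality,
paired t-tests, one-way ANOVA, and two-way mixed-effects absolute-agreement
ICC, plus report generation for method-comparison studies (MD vs MKT vs
histology volumes).

Standard tests delegate to scipy.stats; the single-measure absolute-
agreement ICC — ICC(A,1) in the McGraw & Wong taxonomy — is computed here
from the two-way ANOVA mean squares,

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

with an F-based 95% confidence interval.  Absolute agreement penalizes
systematic rater offsets, unlike consistency-type ICCs.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maps_pipeline import mismatch_percent

__all__ = [
    "TestResult",
    "ICCResult",
    "shapiro_wilk",
    "paired_t",
    "anova_oneway",
    "icc_absolute_agreement",
    "build_report",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    mean_squares: dict = field(default_factory=dict)


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (W statistic, Royston's p approximation)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not (3 <= x.size <= 5000):
        raise ValueError("need a 1-d sample with 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("sample has zero variance")
    w, p = sps.shapiro(x)
    return TestResult(statistic=float(w), df=None, p=float(p), method="shapiro-wilk")


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test on differences d = x - y, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d samples, n >= 2")
    d = x - y
    n = d.size
    if np.ptp(d) == 0.0:
        # Zero-variance differences: identical pairs give t = 0, p = 1; a
        # constant nonzero shift is detected with certainty by convention.
        if d[0] == 0.0:
            return TestResult(0.0, n - 1, 1.0, "paired t")
        return TestResult(math.copysign(math.inf, d[0]), n - 1, 0.0, "paired t")
    t, p = sps.ttest_rel(x, y)
    return TestResult(float(t), n - 1, float(p), "paired t")


def anova_oneway(*groups) -> TestResult:
    """One-way ANOVA across k groups; F with (k-1, N-k) df."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    values = np.concatenate(gs)
    if np.ptp(values) == 0.0:
        k, N = len(gs), values.size
        return TestResult(0.0, (k - 1, N - k), 1.0, "one-way anova")
    f, p = sps.f_oneway(*gs)
    k, N = len(gs), values.size
    return TestResult(float(f), (k - 1, N - k), float(p), "one-way anova")


def _two_way_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    n, k = table.shape
    grand = table.mean()
    rows = table.mean(axis=1)
    cols = table.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = table - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute_agreement(table, *, alpha: float = 0.05) -> ICCResult:
    """Single-measure two-way absolute-agreement ICC(A,1) over an n x k
    subjects-by-raters table, with the McGraw & Wong F-based CI.

    Requires a complete table.  Identical rater columns give exactly 1.0;
    a constant offset between raters strictly lowers the coefficient.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a complete n x k table with n, k >= 2")
    if not np.all(np.isfinite(t)):
        raise ValueError("table is incomplete (non-finite entries)")
    n, k = t.shape
    msr, msc, mse = _two_way_mean_squares(t)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        # No variance anywhere: perfect (degenerate) agreement.
        return ICCResult(1.0, (1.0, 1.0), {"msr": msr, "msc": msc, "mse": mse})
    icc = (msr - mse) / denom

    if icc >= 1.0 - 1e-15:
        ci = (1.0, 1.0)
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci = (float(lower), float(upper))
    return ICCResult(float(icc), ci, {"msr": msr, "msc": msc, "mse": mse})


# ---------------------------------------------------------------------------
# Report generation over tidy volume tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject", "method", "volume_cm3")


def build_report(volumes: pd.DataFrame) -> dict:
    """Summarize a tidy volume table (columns: subject, method, volume_cm3,
    optional rater and repeat).

    Emits per-method means +- SD, paired t-tests between every method pair,
    the MKT-vs-MD mismatch percent of the group means, and absolute-agreement
    ICC tables where repeated measurements exist.  Subjects missing from any
    method are excluded listwise with a logged warning.
    """
    df = volumes.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"volume table lacks columns {missing}")
    if "rater" not in df.columns:
        df["rater"] = 1
    if "repeat" not in df.columns:
        df["repeat"] = 1

    primary = df[(df["rater"] == df["rater"].min()) & (df["repeat"] == df["repeat"].min())]
    methods = sorted(primary["method"].unique())

    # Listwise exclusion: keep subjects measured by every method.
    by_method = {m: set(primary.loc[primary["method"] == m, "subject"]) for m in methods}
    common = set.intersection(*by_method.values()) if by_method else set()
    dropped = sorted(set(primary["subject"]) - common)
    if dropped:
        logger.warning("listwise exclusion of subjects without all methods: %s", dropped)
    primary = primary[primary["subject"].isin(common)]

    wide = primary.pivot_table(
        index="subject", columns="method", values="volume_cm3"
    ).sort_index()

    summary = {
        m: {"n": int(wide[m].count()),
            "mean_cm3": float(wide[m].mean()),
            "sd_cm3": float(wide[m].std(ddof=1)) if wide[m].count() > 1 else float("nan")}
        for m in methods
    }

    pairwise = {}
    for m1, m2 in itertools.combinations(methods, 2):
        res = paired_t(wide[m1].to_numpy(), wide[m2].to_numpy())
        pairwise[f"{m1}_vs_{m2}"] = {
            "t": res.statistic, "df": res.df, "p": res.p, "n": int(len(wide)),
        }

    report: dict = {
        "n_subjects": int(len(wide)),
        "excluded_subjects": [str(s) for s in dropped],
        "summary": summary,
        "paired_tests": pairwise,
    }
    if {"MD", "MKT"} <= set(methods):
        report["mismatch_percent"] = mismatch_percent(
            summary["MKT"]["mean_cm3"], summary["MD"]["mean_cm3"]
        )

    # Reliability: inter-rater (first repeat) and intra-rater (first rater)
    # ICCs per method wherever the crossed table is complete.
    icc_tables = {}
    for m in methods:
        sub = df[df["method"] == m]
        inter = sub[sub["repeat"] == sub["repeat"].min()].pivot_table(
            index="subject", columns="rater", values="volume_cm3"
        )
        if inter.shape[1] >= 2 and inter.notna().all().all() and len(inter) >= 2:
            r = icc_absolute_agreement(inter.to_numpy())
            icc_tables[f"{m}_inter_rater"] = {"icc": r.icc, "ci95": list(r.ci95)}
        intra = sub[sub["rater"] == sub["rater"].min()].pivot_table(
            index="subject", columns="repeat", values="volume_cm3"
        )
        if intra.shape[1] >= 2 and intra.notna().all().all() and len(intra) >= 2:
            r = icc_absolute_agreement(intra.to_numpy())
            icc_tables[f"{m}_intra_rater"] = {"icc": r.icc, "ci95": list(r.ci95)}
    if icc_tables:
        report["icc"] = icc_tables
    return report


def write_report(report: dict, csv_path, json_path) -> None:
    """Persist a report as a per-method summary CSV plus the full JSON."""
    rows = [
        {"method": m, **vals} for m, vals in report.get("summary", {}).items()
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
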