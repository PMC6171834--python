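"""Cohort statistics: normative summaries, age correlations, sex
comparisons and age-quartile ANOVA.

The cohort table is a pandas DataFrame with one row per subject (one eye
each): identifier columns (``subject_id``, ``age``, ``sex``,
``bcva_snellen``, ``spherical_equivalent``, ``laterality``) followed by
metric columns. All tests are two-sided and p-values are reported raw (a
Bonferroni option exists but is off by default, matching how such
normative batteries are conventionally reported).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .normative import METRIC_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "StatResult",
    "QuartileBands",
    "DEFAULT_QUARTILES",
    "summarize",
    "pearson_with_covariate",
    "sex_ttest",
    "quartile_anova",
    "snellen_to_logmar",
    "build_tables",
    "metric_columns",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical test on one metric."""

    metric_name: str
    test_name: str
    n: int
    r_value: float | None = None
    statistic: float | None = None
    p_value: float | None = None
    group_means: dict = field(default_factory=dict)
    group_sds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r_value is not None and not -1.0 - 1e-12 <= self.r_value <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass(frozen=True)
class QuartileBands:
    """Ordered, non-overlapping closed age intervals."""

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for (lo, hi) in self.bands:
            if lo > hi:
                raise ValueError(f"band ({lo}, {hi}) is empty")
        for (a, b), (c, d) in zip(self.bands, self.bands[1:]):
            if c <= b:
                raise ValueError("bands must be ordered and non-overlapping")

    def assign(self, ages: np.ndarray) -> np.ndarray:
        """Band index per age; -1 for ages outside all bands."""
        ages = np.asarray(ages, dtype=float)
        out = np.full(ages.shape, -1, dtype=int)
        for i, (lo, hi) in enumerate(self.bands):
            out[(ages >= lo) & (ages <= hi)] = i
        return out

    def labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in self.bands]


DEFAULT_QUARTILES = QuartileBands(((10, 30), (31, 50), (51, 70), (71, 85)))


def metric_columns(table: pd.DataFrame) -> list[str]:
    """Metric columns of a cohort table, in the canonical battery order."""
    known = [m for m in METRIC_ORDER if m in table.columns]
    if known:
        return known
    skip = {"subject_id", "age", "sex", "bcva_snellen",
            "spherical_equivalent", "laterality", "signal_strength"}
    return [c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])]


def _metric_values(table: pd.DataFrame, metric: str) -> pd.Series:
    v = pd.to_numeric(table[metric], errors="coerce").dropna()
    return v


def summarize(table: pd.DataFrame, group: str | None = None,
              metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-metric mean, SD (n-1), min and max; optionally one sex group."""
    if group is not None:
        table = table[table["sex"] == group]
    rows = []
    for m in metrics or metric_columns(table):
        v = _metric_values(table, m)
        if len(v) < 2:
            warnings.warn(f"metric {m!r} has <2 values; omitted")
            continue
        rows.append({"metric": m, "n": len(v), "mean": v.mean(),
                     "sd": v.std(ddof=1), "min": v.min(), "max": v.max()})
    return pd.DataFrame(rows).set_index("metric")


def snellen_to_logmar(bcva_snellen: str) -> float:
    """logMAR of a Snellen fraction "20/x": log10(x / 20)."""
    text = str(bcva_snellen).strip()
    try:
        num, den = text.split("/")
        num_f, den_f = float(num), float(den)
    except ValueError:
        raise ValueError(f"cannot parse Snellen acuity {bcva_snellen!r}") from None
    if num_f <= 0 or den_f <= 0:
        raise ValueError(f"non-positive Snellen fraction {bcva_snellen!r}")
    return float(np.log10(den_f / num_f))


def _covariate_values(table: pd.DataFrame, covariate: str) -> pd.Series:
    if covariate == "bcva_logmar":
        return table["bcva_snellen"].map(snellen_to_logmar)
    if covariate in ("age", "spherical_equivalent"):
        return pd.to_numeric(table[covariate], errors="coerce")
    raise ValueError(f"unknown covariate {covariate!r}")


def pearson_with_covariate(table: pd.DataFrame, metric: str,
                           covariate: str = "age") -> StatResult:
    """Pearson r of a metric against a covariate, with its t-test p-value.

    p is two-sided from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of
    freedom.
    """
    x = _covariate_values(table, covariate)
    y = pd.to_numeric(table[metric], errors="coerce")
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(float), y[ok].to_numpy(float)
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(
            f"zero variance in {'covariate' if np.std(x) == 0 else metric}")
    r, p = sps.pearsonr(x, y)
    return StatResult(metric_name=metric, test_name=f"pearson_vs_{covariate}",
                      n=n, r_value=float(r), p_value=float(p))


def sex_ttest(table: pd.DataFrame, metric: str,
              equal_var: bool = True) -> StatResult:
    """Two-sample two-sided t-test of a metric between males and females.

    Pooled-variance (Student) by default; ``equal_var=False`` gives the
    Welch flavor.
    """
    groups = {}
    for g in ("M", "F"):
        v = _metric_values(table[table["sex"] == g], metric)
        if len(v) < 2:
            raise ValueError(f"sex group {g} has fewer than 2 values")
        groups[g] = v.to_numpy(float)
    t, p = sps.ttest_ind(groups["M"], groups["F"], equal_var=equal_var)
    return StatResult(
        metric_name=metric,
        test_name="t_pooled" if equal_var else "t_welch",
        n=sum(len(v) for v in groups.values()),
        statistic=float(t), p_value=float(p),
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in groups.items()},
    )


def quartile_anova(table: pd.DataFrame, metric: str,
                   bands: QuartileBands = DEFAULT_QUARTILES) -> StatResult:
    """One-way fixed-effects ANOVA of a metric across age bands.

    Subjects outside every band are excluded (count logged). Bands left
    empty are dropped; at least two non-empty bands are required.
    """
    ages = pd.to_numeric(table["age"], errors="coerce").to_numpy(float)
    idx = bands.assign(ages)
    excluded = int((idx < 0).sum())
    if excluded:
        logger.info("quartile_anova(%s): %d subject(s) outside all bands",
                    metric, excluded)
    vals = pd.to_numeric(table[metric], errors="coerce").to_numpy(float)
    samples, means, sds = [], {}, {}
    for i, label in enumerate(bands.labels()):
        v = vals[(idx == i) & np.isfinite(vals)]
        if len(v) == 0:
            continue
        samples.append(v)
        means[label] = float(v.mean())
        sds[label] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    if len(samples) < 2:
        raise ValueError("need at least two non-empty age bands")
    if all(np.allclose(s, samples[0][0]) for s in samples):
        f, p = 0.0, 1.0  # identical groups: no between-band variance
    else:
        f, p = sps.f_oneway(*samples)
    return StatResult(metric_name=metric, test_name="anova_age_bands",
                      n=sum(len(s) for s in samples),
                      statistic=float(f), p_value=float(p),
                      group_means=means, group_sds=sds)


# ---------------------------------------------------------------------------
# report bundle

def _fmt(v: float, nd: int = 2) -> float:
    return float(np.round(v, nd))


def build_tables(table: pd.DataFrame,
                 bands: QuartileBands = DEFAULT_QUARTILES,
                 covariates: tuple[str, ...] = ("age",),
                 significance: float = 0.05) -> dict[str, pd.DataFrame]:
    """The full normative report: cohort/sex summary, correlations, bands.

    Returns a dict of DataFrames: ``cohort_summary`` (mean/SD/range overall
    and by sex, with the sex t-test p), ``correlations`` (one row per
    metric x covariate), and ``age_bands`` (per-band mean/SD with the
    ANOVA p). Metrics with insufficient data are omitted with a warning.
    """
    mets = metric_columns(table)
    usable = []
    for m in mets:
        if _metric_values(table, m).size >= 3:
            usable.append(m)
        else:
            warnings.warn(f"metric {m!r} has insufficient data; omitted")

    rows = []
    for m in usable:
        total = _metric_values(table, m)
        row = {"metric": m, "mean": total.mean(), "sd": total.std(ddof=1),
               "min": total.min(), "max": total.max()}
        try:
            t = sex_ttest(table, m)
            row.update(male_mean=t.group_means["M"], male_sd=t.group_sds["M"],
                       female_mean=t.group_means["F"],
                       female_sd=t.group_sds["F"], sex_p=t.p_value)
        except ValueError:
            pass
        rows.append(row)
    cohort_summary = pd.DataFrame(rows).set_index("metric")

    rows = []
    for m in usable:
        for cov in covariates:
            try:
                res = pearson_with_covariate(table, m, cov)
            except ValueError:
                continue
            rows.append({"metric": m, "covariate": cov, "n": res.n,
                         "r": res.r_value, "p": res.p_value,
                         "significant": res.p_value < significance})
    correlations = pd.DataFrame(rows)

    rows = []
    for m in usable:
        try:
            res = quartile_anova(table, m, bands)
        except ValueError:
            continue
        row = {"metric": m, "anova_p": res.p_value, "F": res.statistic}
        for label in bands.labels():
            if label in res.group_means:
                row[f"mean_{label}"] = res.group_means[label]
                row[f"sd_{label}"] = res.group_sds[label]
        rows.append(row)
    age_bands = pd.DataFrame(rows).set_index("metric")

    return {"cohort_summary": cohort_summary, "correlations": correlations,
            "age_bands": age_bands}


def plot_age_scatter(table: pd.DataFrame, metrics: list[str], outdir,
                     significance: float = 0.05) -> list[str]:
    """Scatter plots of metrics against age with the fitted trend line.

    Returns the written file paths. Import of matplotlib is deferred so
    headless statistical use never touches a plotting backend.
    """
    import pathlib

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for m in metrics:
        res = pearson_with_covariate(table, m, "age")
        fig, ax = plt.subplots(figsize=(4, 3))
        x = pd.to_numeric(table["age"], errors="coerce")
        y = pd.to_numeric(table[m], errors="coerce")
        ax.scatter(x, y, s=8, alpha=0.6)
        ok = x.notna() & y.notna()
        slope, intercept = np.polyfit(x[ok], y[ok], 1)
        xs = np.array([x.min(), x.max()])
        ax.plot(xs, slope * xs + intercept, color="tab:red")
        ax.set_xlabel("age (years)")
        ax.set_ylabel(m)
        ax.set_title(f"r = {res.r_value:.2f}, p = {res.p_value:.3g}")
        fig.tight_layout()
        path = outdir / f"age_vs_{m}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(str(path))
    return written
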