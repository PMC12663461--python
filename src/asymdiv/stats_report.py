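"""Statistical tests applied to pipeline outputs, and the report writer.

Tests mirror common graphing-software defaults: Pearson chi-square
without continuity correction for category tables, the two-tailed
unpaired Student t-test (pooled variance; Welch by flag), and ordinary
least-squares regression reporting R², F = (n-2)·R²/(1-R²) and the
standard error of the estimate Sy.x.  No multiple-testing correction is
applied by default; Bonferroni / Benjamini–Hochberg adjusters are
available but off.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingStageError
from .kinematics import AsymmetryResult

__all__ = [
    "TestResult",
    "RegressionResult",
    "chi_square_test",
    "t_test_unpaired",
    "linear_regression",
    "adjust_pvalues",
    "summarize_asymmetry_cohort",
    "write_report",
]


@dataclass
class TestResult:
    test: str
    statistic: float
    df: float | None
    p_value: float
    n: list[int]
    effect: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "df": self.df,
                "p": self.p_value, "n": self.n, "effect": self.effect}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    sy_x: float
    n: int
    p_value: float


def chi_square_test(table) -> TestResult:
    """Pearson chi-square on an R x C count table; df = (R-1)(C-1)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.number):
        raise ValueError("table must hold nonnegative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be > 0")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(test="chi_square", statistic=float(stat), df=float(df),
                      p_value=float(p), n=[int(table.sum())])


def t_test_unpaired(x, y, welch: bool = False) -> TestResult:
    """Two-tailed unpaired t-test; pooled variance unless ``welch``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        raise ValueError("zero variance in both groups with equal means")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = x.size + y.size - 2 if not welch else None
    effect = {
        "mean_x": float(x.mean()), "sem_x": float(sps.sem(x)),
        "mean_y": float(y.mean()), "sem_y": float(sps.sem(y)),
    }
    return TestResult(test="t_welch" if welch else "t_student",
                      statistic=float(res.statistic), df=df,
                      p_value=float(res.pvalue), n=[x.size, y.size], effect=effect)


def linear_regression(x, y) -> RegressionResult:
    """Simple OLS regression with R², F and Sy.x (as graphing software prints)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0:
        raise ValueError("x is constant; regression undefined")
    fit = sps.linregress(x, y)
    n = x.size
    resid = y - (fit.slope * x + fit.intercept)
    sse = float((resid ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    f = (n - 2) * r2 / (1 - r2) if r2 < 1 else np.inf
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=r2, f_statistic=float(f),
                            sy_x=float(np.sqrt(sse / (n - 2))), n=n,
                            p_value=float(fit.pvalue))


def adjust_pvalues(pvalues, method: str = "none") -> np.ndarray:
    """Optional multiple-testing adjustment ('none', 'bonferroni', 'bh')."""
    p = np.asarray(pvalues, float)
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown method {method!r}")


def summarize_asymmetry_cohort(
    results: list[AsymmetryResult],
    group: str = "all",
) -> pd.DataFrame:
    """Counts and fractions of anterior/symmetric/posterior calls in a cohort."""
    if not results:
        raise ValueError("empty cohort")
    labels = pd.Series([r.label for r in results])
    rows = []
    for cls in ("anterior", "symmetric", "posterior"):
        count = int((labels == cls).sum())
        rows.append({"group": group, "class": cls, "count": count,
                     "fraction": count / len(results)})
    return pd.DataFrame(rows)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    return obj


def write_report(
    results: dict[str, object],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
    input_files: list[str] | None = None,
) -> Path:
    """Write a deterministic CSV/JSON result bundle plus a run manifest.

    DataFrames become CSV files, everything else JSON.  A ``None`` value
    marks a missing pipeline stage and raises ``MissingStageError`` after
    the gap is recorded in the manifest.  Identical inputs produce
    byte-identical files (keys sorted, no timestamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = sorted(k for k, v in results.items() if v is None)
    written = []
    for name in sorted(results):
        value = results[name]
        if value is None:
            continue
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            value.to_csv(path, index=False, float_format="%.9g")
        else:
            path = out_dir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(_to_jsonable(value), fh, indent=2, sort_keys=True)
                fh.write("\n")
        written.append(path.name)

    config_json = json.dumps(_to_jsonable(config or {}), sort_keys=True)
    from . import __version__

    manifest = {
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "inputs": sorted(input_files or []),
        "outputs": written,
        "missing_stages": missing,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if missing:
        raise MissingStageError(f"missing pipeline stage outputs: {missing}")
    return out_dir
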