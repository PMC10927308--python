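"""Inferential layer for paired two-condition EEG studies.

Condition contrasts use a paired sign-flip permutation test: the study is
within-subject, so under the null each subject's two condition labels are
exchangeable, i.e. the sign of each paired difference can be flipped
independently.  Reported alongside: a pooled-SD Cohen's d, Pearson age
correlations, age residualization (partialling out age before contrasting
conditions), and Benjamini-Hochberg FDR adjustment within each analysis
family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    """Outcome of one paired condition contrast (altitude minus sea level)."""

    observed_diff: float
    p_raw: float
    cohens_d: float
    n_subjects: int
    n_permutations: int
    seed: int | None = None
    p_fdr: float = np.nan


def permutation_test(
    sea: np.ndarray,
    altitude: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
) -> TestResult:
    """Paired sign-flip permutation test on per-subject condition pairs.

    Observed statistic: mean(altitude - sea).  Null distribution: the mean
    of the paired differences under independent random sign flips
    (condition-label exchange within subject).  Two-sided p with add-one
    correction: (1 + #{|null| >= |obs|}) / (1 + n_perm).  ``exact=True``
    enumerates all 2^n sign patterns instead (p = #{|null| >= |obs|} / 2^n).
    """
    sea = np.asarray(sea, dtype=float)
    altitude = np.asarray(altitude, dtype=float)
    if sea.shape != altitude.shape or sea.ndim != 1:
        raise ValueError("sea/altitude must be equal-length 1-D pair vectors")
    n = len(sea)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if not (np.isfinite(sea).all() and np.isfinite(altitude).all()):
        raise ValueError("incomplete pairs (non-finite values)")
    diffs = altitude - sea
    observed = float(diffs.mean())

    if exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 pairs")
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        null = signs @ diffs / n
        p = float((np.abs(null) >= abs(observed) - 1e-12).mean())
        n_used = signs.shape[0]
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
        null = signs @ diffs / n
        p = float((1 + (np.abs(null) >= abs(observed) - 1e-12).sum()) / (1 + n_perm))
        n_used = n_perm

    return TestResult(
        observed_diff=observed,
        p_raw=p,
        cohens_d=cohens_d(sea, altitude),
        n_subjects=n,
        n_permutations=n_used,
        seed=seed if isinstance(seed, int) else None,
    )


def cohens_d(sea: np.ndarray, altitude: np.ndarray) -> float:
    """Two-sample pooled-SD effect size, altitude minus sea level.

    d = (mean(altitude) - mean(sea)) / s_pooled, with the two condition
    samples pooled as independent groups (not the paired dz form).
    """
    sea = np.asarray(sea, dtype=float)
    altitude = np.asarray(altitude, dtype=float)
    n1, n2 = len(sea), len(altitude)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per condition")
    pooled_var = (
        (n1 - 1) * sea.var(ddof=1) + (n2 - 1) * altitude.var(ddof=1)
    ) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: effect size undefined")
    return float((altitude.mean() - sea.mean()) / np.sqrt(pooled_var))


def cohens_dz(sea: np.ndarray, altitude: np.ndarray) -> float:
    """Paired effect size: mean difference / SD of differences."""
    diffs = np.asarray(altitude, dtype=float) - np.asarray(sea, dtype=float)
    sd = diffs.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero difference variance: effect size undefined")
    return float(diffs.mean() / sd)


def pearson_age_correlation(values: np.ndarray, ages: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation between a metric and age, with two-sided p."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages) or len(values) < 4:
        raise ValueError("need >= 4 paired observations")
    if values.std() == 0 or ages.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(values, ages)
    return float(r), float(p)


def regress_out_age(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Residuals of OLS simple regression of value on age.

    Computed on the pooled (both-condition) observations; re-pair the
    residuals by subject before permutation testing.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages) or len(values) < 3:
        raise ValueError("need >= 3 observations")
    if ages.std() == 0:
        raise ValueError("constant ages: regression degenerate")
    slope, intercept = np.polyfit(ages, values, 1)
    return values - (intercept + slope * ages)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def contrast_table(
    study: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    family_cols: tuple[str, ...] = ("family",),
) -> pd.DataFrame:
    """Run the paired contrast for every (family, band, scope, metric) cell.

    ``study`` is a long-format table with columns (subject_id, age,
    condition, band, scope, metric, value, family); FDR adjustment is
    applied within each family.
    """
    required = {"subject_id", "condition", "band", "scope", "metric", "value", "family"}
    missing = required - set(study.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    rows = []
    keys = ["family", "band", "scope", "metric"]
    for key_vals, cell in study.groupby(keys, sort=True):
        wide = cell.pivot(index="subject_id", columns="condition", values="value")
        if wide.isna().any().any():
            raise ValueError(f"incomplete pairs in cell {key_vals}")
        res = permutation_test(
            wide["sea"].to_numpy(), wide["altitude"].to_numpy(),
            n_perm=n_perm, seed=rng,
        )
        rows.append(
            dict(zip(keys, key_vals))
            | {
                "observed_diff": res.observed_diff,
                "cohens_d": res.cohens_d,
                "p_raw": res.p_raw,
                "n_subjects": res.n_subjects,
                "n_perm": res.n_permutations,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for _, idx in out.groupby(list(family_cols)).groups.items():
        out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p_raw"].to_numpy())
    return out
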