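"""Group comparisons and stoichiometry summaries.

Two-sample tests are implemented from their closed forms (pooled-variance
Student's t; Kolmogorov-Smirnov D with the asymptotic Kolmogorov p) so the
statistics layer is independently checkable against scipy.  Differential
family calls require both a fold-change of the replicate means and a t-test
p below alpha; no multiple-testing correction is applied by default, with
Benjamini-Hochberg available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str  # "two_sample_t" | "ks_two_sample"
    n1: int
    n2: int


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classical pooled-variance two-sample Student's t, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per sample")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(pooled * (1 / n1 + 1 / n2))
    if denom == 0:
        t = 0.0 if x.mean() == y.mean() else np.inf * np.sign(x.mean() - y.mean())
    else:
        t = (x.mean() - y.mean()) / denom
    p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return TestResult(float(t), p, "two_sample_t", n1, n2)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D is the maximum ECDF distance,
    p the asymptotic Kolmogorov distribution tail."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n1
    cdf_y = np.searchsorted(y, grid, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = np.sqrt(n1 * n2 / (n1 + n2))
    p = float(np.clip(special.kolmogorov(d * en), 0.0, 1.0))
    return TestResult(d, p, "ks_two_sample", n1, n2)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return out


def call_differential(
    group_a: Mapping[str, Sequence[float]],
    group_b: Mapping[str, Sequence[float]],
    fold: float = 2.0,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-family up/down/ns calls between two replicate groups.

    ``up`` means group A exceeds group B by >= ``fold`` on replicate means
    with t-test p < alpha; ``down`` is the mirror call.  Families missing
    from either group are ``ns`` with a warning.
    """
    families = sorted(set(group_a) | set(group_b))
    rows = []
    for fam in families:
        a = np.asarray(group_a.get(fam, []), dtype=float)
        b = np.asarray(group_b.get(fam, []), dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning(
                "family %s missing replicates in one group; called ns", fam
            )
            rows.append((fam, np.nan, np.nan, np.nan, np.nan, "ns"))
            continue
        res = two_sample_t(a, b)
        mean_a, mean_b = a.mean(), b.mean()
        ratio = mean_a / mean_b if mean_b > 0 else np.inf
        rows.append((fam, mean_a, mean_b, ratio, res.p_value, None))
    df = pd.DataFrame(
        rows, columns=["family_id", "mean_a", "mean_b", "ratio", "p_value", "call"]
    )
    p_eff = (
        benjamini_hochberg(df["p_value"].fillna(1.0))
        if bh_correct
        else df["p_value"].to_numpy()
    )
    calls = []
    for i, row in df.iterrows():
        if row["call"] == "ns":
            calls.append("ns")
        elif p_eff[i] < alpha and row["ratio"] >= fold:
            calls.append("up")
        elif p_eff[i] < alpha and row["ratio"] <= 1 / fold:
            calls.append("down")
        else:
            calls.append("ns")
    df["call"] = calls
    return df


def filter_expressed(
    replicate_rpm: pd.DataFrame, min_rpm: float = 1.0
) -> pd.DataFrame:
    """Keep families with RPM >= min_rpm (inclusive) in every replicate
    column of every compared sample."""
    mask = (replicate_rpm >= min_rpm).all(axis=1)
    return replicate_rpm.loc[mask]


@dataclass
class RatioRecord:
    numerator_id: str
    denominator_id: str
    ratio: float
    condition: str = ""


def stoichiometry(
    mature_mpu: Mapping[str, float],
    partner_mpu: Mapping[str, float],
    pairs: Sequence[tuple[str, str]],
    condition: str = "",
) -> tuple[pd.DataFrame, float, int]:
    """sRNA:partner MPU ratios over a pair list.

    Pairs whose partner MPU is undefined (missing, NaN or <= 0) are
    dropped; returns (per-pair table, group median ratio, dropped count).
    """
    rows = []
    dropped = 0
    for mature_id, partner_id in pairs:
        num = mature_mpu.get(mature_id)
        den = partner_mpu.get(partner_id)
        if num is None or den is None or not np.isfinite(den) or den <= 0:
            dropped += 1
            continue
        rows.append(
            {
                "numerator_id": mature_id,
                "denominator_id": partner_id,
                "ratio": float(num) / float(den),
                "condition": condition,
            }
        )
    df = pd.DataFrame(rows, columns=["numerator_id", "denominator_id", "ratio", "condition"])
    median = float(df["ratio"].median()) if len(df) else float("nan")
    return df, median, dropped
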