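"""Common effect sizes for published Bateman gradients.

Published gradients come as OLS slopes on heterogeneous scales; they are
made comparable by conversion to the Pearson correlation ``r`` between
mating success and reproductive success, with a large-sample sampling
variance, and optionally Fisher's variance-stabilising ``z`` transform.
Moderators (mating-success method, inclusion of unmated females, study
type, publication year, polyandry / mating system) are coded here as well.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "slope_to_r",
    "t_to_r",
    "r_sampling_variance",
    "r_to_fisher_z",
    "classify_mating_system",
    "EFFECT_COLUMNS",
    "validate_effect_table",
    "read_effect_table",
    "write_effect_table",
]

_R_TOL = 1e-9

#: Columns of an effect-size table (one row per published Bateman gradient).
EFFECT_COLUMNS = {
    "effect_id": "opaque per-estimate label",
    "study_id": "opaque study label",
    "species": "binomial species name matching a tree tip",
    "r": "Pearson correlation of RS on MS, |r| < 1",
    "n": "number of females behind the estimate, >= 4",
    "var_r": "sampling variance of r, > 0",
    "ms_method": "'copulatory' or 'genetic' mating success",
    "ms_range": "'with_zero' or 'without_zero' mating-success range",
    "study_type": "'field' or 'laboratory'",
    "year": "publication year",
    "polyandry": "proportion of mated females with >1 partner (optional)",
    "mating_system": "'low' or 'high' polyandry class (optional)",
    "sex_role_reversed": "flag",
    "human": "flag",
}

_CATEGORICAL_LEVELS = {
    "ms_method": {"copulatory", "genetic"},
    "ms_range": {"with_zero", "without_zero"},
    "study_type": {"field", "laboratory"},
    "mating_system": {"low", "high"},
}


def slope_to_r(slope: float, sd_ms: float, sd_rs: float) -> float:
    """Convert an OLS Bateman slope to a Pearson correlation.

    r = slope * sd(MS) / sd(RS); the identity holds on any scale because the
    Pearson correlation is invariant to linear rescaling of either axis.
    """
    if sd_ms <= 0 or sd_rs <= 0:
        raise ValueError("standard deviations must be positive")
    r = slope * sd_ms / sd_rs
    if abs(r) > 1 + _R_TOL:
        raise ValueError(f"inconsistent slope/SD triplet: |r|={abs(r):.6g} > 1")
    return float(np.clip(r, -1.0, 1.0))


def t_to_r(t: float, df: float, sign: float = 1.0) -> float:
    """Recover r from a slope t-statistic and its residual degrees of freedom.

    For rows where only test statistics are published: r = sqrt(t²/(t²+df))
    carrying the sign of the reported slope.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    r = np.sqrt(t**2 / (t**2 + df))
    return float(np.copysign(r, sign if sign != 0 else 1.0))


def r_sampling_variance(r: float, n: int, formula: str = "n-1") -> float:
    """Large-sample sampling variance of a Pearson correlation.

    Default is var(r) = (1-r²)²/(n-1); ``formula='n-2'`` selects the
    alternative denominator used by some conversion references.
    """
    if n < 4:
        raise ValueError("n must be at least 4")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    denom = {"n-1": n - 1, "n-2": n - 2}[formula]
    return float((1 - r**2) ** 2 / denom)


def r_to_fisher_z(r: float, n: int) -> tuple[float, float]:
    """Fisher z transform with its sample-size-only variance 1/(n-3)."""
    if abs(r) >= 1:
        raise ValueError("z undefined for |r| = 1")
    if n < 4:
        raise ValueError("n must be at least 4")
    return float(np.arctanh(r)), float(1.0 / (n - 3))


def classify_mating_system(polyandry: float, threshold: float = 0.5) -> str:
    """Binary mating-system class from the proportion of polyandrous females.

    'high' iff polyandry > threshold; a value exactly at the threshold is
    classified 'high' (documented tie rule).  Default threshold 0.5 is the
    average level of polyandry reported for wild populations; 0.4 and 0.6
    serve as sensitivity thresholds.
    """
    if not 0 <= polyandry <= 1:
        raise ValueError("polyandry must lie in [0, 1]")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return "high" if polyandry >= threshold else "low"


def validate_effect_table(df: pd.DataFrame) -> list[str]:
    """Schema check for an effect-size table; returns row-level failure messages."""
    problems: list[str] = []
    required = ["effect_id", "study_id", "species", "r", "n", "var_r"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for i, row in df.iterrows():
        if not abs(row["r"]) < 1:
            problems.append(f"row {i} ({row['effect_id']}): |r| >= 1")
        if not row["n"] >= 4:
            problems.append(f"row {i} ({row['effect_id']}): n < 4")
        if not row["var_r"] > 0:
            problems.append(f"row {i} ({row['effect_id']}): var_r <= 0")
        if "polyandry" in df.columns and pd.notna(row.get("polyandry")):
            if not 0 <= row["polyandry"] <= 1:
                problems.append(f"row {i} ({row['effect_id']}): polyandry outside [0,1]")
        for col, levels in _CATEGORICAL_LEVELS.items():
            if col in df.columns and pd.notna(row.get(col)) and row[col] not in levels:
                problems.append(f"row {i} ({row['effect_id']}): {col}={row[col]!r} not in {sorted(levels)}")
    if df["effect_id"].duplicated().any():
        problems.append("duplicate effect_id values")
    return problems


def read_effect_table(path: str | Path, delimiter: str = ",", strict: bool = True) -> pd.DataFrame:
    """Read a delimited effect-size table and validate its schema."""
    df = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    problems = validate_effect_table(df)
    if problems and strict:
        raise ValueError("invalid effect table:\n" + "\n".join(problems))
    return df


def write_effect_table(df: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")
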