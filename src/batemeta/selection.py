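"""Individual-level sexual-selection metrics.

The Bateman gradient is the ordinary least-squares slope of reproductive
success (RS, number of offspring) on mating success (MS, number of mates or
copulations) within one study sample.  For interspecific comparison both
axes are *relativised* — divided by their sample means — which makes the
slope unitless.  The opportunity for sexual selection ``I_s`` is the
variance of relativised MS (the squared coefficient of variation), and the
Jones index ``s'_max = beta_ss * sqrt(I_s)`` is the maximum standardised
sexual selection differential.

All variances use the sample (n-1) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IndividualMatingTable",
    "read_individual_table",
    "relativize",
    "bateman_gradient",
    "opportunity_for_sexual_selection",
    "jones_index",
    "polyandry_proportion",
]


@dataclass(frozen=True)
class IndividualMatingTable:
    """Per-female mating success and reproductive success for one sample.

    Parameters
    ----------
    female_id
        Opaque labels, one per female.
    mating_success
        Number of mates (or copulations) per female; non-negative.
    reproductive_success
        Number of offspring per female; non-negative.
    """

    female_id: np.ndarray
    mating_success: np.ndarray
    reproductive_success: np.ndarray

    def __post_init__(self):
        ms = np.asarray(self.mating_success, dtype=float)
        rs = np.asarray(self.reproductive_success, dtype=float)
        ids = np.asarray(self.female_id)
        if ms.shape != rs.shape or ms.ndim != 1:
            raise ValueError("mating_success and reproductive_success must be equal-length vectors")
        if len(ms) < 2:
            raise ValueError("need at least 2 females")
        if len(ids) != len(ms):
            raise ValueError("female_id length mismatch")
        if not (np.all(np.isfinite(ms)) and np.all(np.isfinite(rs))):
            raise ValueError("non-finite values in table")
        if np.any(ms < 0) or np.any(rs < 0):
            raise ValueError("negative counts in table")
        if np.any(ms != np.round(ms)) or np.any(rs != np.round(rs)):
            # some studies report rates rather than counts; accept with a warning
            warnings.warn("non-integer mating or reproductive success values", stacklevel=2)
        object.__setattr__(self, "female_id", ids)
        object.__setattr__(self, "mating_success", ms)
        object.__setattr__(self, "reproductive_success", rs)

    def __len__(self) -> int:
        return len(self.mating_success)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "female_id": self.female_id,
                "mating_success": self.mating_success,
                "reproductive_success": self.reproductive_success,
            }
        )


def read_individual_table(path: str | Path, delimiter: str = ",") -> IndividualMatingTable:
    """Read a delimited text file with columns female_id, mating_success, reproductive_success."""
    df = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    required = {"female_id", "mating_success", "reproductive_success"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return IndividualMatingTable(
        female_id=df["female_id"].to_numpy(),
        mating_success=df["mating_success"].to_numpy(dtype=float),
        reproductive_success=df["reproductive_success"].to_numpy(dtype=float),
    )


def relativize(values) -> np.ndarray:
    """Divide a vector by its mean so the result has mean exactly 1."""
    v = np.asarray(values, dtype=float)
    m = v.mean()
    if m <= 0:
        raise ValueError("zero mean, cannot relativize")
    return v / m


def bateman_gradient(
    table: IndividualMatingTable,
    relativized: bool = True,
    include_zero_ms: bool = True,
) -> float:
    """OLS slope of reproductive success on mating success.

    ``include_zero_ms=False`` drops females with zero mating success *before*
    relativization, so the excluding-zero gradient is computed entirely on
    the mated subsample.
    """
    ms = table.mating_success
    rs = table.reproductive_success
    if not include_zero_ms:
        keep = ms > 0
        ms, rs = ms[keep], rs[keep]
    if len(ms) < 3:
        raise ValueError("fewer than 3 usable rows")
    if relativized:
        ms = relativize(ms)
        rs = relativize(rs)
    var_ms = np.var(ms, ddof=1)
    if var_ms <= 0:
        raise ValueError("no variance in mating success")
    cov = np.cov(ms, rs, ddof=1)[0, 1]
    return float(cov / var_ms)


def opportunity_for_sexual_selection(ms) -> float:
    """I_s: variance of relativised mating success, var(ms)/mean(ms)^2."""
    ms = np.asarray(ms, dtype=float)
    m = ms.mean()
    if m <= 0:
        raise ValueError("zero mean mating success")
    return float(np.var(ms, ddof=1) / m**2)


def jones_index(beta_ss_relativized: float, i_s: float) -> float:
    """s'_max = beta_ss * sqrt(I_s), the maximum standardised differential."""
    if i_s < 0:
        raise ValueError("opportunity for sexual selection must be non-negative")
    return float(beta_ss_relativized * np.sqrt(i_s))


def polyandry_proportion(ms) -> float:
    """Proportion of mated females (MS >= 1) with more than one partner."""
    ms = np.asarray(ms, dtype=float)
    mated = ms >= 1
    if not mated.any():
        raise ValueError("no mated females")
    return float(np.count_nonzero(ms > 1) / np.count_nonzero(mated))
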