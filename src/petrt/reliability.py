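"""Test-retest reliability statistics for paired PET outcome measures.

For each outcome (plasma scalars f_p, C_L, amphetamine levels; brain V_T,
BP_P, BP_ND per region) measured twice per subject:

* VAR, the test-retest variability: 100 |test - retest| / mean(test, retest),
  summarised across subjects as mean +/- sample SD;
* a one-way random-effects variance decomposition with subjects as groups
  and n = 2 repeats: WSMSS = sum_ij (x_ij - xbar_i)^2 / (N(n-1)),
  BSMSS = n sum_i (xbar_i - xbar)^2 / (N-1); WSSD = sqrt(WSMSS), BSSD the
  SD of subject means, both expressed as CVs against the grand mean;
* the intraclass correlation coefficient
  ICC = (BSMSS - WSMSS) / (BSMSS + (n-1) WSMSS), ranging from -1 (no
  between-subject variance) to 1 (test identical to retest);
* the amphetamine-challenge effect size d = |mean dBP_ND| / pooled
  variability, pooled as sqrt((BASE_TRT^2 + POST_TRT^2)/2), combining the
  baseline and post-challenge test-retest variabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PairedOutcomeTable",
    "ReliabilitySummary",
    "var_percent",
    "variance_components",
    "icc",
    "effect_size",
    "summarize_study",
]


class ReliabilityError(ValueError):
    pass


@dataclass(frozen=True)
class PairedOutcomeTable:
    """One outcome in one region: per-subject (test, retest) values."""

    outcome: str
    region: str
    test: np.ndarray
    retest: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.test, dtype=float)
        r = np.asarray(self.retest, dtype=float)
        if t.ndim != 1 or t.shape != r.shape:
            raise ReliabilityError("test and retest must be 1-D and paired")
        if t.size < 2:
            raise ReliabilityError("reliability statistics need at least 2 subjects")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(r)):
            raise ReliabilityError("missing values are not imputed; drop incomplete pairs first")
        object.__setattr__(self, "test", t)
        object.__setattr__(self, "retest", r)

    @property
    def n_subjects(self) -> int:
        return self.test.size


@dataclass(frozen=True)
class ReliabilitySummary:
    """Row of a reproducibility table: mean, variance components, VAR, ICC."""

    outcome: str
    region: str
    mean: float
    bssd: float
    bssd_cv: float
    wssd: float
    wssd_cv: float
    var_mean_pct: float
    var_sd_pct: float
    icc: float
    n_subjects: int
    n_repeats: int
    bsmss: float
    wsmss: float

    def as_dict(self) -> dict:
        return asdict(self)


def var_percent(test, retest):
    """Per-subject test-retest variability, percent.

    100 |test - retest| / ((test + retest)/2); symmetric in the two sessions.
    Accepts scalars or paired arrays.  A zero pair mean makes VAR undefined
    for that subject; scalar input raises, array input returns NaN there with
    a warning (the subject is excluded from summaries).
    """
    t = np.asarray(test, dtype=float)
    r = np.asarray(retest, dtype=float)
    m = 0.5 * (t + r)
    if t.ndim == 0:
        if m == 0:
            raise ReliabilityError("VAR undefined: test/retest mean is zero")
        return float(100.0 * abs(t - r) / abs(m))
    bad = m == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} subject(s) with zero test/retest mean excluded from VAR",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * np.abs(t - r) / np.abs(m)
    out[bad] = np.nan
    return out


def variance_components(table: PairedOutcomeTable) -> dict:
    """One-way random-effects decomposition (subjects as groups, n = 2 repeats).

    Returns BSMSS, WSMSS, BSSD (SD of subject means, ddof=1), WSSD
    (sqrt(WSMSS)) and the CVs of both SDs against the grand mean.
    """
    x = np.stack([table.test, table.retest], axis=1)  # (N, n)
    N, n = x.shape
    subj_means = x.mean(axis=1)
    grand = x.mean()
    wsmss = float(np.sum((x - subj_means[:, None]) ** 2) / (N * (n - 1)))
    bsmss = float(n * np.sum((subj_means - grand) ** 2) / (N - 1))
    bssd = float(np.std(subj_means, ddof=1))
    wssd = math.sqrt(wsmss)
    if grand == 0:
        bssd_cv = wssd_cv = np.nan
    else:
        bssd_cv = bssd / abs(grand)
        wssd_cv = wssd / abs(grand)
    return {
        "bsmss": bsmss, "wsmss": wsmss,
        "bssd": bssd, "wssd": wssd,
        "bssd_cv": float(bssd_cv), "wssd_cv": float(wssd_cv),
        "grand_mean": float(grand),
    }


def icc(table: PairedOutcomeTable) -> float:
    """One-way random-effects ICC, (BSMSS - WSMSS)/(BSMSS + (n-1) WSMSS).

    Ranges from -1 (BSMSS = 0: subjects indistinguishable, all variance
    within) to 1 (WSMSS = 0: test identical to retest).  When every value in
    the table is identical both mean squares vanish and the ICC is undefined;
    NaN is returned with a warning.
    """
    vc = variance_components(table)
    n = 2
    denom = vc["bsmss"] + (n - 1) * vc["wsmss"]
    if denom == 0:
        warnings.warn("ICC undefined: all values identical (zero variance)",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return (vc["bsmss"] - vc["wsmss"]) / denom


def effect_size(delta_mean_pct: float, base_trt_pct: float, post_trt_pct: float) -> float:
    """Challenge effect size d = |mean delta| / sqrt((BASE^2 + POST^2)/2).

    ``delta_mean_pct`` is the mean percent change in BP_ND induced by the
    challenge; the denominator pools the baseline and post-challenge
    test-retest variabilities.  d is reported as a magnitude.
    """
    if base_trt_pct < 0 or post_trt_pct < 0:
        raise ReliabilityError("test-retest variabilities must be non-negative")
    pooled = math.sqrt((base_trt_pct ** 2 + post_trt_pct ** 2) / 2.0)
    if pooled == 0:
        raise ReliabilityError("effect size undefined: zero pooled variability")
    return abs(delta_mean_pct) / pooled


def summarize_pairs(table: PairedOutcomeTable) -> ReliabilitySummary:
    """Full reproducibility row for one paired outcome table."""
    vc = variance_components(table)
    v = var_percent(table.test, table.retest)
    v = v[np.isfinite(v)]
    if v.size >= 2:
        var_mean, var_sd = float(np.mean(v)), float(np.std(v, ddof=1))
    elif v.size == 1:
        var_mean, var_sd = float(v[0]), float("nan")
    else:
        var_mean = var_sd = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        icc_val = icc(table)
    return ReliabilitySummary(
        outcome=table.outcome, region=table.region,
        mean=vc["grand_mean"],
        bssd=vc["bssd"], bssd_cv=vc["bssd_cv"],
        wssd=vc["wssd"], wssd_cv=vc["wssd_cv"],
        var_mean_pct=var_mean, var_sd_pct=var_sd,
        icc=icc_val,
        n_subjects=table.n_subjects, n_repeats=2,
        bsmss=vc["bsmss"], wsmss=vc["wsmss"],
    )


def _paired_from_long(df: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    wide = df.pivot_table(index="subject", columns="session", values=value, aggfunc="first")
    complete = wide.dropna()
    dropped = wide.shape[0] - complete.shape[0]
    if dropped:
        warnings.warn(f"{dropped} subject(s) dropped for incomplete test/retest pairs",
                      RuntimeWarning, stacklevel=3)
    sessions = sorted(complete.columns)
    if len(sessions) != 2:
        raise ReliabilityError(f"expected exactly 2 sessions, found {sessions}")
    return complete[sessions[0]].to_numpy(), complete[sessions[1]].to_numpy()


def summarize_study(outcomes: pd.DataFrame,
                    value_cols: tuple[str, ...] = ("VT", "BPP", "BPND"),
                    region_col: str = "region",
                    reference: str = "Cerebellum") -> pd.DataFrame:
    """Reproducibility table: one row per outcome x region.

    ``outcomes`` is long-format with columns (subject, session, region,
    <value columns>).  Subjects missing either session are dropped with a
    warning; subject order never affects the result.  The reference region
    is summarised for V_T only -- its own binding potentials are
    identically zero.
    """
    rows = []
    for value in value_cols:
        for region, grp in outcomes.groupby(region_col, sort=True):
            if value in ("BPP", "BPND") and str(region) == reference:
                continue
            test, retest = _paired_from_long(grp, value)
            table = PairedOutcomeTable(outcome=value, region=str(region),
                                       test=test, retest=retest)
            rows.append(summarize_pairs(table).as_dict())
    return pd.DataFrame(rows)


def summarize_scalars(scalars: pd.DataFrame, value_cols: tuple[str, ...]) -> pd.DataFrame:
    """Reproducibility rows for per-scan plasma scalars (no region dimension)."""
    rows = []
    for value in value_cols:
        test, retest = _paired_from_long(scalars, value)
        table = PairedOutcomeTable(outcome=value, region="plasma",
                                   test=test, retest=retest)
        rows.append(summarize_pairs(table).as_dict())
    return pd.DataFrame(rows)
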