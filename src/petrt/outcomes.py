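"""Reference-region outcome measures derived from regional V_T.

The cerebellum serves as the reference region: its total distribution
volume estimates the non-displaceable distribution volume V_ND, giving

    BP_P  = V_T(region) - V_T(cerebellum)      (mL cm^-3)
    BP_ND = BP_P / V_T(cerebellum)             (unitless)

Outcomes are computed per scan and only then summarised, so summary BP_ND
is a mean of per-scan ratios (not a ratio of means).  Negative binding
potentials are retained with a warning rather than censored: clamping would
bias the downstream test-retest statistics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["compute_bpp", "compute_bpnd", "scan_outcomes", "outcomes_table", "CEREBELLUM"]

CEREBELLUM = "Cerebellum"


def compute_bpp(vt_region: float, vt_cerebellum: float) -> float:
    """Binding potential relative to plasma: V_T(region) - V_T(cerebellum)."""
    if vt_region <= 0 or vt_cerebellum <= 0:
        raise ValueError("V_T values must be positive")
    bpp = vt_region - vt_cerebellum
    if bpp < 0:
        warnings.warn(f"negative BP_P ({bpp:.3g}); retained, not clamped",
                      RuntimeWarning, stacklevel=2)
    return bpp


def compute_bpnd(vt_region: float, vt_cerebellum: float) -> float:
    """Binding potential relative to non-displaceable uptake: (V_T - V_ND)/V_ND."""
    if vt_cerebellum <= 0:
        raise ValueError("reference-region V_T must be positive")
    bpnd = (vt_region - vt_cerebellum) / vt_cerebellum
    if bpnd < 0:
        warnings.warn(f"negative BP_ND ({bpnd:.3g}); retained, not clamped",
                      RuntimeWarning, stacklevel=2)
    return bpnd


def scan_outcomes(vt_by_region: dict, reference: str = CEREBELLUM) -> pd.DataFrame:
    """Per-region V_T, BP_P, BP_ND for one scan.

    The reference region's own BP_P and BP_ND are identically zero.
    """
    if reference not in vt_by_region:
        raise ValueError(f"reference region {reference!r} missing from V_T table")
    v_nd = vt_by_region[reference]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for region, vt in vt_by_region.items():
            rows.append({
                "region": region,
                "VT": vt,
                "BPP": compute_bpp(vt, v_nd),
                "BPND": compute_bpnd(vt, v_nd),
            })
    df = pd.DataFrame(rows)
    n_neg = int((df.loc[df.region != reference, "BPP"] < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} region(s) with negative binding potential retained",
                      RuntimeWarning, stacklevel=2)
    return df


def outcomes_table(vt_table: pd.DataFrame, reference: str = CEREBELLUM) -> pd.DataFrame:
    """Long outcomes table from a per-scan V_T table.

    ``vt_table`` needs columns (subject, session, region, VT); the result adds
    BPP and BPND computed against each scan's own reference V_T.
    """
    out = []
    for (subj, sess), grp in vt_table.groupby(["subject", "session"], sort=True):
        vt = dict(zip(grp["region"], grp["VT"]))
        df = scan_outcomes(vt, reference=reference)
        df.insert(0, "session", sess)
        df.insert(0, "subject", subj)
        out.append(df)
    return pd.concat(out, ignore_index=True)
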