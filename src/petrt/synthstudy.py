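"""Synthetic amphetamine-challenge test-retest PET studies with known truth.

The generator emulates one tracer study per subject and session:

* a parent plasma curve rising linearly to a peak at 1.5 min and decaying as
  a positive sum of three exponentials, sampled on a dense-early arterial
  schedule (35 samples over 90 min);
* a Hill-type parent fraction declining from 1, measured at six sparse times;
* nine regional time-activity curves (eight cortical regions + cerebellum)
  from the two-tissue compartment forward model, frame-averaged with
  Gaussian noise whose SD scales with the curve value and inversely with the
  square root of frame duration;
* plasma free fraction and amphetamine levels carried as paired scalars.

Session-to-session ("within subject") variation enters as a log-normal
scale multiplier on K1, shared across regions of a scan: a scan-level scale
factor is the dominant real-world test-retest error source (input-function
calibration), makes the true V_T exactly log-normal with the configured
within-subject CV, and cancels in the V_T ratio, so BP_ND is intrinsically
more reproducible than V_T and BP_P -- the behaviour the reliability stage
is meant to detect.  Subject-to-subject ("between subject") variation
scales both K1 and k3, so delivery and receptor availability (and hence
BP_ND) genuinely differ across subjects.  Every scan carries
a truth record (rate constants, V_T, BP_P, BP_ND, clearance), so all
downstream stages are testable against known ground truth.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import published
from .kinetics import TwoTissueParams, forward_2tc, compute_vt
from .plasma import HillParams, InputFunction

__all__ = [
    "StudyDesign",
    "SyntheticScan",
    "SyntheticStudy",
    "default_param_means",
    "sample_subject_params",
    "true_input_function",
    "generate_input_curve",
    "generate_tac",
    "generate_study",
    "write_study",
    "load_study_dir",
]

SESSIONS = ("test", "retest")

DEFAULT_FRAMES = tuple(
    [(i / 6.0, (i + 1) / 6.0) for i in range(6)]            # 6 x 10 s
    + [(1.0 + 0.5 * i, 1.5 + 0.5 * i) for i in range(4)]    # 4 x 30 s
    + [(3.0 + i, 4.0 + i) for i in range(5)]                # 5 x 1 min
    + [(8.0 + 4 * i, 12.0 + 4 * i) for i in range(8)]       # 8 x 4 min
    + [(40.0 + 5 * i, 45.0 + 5 * i) for i in range(10)]     # 10 x 5 min -> 90
)

DEFAULT_PLASMA_TIMES = tuple(
    [0.1 * i for i in range(1, 21)]                          # every 6 s to 2 min
    + [2.5, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 75.0, 90.0]
)  # 35 samples

DEFAULT_PARENT_TIMES = (4.0, 10.0, 20.0, 40.0, 60.0, 80.0)

# Ground-truth metabolite curve and input-curve shape
TRUE_HILL = HillParams(a=0.8, b=1.5, c=25.0)
PEAK_TIME_MIN = 1.5
INPUT_RATES = (0.6, 0.08, 0.011)        # 1/min, fast to slow
INPUT_AMP_FRACTIONS = (0.72, 0.20, 0.08)
PEAK_PER_MBQ = 0.09                     # kBq/mL parent at peak, per MBq injected

DEFAULT_DOSE_MBQ = 300.0                # ~8.1 mCi
TRUE_FP = 0.38
TRUE_AMPH_LEVELS = (87.0, 77.0, 74.0)   # ng/mL at 0, 45, 90 min


def default_param_means(k1: float = 0.30, k2: float = 0.12, k4: float = 0.025) -> dict:
    """Per-region population rate constants anchored to published mean V_T.

    K1, k2 and k4 are shared across regions at typical high-affinity-tracer
    values; k3 is solved per region so that (K1/k2)(1 + k3/k4) equals the
    published regional mean V_T.
    """
    means = {}
    for region, vt in published.REGIONAL_VT_MEAN.items():
        ratio = vt * k2 / k1 - 1.0
        if ratio <= 0:
            raise ValueError(f"target V_T for {region} unreachable with K1/k2 = {k1 / k2:g}")
        means[region] = TwoTissueParams(K1=k1, k2=k2, k3=k4 * ratio, k4=k4)
    return means


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to generate (and regenerate, bit-identically) a study."""

    n_subjects: int = 10
    region_names: tuple = tuple(published.REGIONAL_VT_MEAN)
    frame_schedule: tuple = DEFAULT_FRAMES
    plasma_sample_times: tuple = DEFAULT_PLASMA_TIMES
    parent_fraction_times: tuple = DEFAULT_PARENT_TIMES
    true_param_means: dict = field(default_factory=default_param_means)
    between_subject_cv: float = 0.18
    within_subject_cv: float = 0.09
    noise_scale: float = 0.025
    injected_dose_mbq: float = DEFAULT_DOSE_MBQ
    seed: int = 0

    def __post_init__(self):
        fr = np.asarray(self.frame_schedule, dtype=float)
        if np.any(fr[:, 1] <= fr[:, 0]):
            raise ValueError("every frame must have positive duration")
        if np.any(fr[1:, 0] < fr[:-1, 1] - 1e-12):
            raise ValueError("frames must be non-overlapping and increasing")
        if self.between_subject_cv < 0 or self.within_subject_cv < 0 or self.noise_scale < 0:
            raise ValueError("CVs and noise_scale must be non-negative")
        if list(self.region_names).count("Cerebellum") != 1:
            raise ValueError("design must contain the cerebellum exactly once")
        if self.n_subjects < 2:
            raise ValueError("reliability stages need at least 2 subjects")
        for region in self.region_names:
            if region not in self.true_param_means:
                raise ValueError(f"no population means for region {region!r}")
            p = self.true_param_means[region]
            for name in ("K1", "k2", "k3", "k4"):
                if getattr(p, name) <= 0:
                    raise ValueError(
                        f"population mean {name} for region {region!r} must be positive")

    @property
    def scan_duration(self) -> float:
        return float(np.asarray(self.frame_schedule)[-1, 1])


@dataclass(frozen=True)
class SyntheticScan:
    subject: int
    session: str
    plasma: pd.DataFrame          # time_min, total_activity
    parent: pd.DataFrame          # time_min, parent_fraction
    tac: pd.DataFrame             # frame_start_min, frame_end_min, <regions>
    injected_dose_mbq: float
    f_p: float
    amphetamine_levels: tuple
    true_params: dict             # region -> TwoTissueParams
    true_vt: dict                 # region -> float
    true_bpp: dict
    true_bpnd: dict
    true_clearance_lph: float
    true_input: InputFunction


@dataclass(frozen=True)
class SyntheticStudy:
    design: StudyDesign
    scans: list

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for sc in self.scans:
            for region in self.design.region_names:
                p = sc.true_params[region]
                rows.append({
                    "subject": sc.subject, "session": sc.session, "region": region,
                    "K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4,
                    "VT": sc.true_vt[region], "BPP": sc.true_bpp[region],
                    "BPND": sc.true_bpnd[region],
                    "clearance_lph": sc.true_clearance_lph,
                    "f_p": sc.f_p,
                    "amph_0": sc.amphetamine_levels[0],
                    "amph_45": sc.amphetamine_levels[1],
                    "amph_90": sc.amphetamine_levels[2],
                })
        return pd.DataFrame(rows)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal draw with SD/mean = cv; exactly 1 when cv = 0."""
    if cv == 0:
        return 1.0
    sigma2 = math.log1p(cv * cv)
    return float(np.exp(rng.normal(-0.5 * sigma2, math.sqrt(sigma2))))


def sample_subject_params(design: StudyDesign, subject_index: int, session_index: int) -> dict:
    """True per-region rate constants for one scan.

    The between-subject multiplier (shared by both sessions of the subject)
    scales K1 and k3 in every region: subjects differ both in tracer
    delivery and in receptor availability, so every outcome -- V_T, BP_P
    and BP_ND -- carries real between-subject spread.  The within-subject
    multiplier (independent per session) scales K1 only: session-to-session
    error is dominated by the scan-level input-function scale, which cancels
    in the V_T ratio and leaves BP_ND intrinsically more reproducible.
    Deterministic in (design.seed, subject_index, session_index).
    """
    if not (0 <= subject_index < design.n_subjects):
        raise ValueError("subject index out of range")
    if session_index not in (0, 1):
        raise ValueError("session index must be 0 (test) or 1 (retest)")
    m_between = _lognormal_multiplier(_rng(design.seed, 1, subject_index),
                                      design.between_subject_cv)
    m_within = _lognormal_multiplier(_rng(design.seed, 2, subject_index, session_index),
                                     design.within_subject_cv)
    return {
        region: replace(design.true_param_means[region],
                        K1=design.true_param_means[region].K1 * m_between * m_within,
                        k3=design.true_param_means[region].k3 * m_between)
        for region in design.region_names
    }


def true_input_function(design: StudyDesign, dose_mbq: float | None = None) -> InputFunction:
    """The generator's noiseless parent-plasma curve for a given dose."""
    dose = design.injected_dose_mbq if dose_mbq is None else dose_mbq
    peak = PEAK_PER_MBQ * dose
    amps = np.array(INPUT_AMP_FRACTIONS) * peak
    return InputFunction(
        peak_time=PEAK_TIME_MIN,
        amplitudes=amps,
        rates=np.array(INPUT_RATES),
        hill=TRUE_HILL,
        support=design.scan_duration,
    )


def generate_input_curve(design: StudyDesign, rng: np.random.Generator,
                         dose_mbq: float | None = None):
    """Continuous truth curve plus noisy total-activity and parent-fraction tables.

    Total activity at each arterial sample time is parent / parent-fraction
    with multiplicative log-normal noise; parent-fraction measurements get
    the same multiplicative noise, clipped to (0, 1].
    """
    inp = true_input_function(design, dose_mbq)
    t = np.asarray(design.plasma_sample_times, dtype=float)
    parent = np.atleast_1d(inp(t))
    frac = TRUE_HILL.parent_fraction(t)
    total = parent / frac
    if design.noise_scale > 0:
        sigma = math.sqrt(math.log1p(design.noise_scale ** 2))
        total = total * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=t.size))
    plasma = pd.DataFrame({"time_min": t, "total_activity": total})

    pt = np.asarray(design.parent_fraction_times, dtype=float)
    pf = TRUE_HILL.parent_fraction(pt)
    if design.noise_scale > 0:
        sigma = math.sqrt(math.log1p((0.5 * design.noise_scale) ** 2))
        pf = np.clip(pf * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=pt.size)), 1e-6, 1.0)
    parent_tbl = pd.DataFrame({"time_min": pt, "parent_fraction": pf})
    return inp, plasma, parent_tbl


def generate_tac(params: dict, inp: InputFunction, frames, noise_scale: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Frame-averaged regional TACs with duration-scaled Gaussian noise.

    Noise SD per frame = noise_scale * value / sqrt(frame duration in min);
    a noiseless call returns the 2TC forward model exactly.
    """
    fr = np.asarray(frames, dtype=float)
    dur = fr[:, 1] - fr[:, 0]
    out = {"frame_start_min": fr[:, 0], "frame_end_min": fr[:, 1]}
    for region, p in params.items():
        c = forward_2tc(p, inp, fr)
        if noise_scale > 0:
            c = c + rng.normal(0.0, 1.0, size=c.size) * (noise_scale * np.abs(c) / np.sqrt(dur))
        out[region] = c
    return pd.DataFrame(out)


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Generate a full test-retest study; bit-identical under the same design."""
    scans = []
    cereb = "Cerebellum"
    for subj in range(design.n_subjects):
        for sess_idx, sess in enumerate(SESSIONS):
            params = sample_subject_params(design, subj, sess_idx)
            noise_rng = _rng(design.seed, 3, subj, sess_idx)
            inp, plasma, parent_tbl = generate_input_curve(design, noise_rng)
            tac = generate_tac(params, inp, design.frame_schedule,
                               design.noise_scale, noise_rng)

            meta_rng_b = _rng(design.seed, 4, subj)
            meta_rng_w = _rng(design.seed, 5, subj, sess_idx)
            fp = TRUE_FP \
                * _lognormal_multiplier(meta_rng_b, design.between_subject_cv) \
                * _lognormal_multiplier(meta_rng_w, design.within_subject_cv)
            amph_b = _lognormal_multiplier(meta_rng_b, design.between_subject_cv)
            amph = tuple(
                lvl * amph_b * _lognormal_multiplier(meta_rng_w, design.within_subject_cv)
                for lvl in TRUE_AMPH_LEVELS
            )

            vt = {r: compute_vt(p) for r, p in params.items()}
            bpp = {r: vt[r] - vt[cereb] for r in params}
            bpnd = {r: (vt[r] - vt[cereb]) / vt[cereb] for r in params}
            clearance = 60.0 * design.injected_dose_mbq / inp.auc(extrapolate=True)

            scans.append(SyntheticScan(
                subject=subj, session=sess,
                plasma=plasma, parent=parent_tbl, tac=tac,
                injected_dose_mbq=design.injected_dose_mbq,
                f_p=min(fp, 1.0), amphetamine_levels=amph,
                true_params=params, true_vt=vt, true_bpp=bpp, true_bpnd=bpnd,
                true_clearance_lph=clearance, true_input=inp,
            ))
    return SyntheticStudy(design=design, scans=scans)


# ---------------------------------------------------------------------------
# Study directory I/O (CSV + YAML; the same dialects accepted for real data)


def _design_to_yaml(design: StudyDesign) -> str:
    d = asdict(design)
    d["frame_schedule"] = [list(map(float, f)) for f in design.frame_schedule]
    d["plasma_sample_times"] = list(map(float, design.plasma_sample_times))
    d["parent_fraction_times"] = list(map(float, design.parent_fraction_times))
    d["region_names"] = list(design.region_names)
    d["true_param_means"] = {
        r: {"K1": p.K1, "k2": p.k2, "k3": p.k3, "k4": p.k4}
        for r, p in design.true_param_means.items()
    }
    return yaml.safe_dump(d, sort_keys=True)


def write_study(study: SyntheticStudy, out_dir) -> dict:
    """Write a study as CSV tables + design YAML; returns {relpath: sha256}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}

    def _write(name: str, text: str):
        path = out / name
        path.write_text(text)
        manifest[name] = hashlib.sha256(text.encode()).hexdigest()

    _write("design.yaml", _design_to_yaml(study.design))
    meta_rows = []
    for sc in study.scans:
        tag = f"{sc.subject:02d}_{sc.session}"
        _write(f"plasma_{tag}.csv", sc.plasma.to_csv(index=False))
        _write(f"parent_{tag}.csv", sc.parent.to_csv(index=False))
        _write(f"tac_{tag}.csv", sc.tac.to_csv(index=False))
        meta_rows.append({
            "subject": sc.subject, "session": sc.session,
            "injected_dose_mbq": sc.injected_dose_mbq, "f_p": sc.f_p,
            "amph_0": sc.amphetamine_levels[0],
            "amph_45": sc.amphetamine_levels[1],
            "amph_90": sc.amphetamine_levels[2],
        })
    _write("scans.csv", pd.DataFrame(meta_rows).to_csv(index=False))
    _write("truth.csv", study.truth_frame().to_csv(index=False))
    return manifest


def load_study_dir(path) -> dict:
    """Load the CSV tables written by ``write_study``.

    Returns {"scans": DataFrame, "truth": DataFrame or None, and per scan
    (subject, session): {"plasma", "parent", "tac"} DataFrames}.
    """
    p = Path(path)
    scans = pd.read_csv(p / "scans.csv")
    truth_path = p / "truth.csv"
    out = {
        "scans": scans,
        "truth": pd.read_csv(truth_path) if truth_path.exists() else None,
        "data": {},
    }
    for _, row in scans.iterrows():
        tag = f"{int(row.subject):02d}_{row.session}"
        out["data"][(int(row.subject), row.session)] = {
            "plasma": pd.read_csv(p / f"plasma_{tag}.csv"),
            "parent": pd.read_csv(p / f"parent_{tag}.csv"),
            "tac": pd.read_csv(p / f"tac_{tag}.csv"),
        }
    return out
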