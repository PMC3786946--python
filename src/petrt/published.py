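"""Published summary inputs for [11C]FLB 457 amphetamine test-retest studies.

These are printed group-level summary statistics used as *inputs*: the
regional mean V_T values anchor the synthetic generator's population means,
and the challenge table feeds the effect-size computation in the worked
examples.  Nothing here is a computed output of this package.

Regions: MTL = medial temporal lobe, ACC = anterior cingulate, DLPFC =
dorsolateral prefrontal, OFC = orbital frontal, MPFC = medial prefrontal,
TC = temporal, PC = parietal, OC = occipital cortex.
"""

from __future__ import annotations

import pandas as pd

CORTICAL_REGIONS = [
    "Medial Temporal Lobe",
    "Anterior Cingulate Cortex",
    "Dorsolateral Prefrontal Cortex",
    "Orbital Frontal Cortex",
    "Medial Prefrontal Cortex",
    "Temporal Cortex",
    "Parietal Cortex",
    "Occipital Cortex",
]

#: Published post-amphetamine regional mean V_T (mL cm^-3), cerebellum included.
REGIONAL_VT_MEAN = {
    "Cerebellum": 3.90,
    "Medial Temporal Lobe": 8.45,
    "Anterior Cingulate Cortex": 6.97,
    "Dorsolateral Prefrontal Cortex": 5.96,
    "Orbital Frontal Cortex": 7.09,
    "Medial Prefrontal Cortex": 6.36,
    "Temporal Cortex": 9.64,
    "Parietal Cortex": 6.13,
    "Occipital Cortex": 5.81,
}

#: Published post-amphetamine regional mean BP_P (mL cm^-3).
REGIONAL_BPP_MEAN = {
    "Medial Temporal Lobe": 4.55,
    "Anterior Cingulate Cortex": 3.07,
    "Dorsolateral Prefrontal Cortex": 2.06,
    "Orbital Frontal Cortex": 3.19,
    "Medial Prefrontal Cortex": 2.46,
    "Temporal Cortex": 5.74,
    "Parietal Cortex": 2.23,
    "Occipital Cortex": 1.91,
}

#: Amphetamine-challenge inputs per region:
#: (mean % change in BP_ND, baseline test-retest %, post-challenge test-retest %).
CHALLENGE_INPUTS = {
    "Medial Temporal Lobe": (-7.0, 11.0, 7.0),
    "Anterior Cingulate Cortex": (-8.0, 15.0, 7.0),
    "Dorsolateral Prefrontal Cortex": (-13.0, 8.0, 5.0),
    "Orbital Frontal Cortex": (-8.0, 7.0, 11.0),
    "Medial Prefrontal Cortex": (-11.0, 6.0, 4.0),
    "Temporal Cortex": (-4.0, 10.0, 4.0),
    "Parietal Cortex": (-12.0, 8.0, 4.0),
    "Occipital Cortex": (-5.0, 10.0, 7.0),
}


def challenge_table() -> pd.DataFrame:
    """Challenge inputs as a tidy frame (region, delta_bpnd_pct, base_trt_pct, post_trt_pct)."""
    rows = [
        {"region": r, "delta_bpnd_pct": d, "base_trt_pct": b, "post_trt_pct": p}
        for r, (d, b, p) in CHALLENGE_INPUTS.items()
    ]
    return pd.DataFrame(rows)
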