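# petrt

Quantification and test-retest reliability analysis for dynamic PET
neuroreceptor studies with arterial sampling, built around the
amphetamine-challenge paradigm used with high-affinity dopamine D2/3
radioligands such as [11C]FLB 457.

Measuring cortical dopamine release hinges on a chain of estimates: a
metabolite-corrected arterial input function, regional distribution volumes
V_T from a two-tissue compartment (2TC) fit, and reference-region binding
potentials BP_P = V_T − V_ND and BP_ND = (V_T − V_ND)/V_ND with cerebellar
V_T estimating the non-displaceable volume V_ND. Whether a challenge-induced
change ΔBP_ND is detectable depends on how reproducible those outcomes are
when the same subject is scanned twice. `petrt` implements the whole chain
plus the reliability statistics used to judge it:

* per-subject test-retest variability VAR = 100·|test − retest| / mean;
* one-way random-effects variance components (BSMSS, WSMSS, BSSD, WSSD and
  their CVs) and the intraclass correlation
  ICC = (BSMSS − WSMSS)/(BSMSS + (n−1)·WSMSS), n = 2;
* challenge effect size d = |mean ΔBP_ND| / √((BASE² + POST²)/2), pooling
  baseline and post-challenge test-retest variability.

Because no raw study data are publicly deposited, the package ships a
synthetic-study generator (`petrt.synthstudy`) that emulates the full design
— triexponential plasma curves, Hill-type parent fractions, 2TC kinetics in
8 cortical regions + cerebellum, between-/within-subject log-normal
variation, frame-level noise — with population V_T anchored to published
post-amphetamine regional means and a complete ground-truth ledger, so every
downstream stage is testable end to end. See `docs/methods.md` for the
models, defaults and their rationale.

## Worked example

The numbered drivers under `analysis/` run the pipeline stage by stage,
writing tables to `results/`:

```
python analysis/01_simulate_study.py --seed 1
python analysis/02_fit_input_functions.py
python analysis/03_fit_kinetics.py
python analysis/04_compute_outcomes.py
python analysis/05_reliability_tables.py
python analysis/06_challenge_effect_size.py
```

With the default design (10 subjects × 2 sessions, 9 regions) this prints,
among other things:

```
fitted 180 region-scans; V_T recovery error median +0.5%, IQR [-0.3%, +1.6%]
...
                                  VT   BPP  BPND
Cerebellum                      3.90  0.00  0.00
Medial Temporal Lobe            8.50  4.59  1.15
Temporal Cortex                 9.66  5.75  1.44
...
per-outcome means across regions:
         var_mean_pct   icc
BPND             4.43  0.90
BPP             10.21  0.92
VT               9.26  0.89
```

The fitted group-mean V_T lands on the generator's population anchors
(cerebellum 3.90, medial temporal lobe 8.45, temporal cortex 9.64 mL cm⁻³),
and the reliability ordering reproduces the empirical finding that motivates
BP_ND as the outcome of choice: session-level input-function scale errors
cancel in the V_T ratio, so BP_ND is markedly more reproducible (VAR ≈ 4%)
than V_T or BP_P (≈ 9–10%). The final driver recomputes the
challenge-detectability table from the published summary inputs, e.g.
medial prefrontal cortex: Δ = −11%, baseline T-RT 6%, post-challenge T-RT 4%
→ d = 2.16.

The same stages are available as a CLI (`petrt simulate`, `petrt fit-input`,
`petrt fit-kinetics`, `petrt outcomes`, `petrt reliability`,
`petrt run-all`, `petrt challenge-demo`), all seeded and manifest-tracked:
`petrt run-all --seed 1 --out-dir out/` writes every intermediate artifact
plus a manifest of content hashes, and a rerun with the same configuration
is bit-identical.

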