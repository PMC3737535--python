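# flptpm

Simulation and kinetic analysis of **Flp site-specific recombination**
observed by single-molecule **tethered particle motion (TPM)**.

In a TPM assay a 1168 bp DNA molecule carrying *FRT* recombination sites
tethers a reporter bead to a coverslip. The bead's restricted Brownian-motion
(BM) amplitude tracks the effective tether length: recombinase binding bends
the sites (amplitude drops from ~83 nm to ~59-65 nm), synapsis of two bound
sites loops the DNA (~42-48 nm), and an SDS quench at the end of the
observation strips all non-covalent contacts, so the final amplitude reveals
whether covalent strand exchange (Holliday-junction formation or completed
recombination) took place. `flptpm` is for single-molecule biophysicists who
want a complete, reproducible model system for this class of experiment: a
stochastic simulator of the reaction scheme that produces realistic
bead-motion traces, and the full trace-analysis pipeline that recovers the
kinetic constants from them.

The kinetic core is a continuous-time Markov scheme

```
            kf_np*[Flp]                     kf_ps*[Flp]
 FREE  <=================>  NONPRODUCTIVE     FREE ----> PRESYNAPTIC
            kd_np
                     (1 - p_b): kf_wayward               p_b: kf_synaptic
 PRESYNAPTIC ----------------> SYNAPSED_WAYWARD    PRESYNAPTIC ----> SYNAPSED_ACTIVE
                kd_wayward                                  |  k_r (irreversible)
 SYNAPSED_WAYWARD ----------> PRESYNAPTIC                   v
                                               HOLLIDAY JUNCTION / PRODUCT
```

with outcome-labelled pre-synaptic dwells (the outcome is drawn first with
probability `p_b`, the dwell is exponential at that outcome's own rate) and
strictly irreversible chemistry — the signature that makes synapsed-dwell
histograms single-exponential for direct-orientation sites but
bi-exponential for inverted sites, where completed inversions also return
the bead to high amplitude. Dwell-time histograms are fitted with
`y = A1 exp(-k1 t) (+ A2 exp(-k2 t))`, and a model-selection rule
(improvement in Poisson-weighted R², rate separation, component weight)
operationalizes the irreversibility test. The analysis side implements the
standard TPM reduction: 40-frame windowed BM amplitudes, five-point
smoothing, stuck-bead / X-Y-distortion / tether-length QC filters,
threshold-with-persistence idealization, orientation-aware SDS-endpoint
classification, and dwell-time kinetics compiled into a per-complex rate
table.

## Worked example

Simulate a 150-molecule cohort of the direct-orientation (excision)
substrate at 200 nM recombinase with a 30-minute reaction, analyze it blind,
and print the recovered kinetics:

```python
import flptpm as f
from flptpm import preprocess as pp, segment as sg, simulate as sim

scheme = f.default_scheme("Flpe", "direct")
protocol = f.default_protocol()          # 200 nM, SDS at 30 min, 29.85 Hz
traces, paths, truth = sim.simulate_cohort(scheme, protocol, 150, seed=11)
summary = f.run_analyze(traces, sg.default_level_model("Flpe", "direct"),
                        pp.QCConfig(), protocol, orientation="direct")
print("QC passed:", summary.n_qc_passed, "of", summary.n_total)
print("classes:", {k: v for k, v in summary.class_counts.items() if v})
print("synapsed molecules ending covalently committed:",
      round(summary.synapsed_low_fraction, 3))
print(summary.kinetic_table.round(6).to_string())
```

prints

```
QC passed: 145 of 150
classes: {'synaptic': 145}
synapsed molecules ending covalently committed: 1.0
                           kf         kf_se   kf_units        kd     kd_se  n_f  n_d
complex
non_productive  185317.375027  10392.130120  M^-1 s^-1  0.037829  0.002237  330  334
wayward              0.018543      0.003953       s^-1  0.014001  0.002746   25   35
pre_synaptic     60341.884711   5673.665129  M^-1 s^-1       NaN       NaN  152    0
synaptic             0.052066      0.005010       s^-1       NaN       NaN  129    0
```

Reading the table: the two association constants (1.85e5 and 6.0e4 M⁻¹s⁻¹)
and the non-productive decay (0.038 s⁻¹) match the generating scheme
(1.8e5, 6.0e4, 0.040); the wayward row shows synapse formation at 0.019 s⁻¹
and dissociation at 0.014 s⁻¹ (true 0.017/0.016, from only 25 and 35 dwells
— the standard errors say so); the synaptic row's 0.052 s⁻¹ is the type-b
synapsis rate (true 0.049). Every QC-passing molecule ended with a low
post-SDS amplitude, i.e. covalently committed — the high-efficiency,
early-commitment behavior the scheme encodes. `run_recover` wraps this loop
and grades each rate against the generating value; the `flptpm` CLI exposes
`simulate`, `analyze` (also `--qc-only`) and `recover` with YAML configs and
TSV/JSON outputs.

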