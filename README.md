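# gqkinetics

Single-molecule analysis of helicase-mediated G-quadruplex (GQ) unfolding,
and of how GQ-stabilizing small-molecule ligands inhibit it.

Guanine-rich sequences such as the human telomeric repeat fold into
four-stranded G-quadruplexes that stall replication unless resolved by
helicases like Bloom (BLM). Ligands that stabilize GQs are usually ranked
by the thermal-stability shift they induce, but what matters in a cell is
how well they resist *enzymatic* unfolding. This package implements the two
single-molecule readouts of that resistance, together with a synthetic-data
generator that makes every analysis stage verifiable against known ground
truth:

1. **Event kinetics (smFRET).** A surface-tethered GQ carries a donor/
   acceptor pair; helicase-mediated unfolding appears as a dip in the FRET
   efficiency `E = I_A / (I_D + I_A)`. An unfolding event requires a dip to
   `E ≤ 0.45` (for at least 2 frames, so single-frame noise excursions never
   count) after the molecule has shown a folded level `E ≥ 0.55`, with
   hysteresis so wander between the thresholds is never double-counted.
   The condition-level unfolding rate pools all events over the summed
   per-molecule observation times (start of recording to photobleach or end
   of movie), zero-event molecules contributing time only:

       k = Σ events / Σ observation time .

   Uncertainty comes from a molecule-level bootstrap: resample the N
   per-molecule rates with replacement, average, repeat 20 000 times; the SD
   of a Gaussian fitted to the resampled-mean histogram is the reported
   error, with the 2.5–97.5% percentile interval alongside. Ligand
   conditions are normalized to their matched no-ligand reference.

2. **Cumulative activity (TIRF spot counting).** In a second construct the
   GQ must be unfolded before the helicase can unwind a downstream 12-bp
   duplex, releasing the donor-labelled strand from the surface. Counting
   the surviving donor spots over a time-lapse, normalizing to the first
   snapshot, and comparing the removed fraction at 600 s gives a
   threshold-free measure of relative activity.

Also included: folded-state FRET histograms (short-movie pooling) with
sum-of-Gaussians fits resolving the parallel (E≈0.70), antiparallel/hybrid
(E≈0.59) and donor-only leakage (E≈0.12) populations; robust photobleach
windowing; strict CSV/YAML/JSON/TIFF I/O; and a CLI.

## Worked example

Simulate a no-ligand reference and a slower "ligand" condition (the
generator's two-state folded↔unfolded chain with hazards `k_unfold`,
`k_refold`, realistic FRET noise and dye photobleaching), then run the full
event-kinetics pipeline:

```python
import gqkinetics as g

ref_cfg = g.TraceSimConfig(n_molecules=200, n_frames=3000, k_unfold=0.05, seed=11)
lig_cfg = g.TraceSimConfig(n_molecules=200, n_frames=3000, k_unfold=0.02, seed=12)
results = {}
for name, cfg in [("blm_only", ref_cfg), ("ligand", lig_cfg)]:
    traces, _ = g.simulate_condition(cfg)
    analysis = g.analyze_condition(traces, name)
    boot = g.bootstrap_mean_rate(analysis.records, n_boot=20000, seed=7)
    est = analysis.estimate
    print(f"{name}: {est.n_molecules} molecules, {est.n_events} events over "
          f"{est.total_time:.0f} s -> {est.pooled_rate:.3f} +/- {boot.gaussian_sd:.3f} /s")
    results[name] = (est, boot)
rel = g.relative_rate(results["ligand"][0], results["blm_only"][0],
                      results["ligand"][1], results["blm_only"][1])
print(f"relative rate: {rel.relative_rate:.2f}")
```

Output:

```
blm_only: 181 molecules, 451 events over 10289 s -> 0.044 +/- 0.006 /s
ligand: 182 molecules, 163 events over 8980 s -> 0.018 +/- 0.003 /s
relative rate: 0.41
```

The reference condition recovers a pooled rate close to its generative
hazard times the folded-state occupancy (0.05 × 0.91 ≈ 0.045 /s); the
ligand condition runs at 41% of the reference, with per-condition bootstrap
errors. About 10% of molecules are excluded automatically — they are
donor-only (no active acceptor, constant E ≈ 0.12) and carry no kinetic
information.

The same pipeline is available from the shell:

```sh
gqkinetics simulate-traces --config sim.yaml --seed 7 --out data/ref
gqkinetics analyze-traces --manifest ref.yaml --manifest pds.yaml \
    --low 0.45 --high 0.55 --min-dwell 2 --boot 20000 --seed 7 --out results/
gqkinetics analyze-spots --ref ref_counts.csv --cond lig_counts.csv \
    --t-ref 600 --out results/
```

`analyze-traces` writes a per-molecule CSV, a rate+bootstrap JSON per
condition, a summary table (condition, molecules, events, total time, rate,
SD), and each ligand's rate relative to the reference.

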