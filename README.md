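# caphys

Screening analysis for stimulus-locked wide-field calcium imaging plus
voltage-clamp current analysis, together with synthetic generators that
emulate both data modalities with full ground truth — so every stage of the
pipeline is testable without any external data.

## What it does

**Imaging pipeline** (`caphys.imaging`): two-channel TIFF stacks with
alternating unstimulated/stimulated frames are background-subtracted
(rolling ball, grayscale opening with a ball element, default radius 50 px),
XY-stabilised (subpixel phase cross-correlation), and reduced to per-ROI
F1/F2 pairs per stimulation cycle.  The activity statistic is the
instantaneous `dF/F = (F2 - F1) / F1`.  Each cell's pre-drug baseline
(>= 5 min) is fitted flat or — when the slope is significant — as an
extrapolated sloping line; a cell is called a responder when at least 3
consecutive post-drug cycles exceed 3 baseline SDs of the detrended series.
Session QC excludes sessions with counterstain z-drift and cells that are
not electrically responsive; counterstain-positive cells are ineligible as
responders but stay in the reported denominator.

**Ephys pipeline** (`caphys.ephys`): P/N leak subtraction (scaled average of
the sub-sweeps; -80→0 mV test vs -80→-100 mV sub-steps gives scale -4),
boxcar-smoothed peak currents with a 2-ms post-edge blank, I-V curves over
the -90..+40 mV ladder, and drug-response time-course classification
(responder / rundown / flat) against an extrapolated geometric rundown
trend.

**Statistics & reporting** (`caphys.stats`, `caphys.report`): Welch's
unequal-variance t test, responding-proportion arithmetic (half-up
rounding), and deterministic report bundles (CSV + text).

**Synthetic data** (`caphys.synth`): renders imaging sessions (Gaussian
soma profiles, photobleach, read noise, planted logistic-onset responders,
counterstain z-drift events) and voltage-clamp sweep sets (Boltzmann-gated
conductance, linear leak, biexponential capacitive transients, geometric
rundown, saturating drug gain, P/N sub-sweeps), each with a complete
ground-truth record for recovery testing.

## CLI

```bash
caphys simulate imaging --config imaging.yaml --out sim/          # TIFFs + sidecar + ROIs + ground truth
caphys simulate ephys   --out sim_ephys/ --seed 4                 # sweeps.csv + protocol.json
caphys analyze-imaging  --stack-dir sim/ --config params.yaml --out results/
caphys analyze-ephys    --sweeps sim_ephys/ --out results_ephys/
caphys report           --in results/ --out report/
caphys run-all          --out study/ --seed 1                     # simulate -> analyse -> report
```

Config files are YAML with keys matching `ImagingConfig`, `ChannelModel` /
`VoltageProtocol`, and `AnalysisParams` (`k_sd`, `min_consecutive`,
`rolling_ball_radius_px`, z-drift and responsiveness thresholds).  Every
stage writes a `run_log.json` with the config hash and seed; `run-all`
output is bit-identical for a fixed master seed.

## Notes

- Scaled-down defaults: synthetic sessions default to small fields
  (~100 px, tens of cells) so the recovery suites run on one CPU in
  minutes; analysis parameters in the tests use a proportionally smaller
  rolling-ball radius (12 px) on those fields.
- Inward currents are negative; percent changes of current are computed on
  magnitudes and are invariant to amplifier gain rescaling.
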