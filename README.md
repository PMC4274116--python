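# massdivide

Quantitative-phase-imaging (QPI / live-cell interferometry) analysis of how
dividing cells partition their dry mass between daughters.

In QPI, each pixel reports the optical path difference (OPD, in nm) through
the specimen.  Integrated over a cell's footprint, OPD is proportional to dry
mass through the specific refractive increment α = 1.8×10⁻⁴ m³/kg:

    m = Σ OPD · A_pixel / α .

`massdivide` turns a phase movie into per-division statistics of the
daughter-cell mass asymmetry

    Δm = 2 |m_d1 − m_d2| / (m_d1 + m_d2),

its initial value Δm₀ at the cleavage furrow (t = 0), and the rate r at which
it changes during late cytokinesis, with events ordered by
θ = atan2(r, Δm₀) for population heatmaps.

The pipeline stages, each usable on its own:

- **synthetic** — seeded generator of phase movies of growing, rounding,
  dividing cells with a complete ground-truth ledger (true masses, wrap
  masks, event times, true Δm(t)), so every stage is verifiable without a
  microscope.
- **unwrap** — phase unwrapping: a linear discriminant over 16 per-pixel
  statistics finds the boundaries of phase-wrapped regions (OPD reported
  modulo the 530 nm wavelength), a random walker segments the score image,
  and single positive +λ corrections are applied.
- **segment** — Gaussian smoothing, per-component Otsu marker selection and
  watershed splitting of touching cells; per-cell mass (pg), area, mean
  phase shift, shape factor 4πA/P², and frame confluence.
- **tracking** — minimum-cost frame-to-frame linking of cell centroids
  (squared-displacement cost, 20 µm/frame gate, no gap closing).
- **division** — division events from three criteria: a parent track ends
  and two ~half-mass tracks begin nearby; the parent mean-phase trace
  matches a rising sigmoid (mitotic rounding); both daughter traces match a
  falling sigmoid (flattening).  Non-adherent mode uses the mass criterion
  only.  Also reports time in mitosis and time rounded post-division.
- **stats** — Δm dynamics, heatmap ordering, population curves (mean |Δm|
  vs time, mass CV in 10-min bins, binned growth rates), Welch's t test and
  the regression F test.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate one adherent cell that divides slightly asymmetrically
(daughter-1 fraction f = 0.55, so the true Δm₀ = 2|2f−1| = 0.20), then run
the full pipeline:

```sh
cat > scenario.yaml <<'EOF'
n_frames: 50
interval: 3.0
noise_sd: 3.0
shape: [96, 96]
cells:
  - cell_id: cell0
    center: [48.0, 48.0]
    initial_mass: 300.0
    growth_rate: 0.3
    t_furrow: 96.0
    split_fraction: 0.55
EOF
massdivide simulate --scenario scenario.yaml --seed 3 --out sim
massdivide run --in sim/movie_opd.tif --mode adherent --out results
```

which prints

```
wrote 50 frames to sim
{"n_frames": 50, "n_regions": 68, "n_tracks": 3, "n_events": 1}
```

— 68 segmented regions (one cell for 32 frames, then two daughters for 18),
three tracks (parent and two daughters), one detected division.
`results/events.csv` holds:

```
event_id  t_furrow_min  m_parent_pg  m_d1_pg  m_d2_pg   dm0  time_in_mitosis_min  time_rounded_post_min
       0          96.0       327.95  179.938  148.671  0.19                 27.0                   24.0
```

The furrow is found at 96 min (the programmed frame), the parent mass is
328 pg (300 pg plus 0.3 pg/min growth), the measured Δm₀ = 0.19 against the
programmed 0.20 (watershed assigns the lobe-overlap pixels to one side, a
~5% shrinkage documented in the methods note), and the rounding times —
27 min in mitosis, 24 min rounded after division — recover the programmed
sigmoid midpoints (30 and 24 min) to within one 3-min frame.
`results/asymmetry.csv` adds the per-event rate (r ≈ 0: no redistribution
was programmed) and ordering key θ, and `results/heatmap_signed.csv`,
`mean_abs_dm.csv`, `mass_cv.csv` hold the population summaries.

The same analysis is available as a library:

```python
import massdivide as md

scenario = md.CellScenario(cell_id="c", center=(48., 48.), t_furrow=96.0,
                           split_fraction=0.55)
frames, truth = md.simulate_movie([scenario], n_frames=50, seed=3,
                                  shape=(96, 96))
regions = [md.segment_and_measure(f, md.SegmentationConfig()) for f in frames]
tracks = md.build_tracks(regions, 20.0, [f.time for f in frames])
events = md.detect_divisions(tracks, adherent=True, n_frames=50)
print(events[0].dm0)          # 0.19
```

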