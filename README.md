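# flymotor

Quantitative analysis of heat-shock-stress-induced degeneration in the
*Drosophila* flight motor — the network of dorsal longitudinal flight-muscle
(DLM) fibers, their motor neurons, and the associated perisynaptic glia.
The package implements, as tested and reusable code, the three quantitative
procedures such studies rely on, together with a synthetic-data simulator
that provides exact ground truth for every stage:

1. **Segment-based fragmentation scoring** of terminal axon branches and
   glial processes on confocal maximum projections.  A branch centerline is
   divided along its long axis into consecutive 1 µm segments; a segment
   containing a clearly discernible discontinuity longer than 0.5 µm is
   scored non-continuous, and

   *percent continuous* = 100 × (continuous segments) / (all segments)

   is the measure of non-degenerated axonal (HRP/SYT channels) or glial
   (GS2 channel) structure.  The standard sampling design scores the ten
   most centrally located branches in each of three preparations (n = 30).

2. **Perinuclear ubiquitin-puncta classification and P62 colocalization**
   in muscle fibers.  Ubiquitin-positive puncta are detected on the
   projection, classified by the signed distance *d* from their centroid to
   the nearest DAPI-defined nucleus boundary (*d* < 0 → nuclear interior;
   0 ≤ *d* ≤ d_max → perinuclear, default d_max = 2 µm; else
   non-perinuclear), and scored for object-based colocalization with the
   autophagy adaptor P62 (a punctum is P62-positive iff ≥ 50% of its pixels
   exceed the P62 channel's robust threshold).  A two-timepoint comparison
   flags classes whose counts collapse (ratio < 0.25) as *cleared* —
   the hallmark of the protective perinuclear compartment.

3. **Behavioral indices and group statistics.**  Flight index
   FI = mean over tests of the per-test mean adhesion height (cm) of six
   flies in an oiled cylinder (integer heights, 0–17 cm); climbing index
   CI = 1 / (grand-mean climb time) in s⁻¹.  Group values are reported as
   mean ± s.e.m. with n = number of independent groups, compared by the
   classic pooled-variance two-tailed Student's t-test at P ≤ 0.05
   (Welch's test available as an option).

Because no imaging data are deposited with such studies, the
`flymotor.synthetic` module simulates the inputs with known truth: tubular
axon branches with an adjacent glial sheath and Poisson-process
fragmentation gaps, muscle fields with nuclei, perinuclear ring puncta,
larger dispersed puncta and a partially colocalized P62 channel, and
behavioral cohorts of flier/non-flier mixtures.  Generator and scorer share
one distance definition and one gap rule, so every pipeline stage is tested
closed-loop against exact ground truth.

## Worked example

Simulate two conditions — a mild-fragmentation control (gap rate
0.01 µm⁻¹) and a heat-shock-like condition (0.15 µm⁻¹) — score 3
preparations × 10 branches each, and compare flight cohorts (intact vs
fully flightless):

```sh
flymotor run --config demo.yaml --outdir demo_out
```

with `demo.yaml`:

```yaml
seed: 1
fragmentation:
  conditions:
    control: {gap_rate_per_um: 0.01}
    hs:      {gap_rate_per_um: 0.15}
  n_preparations: 3
  branches_per_preparation: 10
  n_candidates: 12
flight:
  conditions:
    control: {p_flightless: 0.0}
    hs:      {p_flightless: 1.0}
  params: {n_tests: 10}
```

`demo_out/fragmentation_summary.json` then reports (abridged):

```
control: percent_continuous mean 97.86, sem 0.79, n 30
hs:      percent_continuous mean 70.17, sem 1.87, n 30
ttest:   t = 13.67, df = 58, p = 8.6e-20, significant
```

i.e. the control branches are almost fully continuous while the stressed
condition has lost ~30% of its segments, a difference the pooled t-test on
the 30 + 30 branch scores detects overwhelmingly.  The flight summary shows
FI 10.42 ± 0.26 (control, n = 10 tests) vs FI 0 (flightless cohort),
p = 3.6e-19 — the flight-loss phenotype.  Each run writes a
`manifest.json` echoing the resolved configuration and package version;
identical configurations reproduce results byte for byte.

The same analyses are available programmatically
(`flymotor.generate_branch_image`, `flymotor.score_branch`,
`flymotor.detect_puncta`, `flymotor.flight_index`, …) and as individual CLI
subcommands (`simulate`, `score-fragmentation`, `score-puncta`,
`compare-timepoints`, `behavior`, `report`).

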