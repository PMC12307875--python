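# mamquant

Quantification toolkit for the imaging and plate assays used to study
ER stress and ER–mitochondria communication: organelle contact ("MAM")
overlap from two-channel fluorescence, mitochondrial length and morphology
classes, tandem-fluorophore autophagy/mitophagy flux, reference-normalized
calcium traces, fractional ATP bioenergetics, flow-cytometry summaries,
and volcano-filter screening of differential-expression tables against a
mitochondrial gene list. It is aimed at cell biologists who have these
readouts as TIFFs and CSVs and want reproducible, parameter-recorded
numbers instead of ad-hoc spreadsheet steps.

Every analysis ships with a synthetic generator that produces the same
kind of data with exact ground truth, so each statistic is validated by
recovery tests — no external data needed.

## The statistics it computes

- **Overlap index**: channels are uniformly contrast-stretched,
  thresholded (global Otsu from the control batch by default), puncta
  < 10 px removed; the per-sample count of coordinates foreground in both
  binarized channels is normalized to the control-group mean:
  `index_i = overlap_i / mean(overlap_control)`, so controls average to 1.
  Pearson's r on raw intensities is reported separately.
- **Morphometry**: per mitochondrion, length = longest skeleton geodesic
  (resampled to remove chain-code bias, end-corrected via the distance
  transform) × pixel size; categories: fragmented < 2.5 µm ≤ intermediate
  ≤ 5 µm < filamentous.
- **Flux**: red-puncta % = 100·#red-only/#total (green-positivity by a
  background median + 3·MAD rule); red-intensity % = 100·Σred/(Σred+Σgreen).
- **Calcium**: ΔF/F0 on the per-timepoint indicator/reference ratio,
  `dff0(t) = (R(t) − R(0))/R(0)` — shared bleaching cancels.
- **Bioenergetics**: glucose dependence = (Ā_ctrl − Ā_DG)/Ā_ctrl,
  mitochondrial dependence = (Ā_ctrl − Ā_OA)/Ā_ctrl, with FAO/AAO and
  glycolytic capacities as their complements (pair sums exactly 1).
- **Expression**: up/down calls at |log2FC| ≥ 2 and p ≤ 0.01 (inclusive),
  case-insensitive mitochondrial-list mapping, and 2^−ΔΔCt qPCR fold
  changes.
- **Plumbing**: Welch unpaired two-tailed comparisons, group mean ± SEM,
  fold changes, and a deterministic simulate→quantify→report pipeline.

See `docs/methods.md` for assumptions, parameter defaults and edge cases.

## Worked example

Simulate a tandem mCherry-EGFP reporter cell with 30% acidified vesicles
and quantify it:

```sh
mamquant simulate --kind reporter --seed 3 --out rep.tif
printf 'sample_id,group,path\nr1,control,rep.tif\n' > manifest.csv
mamquant flux --manifest manifest.csv --mode lc3 --out flux.csv
cat flux.csv
```

```
sample_id,group,value_pct,status
r1,control,30.0,ok
```

30.0 is the red-puncta percentage — of the 30 generated puncta, exactly
round(30 × 0.3) = 9 have their EGFP quenched, and the detector/classifier
recovers all of them. The same pattern works for the other assays, e.g.
an ATP plate:

```sh
mamquant simulate --kind plate --seed 3 --out plate.csv
mamquant atp --plates plate.csv --out profile.csv
```

which for a plate generated with true fractions (glucose 0.40,
mitochondrial 0.60) at 5% replicate noise prints a profile with
`glucose_dependence_pct ≈ 41.4` and `mitochondrial_dependence_pct ≈ 62.1`
— the generative truth recovered within the noise. The full library API
(`mamquant.colocalization`, `.morphometry`, `.reporters`, `.signals`,
`.bioenergetics`, `.expression`, `.pipeline`, `.synthetic`) exposes the
same computations on in-memory arrays and DataFrames.

An end-to-end deterministic run (simulate → overlap index → morphometry →
ATP profiles, with a JSON run log):

```sh
mamquant run --seed 5 --out-dir demo_run
```

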