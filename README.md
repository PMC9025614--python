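# tailmorph

Quantitative analysis for the **mouse-tail model of psoriasis** — the classic
in-vivo morphometric assay in which a substance's anti-psoriatic potency is
read off the tail-scale epidermis. The baseline state of the mouse tail scale
is *parakeratotic* (no granular layer, as in psoriatic plaque); an active
compound induces *orthokeratosis*, i.e. a granular layer re-appears over part
of each scale. `tailmorph` is for preclinical dermatopharmacology groups who
run (or simulate) this assay and want its measurements, derived parameters
and statistics as a tested, reproducible pipeline instead of spreadsheet
arithmetic.

## The model and its parameters

For each scale (the epidermal unit between two adjacent hair follicles) two
primary lengths are measured on a stained section:

* **A** — horizontal length of the *continuous* granular layer in the scale (µm),
* **B** — horizontal scale length, follicle to follicle (µm),

plus five vertical epidermal-thickness readings per scale, taken from the
dermo-epidermal junction to the bottom of the stratum corneum (the cornified
layer is excluded). Derived parameters:

* **Orthokeratosis degree** of a scale: `OK = 100 · A / B` (percent).
* **Mean epidermal thickness** of a scale: the mean of its readings (µm).
* **Percentual drug activity** of a treatment group with mean degree `Oks`
  against the vehicle-control group's mean degree `Okc`:

  `activity = (Oks − Okc) / (100 − Okc) × 100`

  (0 for the vehicle itself, 100 at complete orthokeratosis; negative values
  are reported as computed).

Group comparisons use the Kruskal–Wallis test (tie-corrected midranks). The
pairwise matrix runs its two-sample special case for every unordered group
pair, by default on **per-animal means** (the animal is the exchangeable
unit, n = 6 per group) with an **exact permutation p-value** — the full
enumeration of all C(12, 6) = 924 assignments — and flags each pair `S`
(p ≤ 0.05) or `N`.

The package ships a synthetic-study generator that emulates the assay's
design — 7 treatment arms (untreated, white soft paraffin vehicle, tretinoin
0.05 % positive control, diclofenac 1 %/2 %, celecoxib 1 %/2 %), 6 animals
per group, 10 scales per animal, 5 thickness readings per scale — with the
reported group means/SDs as defaults, plus schematic labeled pseudo-histology
images with ground-truth sidecars so the image-measurement code can be
validated end to end.

## Worked example

```python
import tailmorph as tm

# the packaged 7-arm study design; simulate one study
specs = tm.default_study_specs()
frame = tm.generate_study(specs, seed=7)           # 420 scales, 2100 readings

summaries = tm.summarize_groups(
    frame, control_group="white soft paraffin", activity_excluded=("untreated",)
)
for s in summaries:
    act = "" if s.drug_activity is None else f"  activity {s.drug_activity:5.2f}%"
    print(f"{s.group:20s} OK {s.ok_mean:5.2f} ± {s.ok_sd:5.2f}%{act}")

matrix = tm.pairwise_comparisons(frame, endpoint="orthokeratosis", unit="animal")
print(matrix.to_markdown())
```

prints (seed 7):

```
untreated            OK 17.68 ±  1.83%
white soft paraffin  OK 18.30 ±  2.91%  activity  0.00%
tretinoin 0.05%      OK 47.08 ±  6.45%  activity 35.23%
diclofenac 1%        OK 39.49 ± 14.09%  activity 25.94%
diclofenac 2%        OK 40.65 ±  7.10%  activity 27.35%
celecoxib 1%         OK 43.55 ±  6.37%  activity 30.90%
celecoxib 2%         OK 59.29 ± 10.62%  activity 50.17%
```

Each line is one arm's mean ± SD orthokeratosis degree over its 60 scales and
its drug activity relative to the vehicle; the pairwise matrix flags every
treated arm `S` against both negative controls (p = 0.002, the exact
animal-level floor 2/924) while the two negative controls are `N` against
each other — the qualitative pattern expected of an active compound panel.

The same pipeline runs from the shell:

```bash
tailmorph run --seed 7 --out results_dir        # generate → score → stats → figures
tailmorph generate --seed 7 --out m.csv
tailmorph score --measurements m.csv --control "white soft paraffin" --out summary.csv
tailmorph stats --measurements m.csv --endpoint orthokeratosis --unit animal --out pw.csv
tailmorph measure --images DIR --out measured.csv   # label-image morphometry
```

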