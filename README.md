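# stilkit

Stromal tumor-infiltrating lymphocytes (sTILs) — mononuclear immune cells
within breast-cancer stroma — are a prognostic and predictive biomarker,
but visual scoring by pathologists suffers substantial interobserver
variability. `stilkit` is a Python library and CLI that models, end to end,
how an automated (deep-learning-style) sTIL reader interacts with a panel
of pathologists: computing the sTIL score from cell detections and tissue
segmentations, calibrating its constant, quantifying inter-rater agreement,
triaging discordant reads for assisted revision, and testing whether the
resulting scores predict neoadjuvant-chemotherapy response. It is aimed at
researchers studying reader-study design and human–AI scoring workflows in
digital pathology; all inputs can be generated synthetically, so the whole
pipeline runs without any image data.

## The score

With `N` lymphoid cells detected on cancer-stroma pixels of area `A` (μm²),

    sTIL% = α · N / (A / U),      α = 7.0,  U = 400 μm²

Treating a lymphocyte as a disk of radius 3 μm, geometric stromal coverage
is `100·π·9·N/A`, so the implied multiplier at U = 400 is
`100·π·9/400 ≈ 7.068` — which is why α ≈ 7 turns a dot count into a
percentage commensurate with pathologists' visual coverage estimates.
`calibrate_alpha` selects α from candidates {6.5, 7.0, 7.5} by Lin's
concordance correlation coefficient (CCC) against a rater-panel mean on
randomly cropped grids. Agreement machinery includes Lin's CCC with Fisher-z
confidence intervals, per-case coefficient of variation, nonparametric
Bland–Altman limits (2.5/97.5 percentiles), McNemar's test, t tests, and a
from-first-principles IRLS logistic regression reporting odds ratios with
Wald intervals. See `docs/methods.md` for the full model description.

## Worked example

```python
import stilkit as sk

tmap  = sk.generate_tissue_map(1200, 1200, mpp=2.0,
                               stroma_fraction=0.4, cancer_fraction=0.35, seed=1)
cells = sk.generate_cells(tmap, sk.IntensityConfig(base_density=7000), seed=2)

truth = sk.true_stil(tmap, cells)
score = sk.score_slide(cells, tmap)
rater = sk.simulate_rater(tmap, cells, sk.RaterProfile(rater_id="A"), seed=3)
auto  = sk.simulate_dl_reader(tmap, cells, sk.ReaderErrorProfile(), seed=4)
```

prints (via the obvious format strings):

```
true sTIL      19.76%  (4025 lymphocytes in 0.576 mm² stroma)
equation score 19.57%  (alpha=7.0, U=400 um^2)
rater A reads  15%
automated read 17.90%  (realized stroma IoU 0.666)
```

The equation score sits within 1% of the geometric truth (the constant
ratio 7.0/7.068); the simulated pathologist is noisier and biased low; the
automated reader loses some counts to its degraded stroma mask (IoU tuned
to 0.666) but regains them through its false-positive load, landing close
to truth.

A full synthetic reader study — 50 slides, four biased/noisy raters three
of whom score each slide, one automated reader, 10-point triage, assisted
revision, response cohort — is one call:

```python
bundle = sk.run_full_study(sk.RunConfig(), seed=42)
bundle.write("out/")   # report.json, panels, slides, cohort, config echo
```

For seed 42 the report shows 41/50 slides (82%) initially discordant
(max pairwise rater difference ≥ 10 points); 24 slides (48%) revisited by
at least one rater (9 by one, 8 by two, 7 by three raters); across-rater
COV falling from 0.503 to 0.372 after revision; discordant slides falling
41 → 29 (McNemar p ≈ 5e-4); and every pairwise rater CCC increasing (e.g.
B~C 0.618 → 0.851). The same numbers are in `bundle.results` and in the
written `report.json`.

The CLI mirrors the stages:

```
stilkit simulate --seed 3 --out slides/ --n-slides 10
stilkit score slides/slide_0000.pgm slides/slide_0000.cells.csv
stilkit calibrate --replicates 100 --seed 0
stilkit run-all --seed 42 --out out/
```

Tissue maps travel as plain PGM rasters (labels 0 = background, 1 = cancer
area, 2 = cancer stroma; μm-per-pixel in a comment line), cell tables,
score panels and cohorts as CSV, reports as JSON.

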