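# iamtox

Predicting the acute aquatic toxicity of organic UV filters (sunscreen
ingredients) from their phospholipid binding, measured by biomimetic
HPLC on an immobilized-artificial-membrane (IAM) column.

Sunscreen UV filters wash into surface waters in large amounts, and many of
the common ones are highly lipophilic. Their toxicity to aquatic organisms
tracks how strongly they partition into cell membranes, which an IAM column
(phosphatidylcholine bonded to silica) measures directly as the
Chromatographic Hydrophobicity Index, CHI<sub>IAM</sub> — roughly the %
acetonitrile in the mobile phase at elution. Unlike log *P*, CHI<sub>IAM</sub>
also captures electrostatic repulsion of anionic species from the
phospholipid surface, which is why it predicts ecotoxicity better.

The package is aimed at cheminformatics / environmental-risk practitioners
who want a tested, scriptable version of this workflow:

* **CHI calibration** — ordinary least squares of predetermined standard
  CHI values on gradient retention times, `CHI = a·t_R + b`, with a
  standard-error diagnostic, plus binding-strength classes
  (CHI > 45 strong, CHI < 20 weak).
* **QSAR models** — single-descriptor lines
  `pLC50/pEC50 = β₀ + β₁·CHI_IAM` for fish (48 h LC50) and *Daphnia magna*
  (48 h EC50, immobilization), with the usual fit statistics
  (R², R²adj, s, F). Coefficients are recovered from the published
  (CHI, prediction) pairs by OLS, guarded by a ≤ 0.01 refit gate.
* **Applicability domain** — Williams-plot diagnostics: leverage
  `h = x'(X'X)⁻¹x`, warning leverage `h* = 3k/n`, and externally
  studentized residuals `r_i = e_i / (σ₍₋ᵢ₎ √(1−h_i))`.
* **External validation** — residuals, RMSEP, RSEP % (100·RMSEP/ȳ) and
  bias (mean ŷ−y) with model-comparison tables.
* **Hazard classification** — `C [mg/L] = MW·10^(−p)·1000` and GHS acute
  aquatic categories (I ≤ 1 < II ≤ 10 < III ≤ 100 mg/L).
* **PCA profiling** — autoscaled PCA of the descriptor matrix with
  score-plot cluster labels (lipophilic-neutral vs anionic-hydrophilic).
* **Synthetic data** — seeded generators for training sets, calibration
  runs and compound panels at the published noise scales, so every stage is
  testable without downloads.

The 13-compound UV-filter panel (descriptors, measured CHI<sub>IAM</sub>,
experimental and third-party endpoint values) ships as CSV fixtures under
`iamtox/data/`.

## Worked example

```python
from iamtox import load_uv_filter_panel, run_predict

rows = run_predict(load_uv_filter_panel(), "daphnia_pEC50")
for r in rows:
    if r.compound in ("Dioxybenzone", "Homosalate", "Sulisobenzone"):
        print(f"{r.compound:14s} CHI={r.descriptor_value:5.1f} "
              f"pEC50={r.p_value:.2f} EC50={r.hazard.conc_mg_l:6.2f} mg/L "
              f"{r.hazard.label}")
```

prints

```
Dioxybenzone   CHI= 39.9 pEC50=4.21 EC50= 15.12 mg/L Harmful
Homosalate     CHI= 56.8 pEC50=4.85 EC50=  3.69 mg/L Toxic
Sulisobenzone  CHI= 14.3 pEC50=3.23 EC50=180.01 mg/L Not classified
```

Homosalate, a strong phospholipid binder (CHI 56.8), is predicted acutely
toxic to *Daphnia* in the single-digit mg/L range (GHS Acute II), while the
fully anionic sulisobenzone binds weakly and falls outside the GHS acute
classes. The same models, applied at 2-decimal precision, reproduce the
published prediction tables; `iamtox reproduce-tables` writes the
re-derived tables plus a per-cell manifest that separates exact matches
from the documented inconsistencies of the printed source tables.

The CLI mirrors the library:

```bash
iamtox calibrate --standards standards.csv --samples samples.csv
iamtox predict --model daphnia:chi --compounds panel.csv
iamtox ad-check --model fish:chi --training-summary summary.csv --compounds panel.csv
iamtox validate --endpoint daphnia --compounds endpoints.csv
iamtox classify --compounds panel.csv --endpoint fish --source chi
iamtox pca --compounds panel.csv --scores-out scores.csv
iamtox synth training --seed 7 --out train.csv
iamtox reproduce-tables --output-dir repro
```

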