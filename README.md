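# hypoxiquant

Quantification of pimonidazole-detectable hypoxia in brightfield
immunohistochemistry of tumor sections, with the reliability statistics
needed to decide how many sections per tumor to analyze.

Pimonidazole is a 2-nitroimidazole tracer that forms adducts in viable cells
at pO₂ < 10 mmHg; in tissue sections it is detected by IHC with the brown
DAB chromogen over a blue hematoxylin counterstain.  In pancreatic ductal
adenocarcinoma (PDAC) the dense desmoplastic stroma makes epithelial/stromal
discrimination hard, so a useful hypoxia score must work at the level of
individual cells, not pixels.  `hypoxiquant` implements that pipeline as an
open, testable library:

1. **Stain preparation** — per-tile white-balance estimation from background
   glass, Beer–Lambert conversion to optical density
   (OD = −log₁₀(I/I₀)), and linear unmixing of the OD vectors into
   hematoxylin and DAB concentration channels with configurable stain
   vectors.
2. **Cell segmentation** — Otsu + distance-transform-watershed nucleus
   segmentation on the hematoxylin channel, then simulation of cell bodies
   by growing class-specific cytoplasm radii around each nucleus
   (epithelial > fibroblast > inflammatory), with contested pixels going to
   the nearest nucleus.
3. **Cell classification** — two-annotator consensus merging with an
   anti-epithelial precedence (epithelial < stromal < inflammatory/other),
   and a pixel-wise random-forest classifier trained on consensus-labelled
   nuclei, aggregated per cell by majority vote.
4. **Hypoxia scoring** — a cell is pimonidazole positive when more than 50%
   of its mean OD comes from the DAB channel *and* its DAB OD is at least
   0.1.  The hypoxic percentage (HP) of a compartment is the area of its
   positive cells over the total analyzed tumor area, so
   HP_wt = HP_epi + HP_str holds exactly at every aggregation level.
5. **Heterogeneity statistics** — nested random-effects decomposition of HP
   into between-patient, between-section and between-ROI variance
   (REML via statsmodels, with closed-form ANOVA estimators as a
   cross-check), the intraclass correlation ICC₁ = σ²_patient/σ²_total, and
   the Spearman–Brown step-up ICC_k = k·ICC₁/(1+(k−1)·ICC₁) for the mean of
   k sections.
6. **Synthetic data** — a generator for H-DAB PDAC-like tiles (gland-ring
   epithelium, elongated fibroblasts, inflammatory clusters, a
   diffusion-limited DAB gradient) with exhaustive ground truth, simulated
   annotators, and hierarchical HP tables with specified variance
   components, so the whole pipeline is testable without patient data.

## Worked example

How many sections per tumor are needed for a reliable HP estimate?  Fit the
variance components of a (here: synthetic) section-level HP table and read
the ICC as a function of section count:

```python
import hypoxiquant as hq

cfg = hq.HPTableSynthConfig(n_patients=92, n_sections=5, n_rois=1,
                            mean=12.0, sigma2_patient=9.0,
                            sigma2_section=0.0, sigma2_roi=4.0, seed=16)
df = hq.generate_hp_table(cfg)           # columns: patient_id, section_id, hp_wt
res = hq.HPVarianceModel.from_dataframe(df, value="hp_wt").fit()
print(res.summary())
```

```
HP variance components (two-level)
==============================================
measure:            hp_wt
method:             reml
grand mean (HP %):    12.518
sigma2 patient:        8.814
sigma2 section:        3.705
fraction patient       70.4 %
fraction section       29.6 %
ICC (1 section):       0.704
ICC (2 sections):      0.826
ICC (3 sections):      0.877
ICC (4 sections):      0.905
ICC (5 sections):      0.922
sections for ICC >= 0.85: 3
```

The fit recovers the generating structure (σ²_patient = 9, σ²_within = 4,
i.e. ICC₁ = 0.69 and ~70% of variance between patients): a single section is
an unreliable tumor-level measurement (ICC 0.70), but averaging three
sections crosses the conventional 0.85 high-reliability bar.

The image side of the pipeline runs the same way:

```python
img, truth = hq.generate_tissue_tile(hq.TissueSynthConfig(seed=3))
result = hq.analyze_tile(img, classes=truth.classes)  # or model=<trained forest>
print(result.hp_record.hp_epi, result.hp_record.hp_str, result.hp_record.hp_wt)
```

A thin CLI (`hypoxiquant separate-stains / analyze / consensus / score
/ stats / icc / simulate`) wraps these functions for shell use.

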