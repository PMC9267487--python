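# vesselzoner

Spatial phenotyping of capillary subsets in regenerating flat-bone
sections, with bone histomorphometry.

## The problem

During intramembranous bone regeneration (e.g. vertical augmentation on
the calvarium), capillaries that co-express high levels of the
endothelial markers **CD31** (PECAM1) and **EMCN** (Endomucin) —
"type-H-like" vessels — are thought to organize osteogenic niches: they
concentrate in the osteogenic zone between the new-bone front and the
granulation tissue, surrounded by Osterix-positive (OSX) osteoprogenitors.
Testing this on histology requires a quantitative chain: measure punctate
in-situ-hybridization signal per capillary, gate capillaries into
expression categories, and map each category's spatial distribution
relative to the native bone surface (the *bone bed*).

`vesselzoner` implements that chain as a tested, deterministic pipeline
for people who analyze section images exported from QuPath-style tools —
and ships a synthetic-histology generator with planted ground truth so
that every stage can be validated end to end without real slides.

## What it computes

Per capillary ROI *i* and channel *c* ∈ {CD31, EMCN}, the **relative
area**

&nbsp;&nbsp;&nbsp;&nbsp;aᵢ꜀ = |spot pixels in ROIᵢ| / |ROIᵢ pixels|,

where spots are segmented by white top-hat filtering, a per-channel
global threshold (Otsu or fixed), and a component-size filter.  A
**threshold cross** (t_CD31, t_EMCN) then partitions the (a_CD31,
a_EMCN) plane into four quadrants — HH, HL, LH, LL, with "≥ threshold"
counting as High.  The cross is placed automatically at the limit of the
denser core of the 2-D kernel density estimate: the smallest superlevel
set connected to the global mode that holds a target share of the sample
(default 75%), stopping short of merging with any second density cluster;
this keeps the dominant Low/Low population in the LL quadrant.  Manual
thresholds are supported for operator fidelity.

Each capillary also gets its minimal Euclidean distance to the bone-bed
polyline.  Per-category distance distributions are summarized as
violin-style profiles (Gaussian KDE reflected at zero) and compared with
the two-sample Kolmogorov–Smirnov statistic

&nbsp;&nbsp;&nbsp;&nbsp;D = sup₍ₓ₎ |F̂₁(x) − F̂₂(x)|,

with the asymptotic p-value at significance p ≤ 0.05.  Companion modules
register adjacent sections by landmark similarity fitting, score OSX
point enrichment near HH vs LL capillaries, and compute bone
histomorphometry (new-bone area fraction, mean front heights above the
bed, equal-variance t-test between groups).

## Worked example

Simulate one full synthetic section (5 × 8 mm at 4 µm/px, 269 capillaries,
HH band planted at 2.0 mm, LL at 0.8 mm) and analyze it end to end:

```python
from vesselzoner import RunConfig, SceneConfig, run_pipeline

run_pipeline(RunConfig(mode="simulate", out_dir="demo", seed=11,
                       scene=SceneConfig()))
print(open("demo/summary.txt").read())
```

```
mode: simulate
seed: 11
capillaries analyzed: 269
category counts: HH=50, HL=18, LH=13, LL=188
threshold cross: t_cd31=0.178735 t_emcn=0.136053 method=auto fallback=False
profile HH: n=50 mean=1.9936 mm sem=0.0764 mm mode=1.8256 mm
profile HL: n=18 mean=1.1731 mm sem=0.1154 mm mode=0.9317 mm
profile LH: n=13 mean=1.3588 mm sem=0.1877 mm mode=1.8045 mm
profile LL: n=188 mean=0.8273 mm sem=0.0344 mm mode=0.6359 mm
KS HH vs HL: D=0.5889 p=9.512e-05
KS HH vs LH: D=0.4385 p=2.563e-02
KS HH vs LL: D=0.8149 p=3.255e-24
KS HL vs LH: D=0.2949 p=4.543e-01
KS HL vs LL: D=0.3457 p=2.946e-02
KS LH vs LL: D=0.4771 p=4.827e-03
OSX enrichment (HH vs LL, r=100 um): 2.337
histomorphometry: bone=8.949% bone_height=0.698 mm gt_height=7.820 mm
ground-truth category agreement: 0.9926
```

Reading this: the automatic cross left the large LL population (188/269)
in the Low/Low quadrant; the recovered HH capillaries sit at a mean
1.99 mm above the bed versus 0.83 mm for LL — the planted osteogenic-band
gradient — and their distance distributions differ decisively (KS HH vs
LL, p ≈ 3e-24).  OSX points are ~2.3× denser within 100 µm of HH
capillaries than of LL ones (planted enrichment 3, diluted by band
overlap).  99.3% of capillaries recovered their planted category from the
rendered, noisy images.

The same analysis runs on real exports from the shell:

```sh
vesselzoner analyze --cd31 cd31.tif --emcn emcn.tif \
    --annotations section.geojson --out results/
vesselzoner simulate --config run.yaml --out demo/   # synthetic end-to-end
vesselzoner convert --in qupath_export.geojson --out normalized.geojson
```

Annotations are GeoJSON FeatureCollections (capillary `Polygon`s with
`"class": "capillary"`, one bone-bed `LineString` with
`"class": "bone_bed"`); features travel as plain CSV.

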