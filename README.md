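# funduslayers

Layer decomposition of color fundus photographs for detecting the two main
visible signs of diabetic retinopathy: **red lesions** (microaneurysms and
hemorrhages — small dark reddish spots) and **hard exudates** (bright,
sharp-edged yellowish lipid deposits).  It is aimed at researchers building
or benchmarking retinal screening pipelines who want a transparent,
fully-inspectable alternative to end-to-end learned detectors, together with
a synthetic-fundus generator that provides exact ground truth for every
structure the method models.

## Method

All sizes are expressed as fractions of the field-of-view diameter *D*
(pixels), so the pipeline is resolution independent; the optic disc is
modeled as a circle of radius *R*<sub>OD</sub> = *D*/12.

1. **Preprocess** — five operations: bright border artifact removal,
   background extension, illumination/color equalization, denoising, and
   contrast enhancement, yielding the normalized image *I*<sub>prep</sub>.
2. **Background** — a large-window median estimate *I*<sub>bg</sub>;
   replacing dark pixels with the background gives *I*<sub>bg−bri</sub>,
   replacing bright pixels gives *I*<sub>bg−dark</sub>.
3. **Residuals** — the dark residual
   *I*<sub>dark</sub> = clip(*I*<sub>bg</sub> − *I*<sub>bg−dark</sub>, 0, 1)
   colors every dark structure by the per-channel magnitude of its deviation
   (bright residual analogously).  Vessel pixels are removed using a
   segmented vessel mask.
4. **HSV layers** — fixed inclusive HSV ranges split each residual into
   layers: choroidal/tigroid texture (H = [0.75, 0.1], wrapping past red),
   red-lesion candidates (H = [0.1, 0.45], S ≥ 0.1, V ≥ 0.2), bright
   choroidal texture (H = [0.75, 0.15]), nerve-fiber reflective streaks
   (H = [0.25, 0.85], restricted to a morphological band around the major
   vessels: opening radius *R*<sub>OD</sub>/10, dilation *D*/60), and
   exudate candidates (H = [0.15, 0.45], S ≥ 0.1, V ≥ 0.1).  Confounder
   layers take precedence; the optic-disc circle is excluded from exudate
   candidates.
5. **Classification** — every 8-connected candidate region is described by
   100 features (shape, color statistics in the region and in an
   *R*<sub>OD</sub>-circle around it on each layer, edge sharpness, line
   response, distances to disc and fovea).  A fast correlation-based filter
   (FCBF, symmetrical-uncertainty ranking with redundancy elimination)
   selects features; the published subsets (24 for red lesions, 34 for
   exudates) ship as defaults.  A 3-layer perceptron (tanh hidden layer,
   logistic output; 51 hidden units / λ = 0.5 for red lesions, 55 / 0.4 for
   exudates) trained by scaled conjugate gradient on cross-entropy separates
   true lesions from false candidates.
6. **Evaluation** — a ground-truth lesion counts as detected when at least
   one of its pixels is predicted (SEp, PPVp); an image is pathological when
   at least 30 lesion pixels are predicted (SEi, SPi, ACCi).

## Worked example

```python
import json
from funduslayers.pipeline import collect_training_sets, detect, train_pipeline
from funduslayers.synth import SceneSpec, generate, generate_corpus

corpus = generate_corpus(12, seed=7, pathological_frac=0.5)
sets = collect_training_sets(corpus)
model_rl, log = train_pipeline(corpus, "rl", seed=7, precollected=sets["rl"])
model_ex, _ = train_pipeline(corpus, "ex", seed=7, precollected=sets["ex"])
print("training log:", {k: log[k] for k in
      ("n_candidates", "n_positive", "n_balanced", "n_hidden", "reg_lambda")})

img, truth = generate(SceneSpec(seed=99, n_ma=4, n_he=2, n_ex=3))
res = detect(img, model_rl, model_ex)
print(json.dumps({k: res["summary"][k] for k in ("rl", "ex", "pathological")}, indent=2))
print("true RL pixels:", int(truth["rl"].sum()),
      "true EX pixels:", int(truth["ex_union"].sum()))
```

prints

```
training log: {'n_candidates': 96, 'n_positive': 38, 'n_balanced': 76, 'n_hidden': 51, 'reg_lambda': 0.5}
{
  "rl": {"n_candidates": 11, "n_pixels": 98, "pathological": true},
  "ex": {"n_candidates": 7, "n_pixels": 70, "pathological": true},
  "pathological": true
}
true RL pixels: 94 true EX pixels: 75
```

The 12-image corpus yields 96 red-lesion candidate regions of which 38
overlap a true lesion; training balances the classes (76 samples) and fits
the default 51-unit perceptron.  On an unseen scene with 4 microaneurysms,
2 hemorrhages and 3 exudates, the detector keeps 11 red-lesion and 7
exudate regions (98 and 70 pixels against 94 and 75 true pixels) and flags
the image pathological under the 30-pixel rule.

A command-line interface mirrors the library:
`funduslayers simulate | preprocess | background | anatomy | decompose |
train | detect | evaluate | select-features` (see `funduslayers --help`).

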