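# seadapt

Semi-supervised domain adaptation for patch-based multispectral benthic
habitat classification.

A CNN that maps seagrass, sea, sand, land and intertidal habitat in
multispectral imagery of one coastal site usually fails at a new site: the
per-class spectral distributions shift between locations, and labeling every
new scene is expensive. `seadapt` adapts a trained source-site model to a
new site using **all unlabeled patches** from both sites plus **n labeled
samples per class** (*n*-shot) from the new site, in two steps:

1. **Adversarial marginal alignment.** A discriminator D is trained to tell
   source embeddings G_s(x_s) from target embeddings G_t(x_t) (binary
   cross-entropy, source = 1); the target embedding G_t — initialized from
   the frozen G_s — is trained to fool it, so that p(G_t(x_t)) matches
   p(G_s(x_s)) without any target labels.
2. **Few-shot contrastive semantic alignment.** Each labeled target sample
   is paired with 400 source samples per class. The joint objective

   L = L_C(G_t∘C_t) + L_C(G_s∘C_s) + L_SA + L_CS

   combines the classification losses with a semantic-alignment term
   L_SA = Σ ½‖G_s(x_i^s) − G_t(x_j^t)‖ over same-class cross-domain pairs
   and a class-separation term L_CS = Σ ½·max(0, m − ‖·‖)² over
   different-class pairs (margin m = 1), with gradients flowing into both
   embeddings.

The classifier is patch-based: a 5×5×8 reflectance patch predicts the class
of its center pixel through a 2-layer CNN embedding (20@2×2, 100@4×4, giving
a 100-dim embedding) and an 84-unit dense classifier. Single-step baselines
(source-only, adversarial-only, fine-tuning, contrastive-only) run from the
same configuration. Because no benchmark imagery is bundled, the package
includes a synthetic scene generator with controllable marginal and
class-conditional shift, plus the empirical atmospheric-correction chain
(diffuse attenuation, Beer's-law propagation, remote-sensing reflectance,
band averaging, per-band linear calibration) used to bring imagery and
shipboard radiometry onto one scale.

## Worked example

Generate a synthetic cross-site pair under the strong-shift regime and adapt
with 5 labeled target samples per class (schedule scaled 1:10 for a quick
run):

```bash
seadapt synth --regime strong --seed 1 --out data/
seadapt adapt --data data/ --method source-only --reps 3 --seed 7 --scale 10 --out runs/source_only/
seadapt adapt --data data/ --method proposed --shots 5 --reps 3 --seed 7 --scale 10 --out runs/proposed/
```

which logs, for the unadapted and adapted models respectively:

```
stage=adapt method=source-only rep=0 accuracy=0.6962
stage=adapt method=source-only rep=1 accuracy=0.6962
stage=adapt method=source-only rep=2 accuracy=0.6962
stage=adapt method=proposed rep=0 accuracy=1.0000
stage=adapt method=proposed rep=1 accuracy=1.0000
stage=adapt method=proposed rep=2 accuracy=1.0000
```

Each `accuracy` is the fraction of labeled target pixels (excluding the 25
shots) classified correctly. The source-only model misclassifies ~30% of the
target site — its errors are structural (whole regions confused under the
spectral shift), so every replicate fails on the same pixels — while the
adapted model recovers the target site exactly. `runs/proposed/results.csv` holds the per-replicate rows
plus mean ± sd, and `manifest.json` records config, seeds and artifacts for
re-running. The same pipeline is available as a library:

```python
from seadapt import TrainConfig, run_two_step, synthdata

suite = synthdata.benchmark_suite(seed=1)
src, sm, tgt, tm, truth = synthdata.generate_scene_pair(suite["strong"].config)
result = run_two_step(src, sm, tgt, tm, shots=5,
                      config=TrainConfig(seed=7).scaled(10))
print(result.target_accuracy)
```

Other subcommands: `evaluate` (stratified k-fold CV), `map` (scene-wide
classification maps, TIFF + color PNG), `tsne` (2-D embeddings of raw and
embedded samples for shift visualization), and `atmcorr` (per-band
calibration from station radiometry).

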