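# mvseg — multi-view CNN segmentation of ocular structures and tumor in eye MRI

`mvseg` segments co-registered multi-sequence eye MRI into six classes —
background, sclera, vitreous humour, lens, retinal detachment and tumor —
in a single step, for quantitative work on retinoblastoma (volumetry,
radiomics) where manual delineation is the bottleneck. It is aimed at
researchers in ophthalmic image analysis who need a voxelwise classifier
that trains on small cohorts, plus the scaffolding to develop and validate
it without patient data.

## The model

Every voxel **x** is classified from 2D patches in the three orthogonal
planes through it (a 2.5D *multi-view* design) at pyramid scales
λ ∈ {0, 1, 2}: the scale-λ patch covers a (32·2^λ)² in-plane field of view,
average-pooled back to 32×32, with MR sequences (FIESTA-like steady-state,
T2, contrast-enhanced T1) as channels. Each (view, λ) branch applies

    [conv 3×3 → BN → ReLU] ×2 → max-pool 2×2 → dropout(0.25) → dense(32) → BN → ReLU

and the concatenated branch outputs pass through
dense(32) → BN → ReLU → dropout(0.25) → dense(6) → softmax, giving
p(c | x). Training minimizes unweighted categorical cross-entropy

    H(p, q) = − Σ_c Σ_a p(a, c) · log q(a, c)

with Adam (batch 64) on a random subset of eligible voxels, reshuffled per
epoch. Preprocessing finds the eye with a 3D Hough sphere transform and
standardizes intensities to mean 0 / variance 1 inside 5-mm eye masks.
Evaluation reports per-class Dice coefficients DSC = 2|A∩B|/(|A|+|B|),
volumes in mL, ICC(A,1) volumetric agreement, Wilcoxon signed-rank
comparisons and tumor-size terciles under leave-one-subject-out (LOSO)
cross-validation. Synthetic eye phantoms (scleral shell, vitreous, lens,
tumor blobs, detachment wedge, per-sequence contrasts + noise) make the
whole pipeline testable end to end. See `docs/methods.md` for details and
design choices.

## Worked example

Generate a phantom cohort, train one LOSO fold of the best configuration
at the reduced desk profile, and evaluate the held-out eye:

```python
import mvseg

cohort = mvseg.generate_cohort(10, base_spec=mvseg.desk_spec(seed=0), seed=7)
params = mvseg.desk_params()

model, log = mvseg.train_fold(
    cohort, held_out="subject00",
    params=params, net_template=mvseg.desk_network(), seed=11,
)
print("epoch losses:", [round(l, 3) for l in log.epoch_losses])

from mvseg.training import prepare_subject, ExperimentGrid
held = prepare_subject(cohort[0], ExperimentGrid.best(), params)
pred = mvseg.predict_volume(
    held.stack, held.roi, model,
    extractor=held.extractor(model.config.scales, model.config.views),
    roi_dilation_mm=params.inference_dilation_mm,
)
result = mvseg.evaluate_prediction(cohort[0].labels, pred.labels, "subject00")
for cls, m in result.metrics.items():
    print(f"{cls:>18}: DSC={m.dsc:.3f}  ref={m.reference_mL:.3f} mL  pred={m.predicted_mL:.3f} mL")
```

which prints (seed-exact):

```
epoch losses: [0.848, 0.436]
            sclera: DSC=0.823  ref=1.022 mL  pred=0.878 mL
          vitreous: DSC=0.910  ref=1.420 mL  pred=1.581 mL
              lens: DSC=0.752  ref=0.106 mL  pred=0.082 mL
retinal_detachment: DSC=0.773  ref=0.119 mL  pred=0.109 mL
             tumor: DSC=0.891  ref=0.367 mL  pred=0.311 mL
               eye: DSC=0.971  ref=3.033 mL  pred=2.961 mL
```

The per-epoch losses are the mean cross-entropy per training sample; DSC is
spatial overlap in [0, 1]. The held-out tumor is recovered at DSC 0.89 with
its 0.37 mL volume estimated at 0.31 mL, and the whole eye (union of the
five ocular classes) overlaps at 0.97. The `mvseg` CLI wraps the same stages
(`mvseg phantom|preprocess|train|infer|evaluate|run`); `mvseg run --out
dir/ --seed 5` executes phantom generation → preprocessing → LOSO →
evaluation and writes per-eye tables, summaries and a checksummed manifest.

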