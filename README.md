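# fedleak

Privacy analysis of federated learning for chest-X-ray-style image
classification, rebuilt as a fully synthetic, CPU-scale pipeline.

A hospital federation trains a shared binary classifier ("finding present"
vs "no finding") by federated averaging: each of 36 clients — five large
adult-population sites plus 31 small sites holding between 1 and 500
images from either an adult or a pediatric population — runs one local
epoch of SGD and shares its updated parameters.  An honest-but-curious
server can invert those parameter updates: starting from random pixels
x', it minimizes

    d(x') = 1 − ⟨∇θ′(x'), ∇θ⟩ / (‖∇θ′(x')‖ ‖∇θ‖) + α·TV(x')

where ∇θ is the gradient proxy recovered from the shared update
(before − after parameter difference), ∇θ′ the autodiff gradient at the
dummy batch, and TV an anisotropic total-variation prior (α = 0.01),
using Adam on the sign of the loss gradient.  The defense is
differentially private local training (DP-SGD): per-sample gradients are
clipped to an ℓ2 bound C (the median unclipped norm from an auxiliary
run), averaged, and perturbed with Gaussian noise of scale σ·C.  Privacy
is accounted as Rényi differential privacy of the subsampled Gaussian
mechanism over orders α ∈ [1.1, 10.9] (step 0.1) ∪ [12, 63] (step 1) and
converted to (ε, δ) via ε = min_α RDP(α) + log(1/δ)/(α−1), with
δ = min(0.9/n, 10⁻²) per client.

Everything runs on numpy: the package ships a small reverse-mode autodiff
engine with higher-order derivatives (the attack differentiates through a
gradient computation), a toy CNN that trains in seconds, exact parameter
enumerations of DenseNet121/ResNet50 for architecture-level analyses, and
a synthetic image generator whose images encode patient age and sex so
that demographic leakage from reconstructions is measurable.

## Worked example

Attack a one-image client and compare with an ε = 10 private update:

```python
import numpy as np
from fedleak import (ModelConfig, build_model, make_image, local_train,
                     TrainConfig, AttackConfig, run_attack, psnr,
                     rescale_unit)

model, params = build_model(ModelConfig(architecture="toy_cnn",
                                        freezing="batch_norm"), init_seed=0)
img = make_image("pediatric", 1, 7, 1, 32, np.random.default_rng(5))
X, y = img.pixels[None], np.array([1.0])

_, delta = local_train(model, params, X, y, TrainConfig(), lr=0.01,
                       rng=np.random.default_rng(2))
result = run_attack(model, params, delta, y,
                    AttackConfig(max_iterations=5000, trials=3),
                    np.random.default_rng(7))
print([round(l, 4) for l in result.trial_finals])
print(round(psnr(img.pixels, rescale_unit(result.reconstructions[0])), 1))
```

prints

```
[0.0017, 0.0027, 0.0018]
24.1
```

— the best-by-loss trial reconstructs the training image at 24.1 dB PSNR
(the image is clearly recognizable; the same attack against an ε = 10
DP-trained update stays below 13 dB and shows no image content).

Run a full scenario from the shell:

```bash
fedleak run --scenario dp_attack --preset desk --seed 0 --out out/
fedleak report out/
```

Scenarios: `baseline_fl`, `freezing_sweep`, `attack_stage`,
`attack_batch_sweep`, `dp_sweep`, `dp_attack`, `subsampling`,
`layerwise_clipping`.  The `desk` preset runs each in minutes on one CPU;
`full` uses the complete study sizes and the 20 000-iteration attack.

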