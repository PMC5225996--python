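"""End-to-end fiber waviness analysis on synthetic micrographs.

Renders a small waviness-contrast condition set (treated fibers straighter
than control), traces every fiber from its ground-truth seed point,
averages hierarchically (fibers within image, then images within arm), and
evaluates the Waviness-% statistic. Ground truth: treated arc/chord 1.189,
control 1.300, i.e. Waviness-% = 63.
"""
from sclerashg import condition_waviness, generate_condition_set, waviness_percent
from sclerashg.pipeline import measure_condition_set
from sclerashg.synth import get_preset

cfg = get_preset("cfg-wav-40", n_rabbits=4, seed=7)
cset = generate_condition_set(cfg)
arm_means = measure_condition_set(cset)

treated = condition_waviness(arm_means["treated"], "treated")
control = condition_waviness(arm_means["control"], "control")
res = waviness_percent(treated, control)

print("per-image mean waviness (each the mean of 10 traced fibers):")
print("  treated:", " ".join(f"{m:.4f}" for m in treated.per_image_means))
print("  control:", " ".join(f"{m:.4f}" for m in control.per_image_means))
print(f"\narm means: treated {treated.condition_mean:.4f} ± {treated.condition_sd:.4f}, "
      f"control {control.condition_mean:.4f} ± {control.condition_sd:.4f}")
print(f"Waviness-% = {res.waviness_percent:.1f} (paired p = {res.p_value:.2e})")
print("values below 100% mean treatment straightened the fiber bundles;")
print("the generator's ground truth for this condition is 63%.")
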