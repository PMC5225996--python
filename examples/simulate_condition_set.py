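"""Generate a paired treated/control image set and check its ground truth.

Builds a small brightness-contrast condition (treated fibers brighter than
control, identical waviness), renders one image pair per animal, and
compares the realized treated-minus-control mean pixel density with the
analytic expectation stored in the config.
"""
from sclerashg import generate_condition_set, mean_pixel_density
from sclerashg.synth import make_intensity_preset

# 20-count brightness effect on 256x256 images, 8 animals
cfg = make_intensity_preset(
    "demo-int", 20.0, image_size=(256, 256), n_fibers=8,
    fiber_width=6.0, fiber_length=120.0, n_rabbits=8, seed=42,
)
print(f"condition '{cfg.name}': control peak {cfg.fiber_intensity_offset_control:.0f}, "
      f"treated peak {cfg.fiber_intensity_offset_treated:.0f} counts")
print(f"analytic expected mean difference: {cfg.analytic_mean_difference():.2f} counts\n")

cset = generate_condition_set(cfg)
for pair in cset:
    d = mean_pixel_density(pair.treated) - mean_pixel_density(pair.control)
    print(f"{pair.rabbit_id}: treated - control image mean = {d:+6.2f} counts")

diffs = [mean_pixel_density(p.treated) - mean_pixel_density(p.control) for p in cset]
mean = sum(diffs) / len(diffs)
se = (sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)) ** 0.5 / len(diffs) ** 0.5
print(f"\nmean over animals: {mean:+.2f} ± {se:.2f} (SE) counts — scatters around"
      " the analytic 20.00 through per-eye brightness variation")
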