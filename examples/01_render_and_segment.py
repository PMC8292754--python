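"""Render a synthetic fish photograph and segment it with the baseline.

Builds one synthetic photograph (dark spotted fish on a light background),
runs the hand-crafted body- and spot-segmentation pipeline, and scores the
predictions against the known ground-truth masks.
"""

from spotid import (BaselineConfig, SyntheticFishSpec, evaluate_segmentation,
                    extract_fish_mask_baseline, extract_spots_baseline,
                    render_fish_image)

spec = SyntheticFishSpec(n_spots=30, rng_seed=7)
image, body_truth, spot_truth = render_fish_image(spec)
print(f"rendered {image.shape[1]}x{image.shape[0]} image with "
      f"{int(spot_truth.sum())} spot pixels")

cfg = BaselineConfig.for_image_size(max(image.shape[:2]))
body_pred = extract_fish_mask_baseline(image, cfg)
spot_pred = extract_spots_baseline(image, body_pred, cfg)

bp, br, bf = evaluate_segmentation(body_pred, body_truth)
sp, sr, sf = evaluate_segmentation(spot_pred, spot_truth)
print(f"body mask:  precision={bp:.3f} recall={br:.3f} F1={bf:.3f}")
print(f"spot mask:  precision={sp:.3f} recall={sr:.3f} F1={sf:.3f}")
print("The body F1 near 0.9 and spot F1 near 0.5 are typical of the")
print("feature-engineered baseline: the heavy blur erodes the outline and")
print("only the cores of blurred spots survive adaptive thresholding.")
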