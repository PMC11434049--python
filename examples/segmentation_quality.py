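"""Segment a noisy phantom image and score it with mean IoU.

Renders the label volume as a two-material grayscale stack (air 60,
tissue 200) with Gaussian noise, thresholds it (Otsu), splits the air
into instances with a distance-transform watershed, and scores the
result against the noise-free reference labeling.
"""

from alveodyn import (
    PhantomSpec,
    generate_unit,
    miou,
    render_grayscale,
    segment_air,
    split_instances,
    voxelize,
)

spec = PhantomSpec(
    duct_radius=10.0,
    duct_length=40.0,
    n_alveoli=4,
    alveolar_radius=10.0,
    mouth_fraction=0.45,
    placement_seed=3,
    voxel_spacing=0.65,
)
exp, _, _ = generate_unit(spec)
reference = voxelize(exp, spec.voxel_spacing)

for noise_sd in (0.0, 10.0, 30.0):
    image = render_grayscale(reference, noise_sd, seed=11)
    air = segment_air(image)
    labels = split_instances(air, reference.spacing)
    agree = (air == reference.air_mask()).mean()
    score = miou(labels, reference)
    print(
        f"noise SD {noise_sd:>5.1f}: voxel agreement {agree:.4f}, "
        f"{len(labels.labels())} instances "
        f"(expected {spec.n_alveoli + 1}), mIoU {score:.4f}"
    )

print(
    "\nVoxel agreement is the fraction of correctly classified air/"
    "tissue voxels; mIoU averages per-instance overlap after optimal "
    "label matching (1.0 = perfect instance segmentation)."
)
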