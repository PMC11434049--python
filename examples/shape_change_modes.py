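"""The shape-change statistic q across the three deformation regimes.

For each mode the same duct-plus-alveoli unit is inflated to 1.5x its
volume, the full measurement chain runs on both states (voxelize →
threshold → watershed split → mesh morphometry), and the unit-level
q = k_insp/k_exp plus the mean change in inter-alveolar angle Δθ are
compared with the generator's ground truth.
"""

from alveodyn import PhantomSpec
from alveodyn.pipeline import run_pair

spec_base = dict(
    duct_radius=10.0,
    duct_length=40.0,
    n_alveoli=4,
    alveolar_radius=10.0,
    mouth_fraction=0.45,
    placement_seed=3,
    voxel_spacing=0.65,
)

print(f"{'mode':<20} {'q meas':>8} {'q true':>8} {'Δθ meas':>9} {'Δθ true':>9}")
for mode in ("duct_dominant", "alveolus_dominant", "isotropic"):
    res = run_pair(PhantomSpec(deformation_mode=mode, **spec_base), seed=0)
    dth = res.angle_pairs["dtheta_deg"].mean()
    dth_t = res.truth.pairs["dtheta_deg"].mean()
    print(f"{mode:<20} {res.q:>8.4f} {res.truth.q_true:>8.4f} "
          f"{dth:>8.2f}° {dth_t:>8.2f}°")

print(
    "\nq < 1 with Δθ > 0: the duct expands more than its alveoli "
    "(low-lung-volume behavior); q > 1 with Δθ < 0: the alveoli deepen "
    "more than the duct (mid-volume); q = 1 with Δθ = 0: balloon-like "
    "similarity (high volume)."
)
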