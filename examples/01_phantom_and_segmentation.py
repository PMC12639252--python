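"""Render a synthetic PET phantom and segment it with the adaptive rule.

Builds one patient volume containing two spherical lesions of known
volume, then runs the blood-pool-adaptive 42 %-of-SUVmax segmenter and
compares segmented volumes against the inserted truth.
"""

from petlesion import LesionSpec, PhantomSpec, generate_phantom, segment_volume

spec = PhantomSpec(
    lesions=(
        LesionSpec(center=(20, 20, 20), radius_mm=9.0, suv_max=9.0, site="liver"),
        LesionSpec(center=(44, 40, 40), radius_mm=7.0, suv_max=6.0, site="lung"),
    ),
    seed=1,
)
phantom = generate_phantom(spec)
print("inserted lesions (truth):")
print(phantom.truth.to_string(index=False))

segmented = segment_volume(phantom.volume, phantom.blood_pool_mask, phantom.site_map)
print("\nsegmented lesions (42 % of local SUVmax, min 0.5 cc):")
for lesion in segmented.lesions:
    print(
        f"  id={lesion.id} site={lesion.site:6s} volume={lesion.volume_cc:5.2f} cc "
        f"SUVmax={lesion.suv_max:4.2f} SUVpeak={lesion.suv_peak:4.2f}"
    )
print(
    "\nSegmented volumes track the inserted spheres; the PET-threshold contour"
    "\nof a blurred lesion is slightly larger or smaller than the crisp insert"
    "\ndepending on its contrast over the local background."
)
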