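"""Full stereological workup of one placenta-like phantom.

Builds the zoned ellipsoidal phantom (decidua / junctional zone /
labyrinthine zone with capillary and maternal-channel tubes), then runs the
two-magnification protocol: Cavalieri volume and zone fractions on SUR
sections, labyrinth vascular volumes/surfaces and membrane thickness on a
high-power midline window, closing with diffusion capacity and efficiency.
"""

import warnings

import numpy as np

from stereoplacenta import PipelineConfig, analyze_placenta, \
    make_placenta_phantom

cfg = PipelineConfig.from_dict({})
phantom, truth = make_placenta_phantom(seed=4)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = analyze_placenta(cfg, phantom, fetal_weight_mg=3630.0,
                           placental_weight_g=0.0045,
                           rng=np.random.default_rng(4))

print(f"total volume     : {res['volume_mm3']:.3f} mm³ "
      f"(truth {truth.total_volume_um3 / 1e9:.3f})")
for z in ("decidua", "junctional", "labyrinth"):
    print(f"  Vv {z:<11}: {res['vv_' + z]:.3f} "
          f"(truth {truth.volumes_um3[z] / truth.total_volume_um3:.3f})")
print(f"FC surface       : {res['fc_surface_cm2']:.3f} cm², "
      f"MBS surface: {res['mbs_surface_cm2']:.3f} cm²")
print(f"membrane tau_h   : {res['tau_h_um']:.1f} µm "
      f"from {res['n_intercepts']} intercepts")
print(f"Dvm              : {res['Dvm']:.3e} cm³ O₂/(min·kPa)")
print(f"SDC              : {res['SDC']:.3e} cm³ O₂/(min·kPa·mg)")
print(f"BW/PW efficiency : {res['bw_pw']:.2f}")
print("Zone fractions and total volume are recovered nearly unbiasedly; "
      "labyrinth vascular quantities carry the single-midline-window "
      "sampling bias shared by all groups (see docs/methods.md).")
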