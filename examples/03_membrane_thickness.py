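"""Harmonic-mean membrane thickness by orthogonal intercepts.

A spherical shell with a 5 µm membrane separating a 'capillary' core from a
surrounding 'blood space' is sectioned; intercepts are measured from the
capillary boundary through the membrane, corrected by 8/(3 pi) for the
plane of sectioning, and harmonically averaged.
"""

import warnings

import numpy as np

from stereoplacenta import harmonic_mean_thickness, make_shell_phantom, \
    orthogonal_intercepts, section_phantom

phantom, truth = make_shell_phantom(inner_radius=80.0, thickness=5.0)
rng = np.random.default_rng(2)
intercepts = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # sections through the cap carry no starts
    stack = section_phantom(phantom, t_sec=4.0, n_select=20, rng=rng,
                            pixel_size=0.5)
    for sec in stack:
        intercepts.extend(orthogonal_intercepts(sec, line_spacing=10.0,
                                                rng=rng))

est = harmonic_mean_thickness(intercepts)
literal = harmonic_mean_thickness(intercepts, correction=(8 / 3) * np.pi)
print(f"intercepts measured      : {est.n}")
print(f"raw intercept range      : {min(intercepts):.2f} - "
      f"{max(intercepts):.2f} µm (oblique sections inflate raw lengths)")
print(f"corrected harmonic mean  : {est.tau_h_um:.3f} µm "
      f"(true thickness {truth.tau_true_um} µm)")
print(f"with the literal (8/3)pi : {literal.tau_h_um:.2f} µm — a ~10x "
      "overestimate, which is why the correction is read as 8/(3 pi)")
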