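# Accommodation-dependent four-surface schematic eye.
#
# Values follow the published Navarro accommodation-dependent model at the
# 589.3 nm reference wavelength, with additive per-medium index offsets for
# 940 nm NIR illumination.  Lens radii, lens thickness, anterior-chamber
# depth and lens index vary with accommodation A [D] through the log-law
# terms below; the axial length is held constant (the vitreous chamber
# absorbs lens-thickness changes).
#
# Sign convention: radius > 0 means the centre of curvature lies toward the
# retina.  All lengths in mm.
schema: purkinjeye/eye-parameters/v1
axial_length_mm: 24.004
pupil_radius_mm: 2.5
rotation_center_z_mm: -13.5
surfaces:
  - name: cornea_anterior
    radius_mm: 7.72
    conic: -0.26
    aperture_radius_mm: 5.5
    thickness_mm: 0.55          # corneal thickness (A-independent)
    medium_after: cornea
  - name: cornea_posterior
    radius_mm: 6.5
    conic: 0.0
    aperture_radius_mm: 5.5
    thickness_mm: 3.05          # anterior-chamber depth at A = 0
    medium_after: aqueous
  - name: lens_anterior
    radius_mm: 10.2
    conic: -3.1316
    aperture_radius_mm: 4.5
    thickness_mm: 4.0           # lens thickness at A = 0
    medium_after: lens
  - name: lens_posterior
    radius_mm: -6.0
    conic: -1.0
    aperture_radius_mm: 4.5
    medium_after: vitreous
media:
  # n_ref at 589.3 nm; nir_offset added for 940 nm operation.
  cornea:   {n_ref: 1.367,  nir_offset: -0.006}
  aqueous:  {n_ref: 1.3374, nir_offset: -0.006}
  lens:     {n_ref: 1.42,   nir_offset: -0.007}
  vitreous: {n_ref: 1.336,  nir_offset: -0.006}
accommodation:
  # law: how the terms below scale with accommodation A [D]:
  #   linear -> coeff * A          (default; matches the Navarro log law at
  #                                 rest and at 4 D, linear in between, as
  #                                 in linear-in-A schematic eyes)
  #   log    -> coeff * ln(1 + A)  (Navarro's original dependence; set the
  #                                 coefficients to -1.75, 0.2294, -0.05,
  #                                 0.1, -0.34 to reproduce it exactly)
  law: linear
  coefficients:
    lens_anterior_radius: -0.7041291
    lens_posterior_radius: 0.0923013
    anterior_chamber_depth: -0.0201180
    lens_thickness: 0.0402359
    lens_anterior_conic: -0.1368022
  # n_lens increases by this coefficient times (10 A + A^2)
  lens_index_coeff: 9.0e-5
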