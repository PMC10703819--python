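# Default measurement scene.
#
# The NIR LED sits slightly above and temporal to the eye axis and the
# camera below it, with enough angular separation that P1, P3 and P4 stay
# distinct on the sensor without vignetting at a 2 mm pupil radius over
# A in [1, 4] D and rotations up to 7 deg.  The LED/camera heights are
# chosen so the camera's depth parallax cancels the baseline vertical
# P3-P4 offset: the vertical separation y_P4 - y_P3 then isolates the
# accommodation response, and the P3-P4 distance responds linearly to eye
# rotation.  These values are this package's own working layout; they are
# documented, user-editable, and make no claim to equal any physical rig.
#
# Scene frame: origin at the unrotated corneal apex, +z toward the scene,
# +x temporal-to-nasal, +y up.  Positions in mm.
schema: purkinjeye/scene/v1
led_position_mm: [-4.0, 7.0, 75.0]
camera_pinhole_mm: [-2.0, -14.0, 75.0]
camera_axis: [2.0, 14.0, -75.0]     # normalized on load; looks at the apex
focal_length_px: 1800.0
sensor_size_px: [400, 300]
pixel_pitch_mm: 0.006
target_array:
  # LED array on the nose-chin axis: fixed 31.5 mm lateral offset gives
  # vergence angles from ~1.8 deg (1 D) to ~7.2 deg (4 D).
  - {depth_D: 4.0, offset_m: 0.0315}
  - {depth_D: 3.5, offset_m: 0.0315}
  - {depth_D: 3.0, offset_m: 0.0315}
  - {depth_D: 2.5, offset_m: 0.0315}
  - {depth_D: 2.0, offset_m: 0.0315}
  - {depth_D: 1.5, offset_m: 0.0315}
  - {depth_D: 1.0, offset_m: 0.0315}
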