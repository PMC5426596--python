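# Default insole sensor layout, version 1.
#
# Planar sensor coordinates (arbitrary units) for the 8-sensor force
# insoles used in the public PhysioNet gait database, following the
# database's own documentation of the sensor grid.  The origin lies
# between the feet of a standing subject who faces the positive Y
# direction, so left-foot sensors have x <= 0, right-foot sensors
# x >= 0, heel sensors the smallest y and toe sensors the largest y.
#
# Override by passing your own layout file of the same shape.
version: 1
sensors:
  - {sensor_id: 1, foot: left,  x: -500, y: -800, role: heel}
  - {sensor_id: 2, foot: left,  x: -700, y: -400, role: midfoot}
  - {sensor_id: 3, foot: left,  x: -300, y: -400, role: midfoot}
  - {sensor_id: 4, foot: left,  x: -700, y: 0,    role: midfoot}
  - {sensor_id: 5, foot: left,  x: -300, y: 0,    role: midfoot}
  - {sensor_id: 6, foot: left,  x: -700, y: 400,  role: midfoot}
  - {sensor_id: 7, foot: left,  x: -300, y: 400,  role: midfoot}
  - {sensor_id: 8, foot: left,  x: -500, y: 800,  role: toe}
  - {sensor_id: 1, foot: right, x: 500,  y: -800, role: heel}
  - {sensor_id: 2, foot: right, x: 700,  y: -400, role: midfoot}
  - {sensor_id: 3, foot: right, x: 300,  y: -400, role: midfoot}
  - {sensor_id: 4, foot: right, x: 700,  y: 0,    role: midfoot}
  - {sensor_id: 5, foot: right, x: 300,  y: 0,    role: midfoot}
  - {sensor_id: 6, foot: right, x: 700,  y: 400,  role: midfoot}
  - {sensor_id: 7, foot: right, x: 300,  y: 400,  role: midfoot}
  - {sensor_id: 8, foot: right, x: 500,  y: 800,  role: toe}
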