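# Default scalable arm+hand model: a representative adult (1.8 m, 72.6 kg).
#
# Segment lengths are fractions of standing height; masses are fractions of
# total body mass; centre-of-mass (com) and radius-of-gyration fractions are
# relative to segment length, following standard anthropometric regression
# tables (Winter / de Leva style). Hand sub-segments (palm, thumb, fingers)
# subdivide the whole-hand mass so that static hand joints still carry
# non-trivial gravity-holding torques.
#
# Coordinate convention: right-handed thorax frame anchored at the right
# glenohumeral joint centre; x anterior, y leftward (medial for the right
# arm), z up; gravity (0, 0, -9.81) m/s^2. Every segment's long axis is its
# local +x; at the all-zero posture the whole limb points anteriorly (+x)
# with the palm facing medially (+y, thumb up).
#
# DOF ordering in this file is the layout of q and tau everywhere downstream.
# Exactly three DOFs are dynamic: shoulder flexion-extension, shoulder
# internal-external rotation, elbow flexion-extension. Shoulder
# flexion-extension is measured relative to the horizontal (0 deg = arm
# horizontal anterior, +45 deg = raised above horizontal).

subject:
  height: 1.8          # m
  mass: 72.6           # kg
gravity: [0.0, 0.0, -9.81]

# Medial distance from the reaching glenohumeral joint to the front of the
# contralateral shoulder, as a fraction of height (used by the workspace grid).
shoulder_separation_fraction: 0.17

endpoint:
  segment: index_distal
  # marker at the distal tip of the index distal phalanx, local frame,
  # fractions of height
  local_fraction: [0.0108, 0.0, 0.0]

segments:
  - name: upper_arm
    parent: root
    length_fraction: 0.186
    mass_fraction: 0.028
    com_fraction: 0.436
    gyration_fraction: 0.322
    dofs:
      - {name: shoulder_add,  axis: [1.0, 0.0, 0.0],  range_deg: [-60.0, 60.0],  dynamic: false}
      - {name: shoulder_fe,   axis: [0.0, -1.0, 0.0], range_deg: [-90.0, 90.0],  dynamic: true}
      - {name: shoulder_rot,  axis: [1.0, 0.0, 0.0],  range_deg: [-90.0, 90.0],  dynamic: true}
  - name: forearm
    parent: upper_arm
    length_fraction: 0.146
    mass_fraction: 0.016
    com_fraction: 0.430
    gyration_fraction: 0.303
    dofs:
      - {name: elbow_fe,      axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 150.0],   dynamic: true}
      - {name: forearm_ps,    axis: [1.0, 0.0, 0.0],  range_deg: [-80.0, 80.0],  dynamic: false}
  - name: palm
    parent: forearm
    length_fraction: 0.0486
    mass_fraction: 0.0038
    com_fraction: 0.55
    gyration_fraction: 0.35
    dofs:
      - {name: wrist_fe,      axis: [0.0, 0.0, 1.0],  range_deg: [-70.0, 70.0],  dynamic: false}
      - {name: wrist_dev,     axis: [0.0, 1.0, 0.0],  range_deg: [-25.0, 25.0],  dynamic: false}
  - name: thumb_metacarpal
    parent: palm
    origin_fraction: [0.0135, 0.011, 0.008]
    length_fraction: 0.027
    mass_fraction: 0.0002
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: thumb_cmc_abd, axis: [0.0, 1.0, 0.0],  range_deg: [0.0, 60.0],    dynamic: false}
      - {name: thumb_cmc_fe,  axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 50.0],    dynamic: false}
  - name: thumb_proximal
    parent: thumb_metacarpal
    length_fraction: 0.016
    mass_fraction: 0.0002
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: thumb_mcp_fe,  axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 55.0],    dynamic: false}
  - name: thumb_distal
    parent: thumb_proximal
    length_fraction: 0.013
    mass_fraction: 0.0002
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: thumb_ip_fe,   axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 80.0],    dynamic: false}
  - name: index_proximal
    parent: palm
    origin_fraction: [0.0486, 0.0, 0.0067]
    length_fraction: 0.0238
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: index_mcp_fe,  axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 90.0],    dynamic: false}
  - name: index_middle
    parent: index_proximal
    length_fraction: 0.0140
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: index_pip_fe,  axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 100.0],   dynamic: false}
  - name: index_distal
    parent: index_middle
    length_fraction: 0.0108
    mass_fraction: 0.0001
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: index_dip_fe,  axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 80.0],    dynamic: false}
  - name: middle_proximal
    parent: palm
    origin_fraction: [0.0486, 0.0, 0.0022]
    length_fraction: 0.0238
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: middle_mcp_fe, axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 90.0],    dynamic: false}
  - name: middle_middle
    parent: middle_proximal
    length_fraction: 0.0140
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: middle_pip_fe, axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 100.0],   dynamic: false}
  - name: middle_distal
    parent: middle_middle
    length_fraction: 0.0108
    mass_fraction: 0.0001
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: middle_dip_fe, axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 80.0],    dynamic: false}
  - name: ring_proximal
    parent: palm
    origin_fraction: [0.0486, 0.0, -0.0022]
    length_fraction: 0.0238
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: ring_mcp_fe,   axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 90.0],    dynamic: false}
  - name: ring_middle
    parent: ring_proximal
    length_fraction: 0.0140
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: ring_pip_fe,   axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 100.0],   dynamic: false}
  - name: ring_distal
    parent: ring_middle
    length_fraction: 0.0108
    mass_fraction: 0.0001
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: ring_dip_fe,   axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 80.0],    dynamic: false}
  - name: little_proximal
    parent: palm
    origin_fraction: [0.0486, 0.0, -0.0067]
    length_fraction: 0.0238
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: little_mcp_fe, axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 90.0],    dynamic: false}
  - name: little_middle
    parent: little_proximal
    length_fraction: 0.0140
    mass_fraction: 0.00015
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: little_pip_fe, axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 100.0],   dynamic: false}
  - name: little_distal
    parent: little_middle
    length_fraction: 0.0108
    mass_fraction: 0.0001
    com_fraction: 0.5
    gyration_fraction: 0.3
    dofs:
      - {name: little_dip_fe, axis: [0.0, 0.0, 1.0],  range_deg: [0.0, 80.0],    dynamic: false}
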