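name: alpha_lga
unit_cell:
- 7.068
- 10.277
- 8.755
- 90.0
- 90.0
- 90.0
miller_faces:
- - 1
  - 0
  - 0
- - -1
  - 0
  - 0
- - 0
  - 1
  - 1
- - 0
  - -1
  - -1
- - 0
  - 1
  - -1
- - 0
  - -1
  - 1
- - 1
  - 0
  - 1
- - 1
  - 0
  - -1
- - -1
  - 0
  - -1
- - -1
  - 0
  - 1
- - 1
  - 1
  - 1
- - 1
  - -1
  - -1
- - -1
  - 1
  - -1
- - -1
  - -1
  - 1
face_groups:
- - 0
  - 1
- - 2
  - 3
  - 4
  - 5
- - 6
  - 7
  - 8
  - 9
- - 10
  - 11
  - 12
  - 13
symmetry_ops:
- rotation:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  permutation:
  - 0
  - 1
  - 2
  - 3
  - 4
  - 5
  - 6
  - 7
  - 8
  - 9
  - 10
  - 11
  - 12
  - 13
- rotation:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - -1.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  permutation:
  - 0
  - 1
  - 3
  - 2
  - 5
  - 4
  - 7
  - 6
  - 9
  - 8
  - 11
  - 10
  - 13
  - 12
- rotation:
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  permutation:
  - 1
  - 0
  - 4
  - 5
  - 2
  - 3
  - 8
  - 9
  - 6
  - 7
  - 12
  - 13
  - 10
  - 11
- rotation:
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - -1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  permutation:
  - 1
  - 0
  - 5
  - 4
  - 3
  - 2
  - 9
  - 8
  - 7
  - 6
  - 13
  - 12
  - 11
  - 10
prior:
  mu:
  - 0.35
  - 0.6
  - 0.65
  - 0.7
  sigma:
  - 0.06
  - 0.09
  - 0.1
  - 0.1
  ordering:
  - - 0
    - 1
  - - 0
    - 2
  - - 0
    - 3
  zingg_bounds:
  - - 0.2
    - 1.0
  - - 0.2
    - 1.0
  area_range:
  - 0.05
  - 0.25
  eta_range:
  - 1.5
  - 1.8
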