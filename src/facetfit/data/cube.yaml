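name: cube
unit_cell:
- 1.0
- 1.0
- 1.0
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
  - 0
- - 0
  - -1
  - 0
- - 0
  - 0
  - 1
- - 0
  - 0
  - -1
face_groups:
- - 0
  - 1
  - 2
  - 3
  - 4
  - 5
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
- rotation:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  - - 0.0
    - -1.0
    - 0.0
  permutation:
  - 0
  - 1
  - 5
  - 4
  - 2
  - 3
- rotation:
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  - - 0.0
    - 1.0
    - 0.0
  permutation:
  - 0
  - 1
  - 4
  - 5
  - 3
  - 2
- rotation:
  - - 0.0
    - 1.0
    - 0.0
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  permutation:
  - 3
  - 2
  - 0
  - 1
  - 4
  - 5
- rotation:
  - - 0.0
    - -1.0
    - 0.0
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  permutation:
  - 2
  - 3
  - 1
  - 0
  - 4
  - 5
- rotation:
  - - 0.0
    - 0.0
    - 1.0
  - - 0.0
    - 1.0
    - 0.0
  - - -1.0
    - 0.0
    - 0.0
  permutation:
  - 5
  - 4
  - 2
  - 3
  - 0
  - 1
- rotation:
  - - 0.0
    - 0.0
    - -1.0
  - - 0.0
    - 1.0
    - 0.0
  - - 1.0
    - 0.0
    - 0.0
  permutation:
  - 4
  - 5
  - 2
  - 3
  - 1
  - 0
- rotation:
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  - - 1.0
    - 0.0
    - 0.0
  permutation:
  - 4
  - 5
  - 0
  - 1
  - 2
  - 3
- rotation:
  - - 0.0
    - 1.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  - - -1.0
    - 0.0
    - 0.0
  permutation:
  - 5
  - 4
  - 0
  - 1
  - 3
  - 2
- rotation:
  - - 0.0
    - -1.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  - - -1.0
    - 0.0
    - 0.0
  permutation:
  - 5
  - 4
  - 1
  - 0
  - 2
  - 3
- rotation:
  - - 0.0
    - -1.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  - - 1.0
    - 0.0
    - 0.0
  permutation:
  - 4
  - 5
  - 1
  - 0
  - 3
  - 2
- rotation:
  - - 0.0
    - 0.0
    - 1.0
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  permutation:
  - 2
  - 3
  - 4
  - 5
  - 0
  - 1
- rotation:
  - - 0.0
    - 0.0
    - 1.0
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - -1.0
    - 0.0
  permutation:
  - 3
  - 2
  - 5
  - 4
  - 0
  - 1
- rotation:
  - - 0.0
    - 0.0
    - -1.0
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - -1.0
    - 0.0
  permutation:
  - 2
  - 3
  - 5
  - 4
  - 1
  - 0
- rotation:
  - - 0.0
    - 0.0
    - -1.0
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - 1.0
    - 0.0
  permutation:
  - 3
  - 2
  - 4
  - 5
  - 1
  - 0
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
  - 2
  - 3
  - 5
  - 4
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
  - 3
  - 2
  - 4
  - 5
- rotation:
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 1.0
  - - 0.0
    - 1.0
    - 0.0
  permutation:
  - 1
  - 0
  - 4
  - 5
  - 2
  - 3
- rotation:
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  - - 0.0
    - -1.0
    - 0.0
  permutation:
  - 1
  - 0
  - 5
  - 4
  - 3
  - 2
- rotation:
  - - 0.0
    - 1.0
    - 0.0
  - - 1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  permutation:
  - 2
  - 3
  - 0
  - 1
  - 5
  - 4
- rotation:
  - - 0.0
    - -1.0
    - 0.0
  - - -1.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - -1.0
  permutation:
  - 3
  - 2
  - 1
  - 0
  - 5
  - 4
- rotation:
  - - 0.0
    - 0.0
    - 1.0
  - - 0.0
    - -1.0
    - 0.0
  - - 1.0
    - 0.0
    - 0.0
  permutation:
  - 4
  - 5
  - 3
  - 2
  - 0
  - 1
- rotation:
  - - 0.0
    - 0.0
    - -1.0
  - - 0.0
    - -1.0
    - 0.0
  - - -1.0
    - 0.0
    - 0.0
  permutation:
  - 5
  - 4
  - 3
  - 2
  - 1
  - 0
prior:
  mu:
  - 1.0
  sigma:
  - 0.15
  zingg_bounds:
  - - 0.5
    - 1.0
  - - 0.5
    - 1.0
  area_range:
  - 0.05
  - 0.25
  eta_range:
  - 1.4
  - 1.8
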