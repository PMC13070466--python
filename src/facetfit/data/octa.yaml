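name: octa
unit_cell:
- 1.0
- 1.0
- 1.0
- 90.0
- 90.0
- 90.0
miller_faces:
- - 1
  - 1
  - 1
- - 1
  - 1
  - -1
- - 1
  - -1
  - 1
- - 1
  - -1
  - -1
- - -1
  - 1
  - 1
- - -1
  - 1
  - -1
- - -1
  - -1
  - 1
- - -1
  - -1
  - -1
face_groups:
- - 0
  - 1
  - 2
  - 3
  - 4
  - 5
  - 6
  - 7
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
  - 1
  - 3
  - 0
  - 2
  - 5
  - 7
  - 4
  - 6
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
  - 2
  - 0
  - 3
  - 1
  - 6
  - 4
  - 7
  - 5
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
  - 2
  - 3
  - 6
  - 7
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
  - 4
  - 5
  - 0
  - 1
  - 6
  - 7
  - 2
  - 3
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
  - 1
  - 5
  - 3
  - 7
  - 0
  - 4
  - 2
  - 6
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
  - 0
  - 6
  - 2
  - 5
  - 1
  - 7
  - 3
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
  - 0
  - 2
  - 4
  - 6
  - 1
  - 3
  - 5
  - 7
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
  - 3
  - 1
  - 7
  - 5
  - 2
  - 0
  - 6
  - 4
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
  - 7
  - 1
  - 3
  - 4
  - 6
  - 0
  - 2
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
  - 6
  - 4
  - 2
  - 0
  - 7
  - 5
  - 3
  - 1
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
  - 0
  - 4
  - 1
  - 5
  - 2
  - 6
  - 3
  - 7
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
  - 7
  - 2
  - 6
  - 1
  - 5
  - 0
  - 4
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
  - 5
  - 1
  - 4
  - 0
  - 7
  - 3
  - 6
  - 2
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
  - 6
  - 2
  - 7
  - 3
  - 4
  - 0
  - 5
  - 1
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
  - 3
  - 2
  - 1
  - 0
  - 7
  - 6
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
  - 5
  - 4
  - 7
  - 6
  - 1
  - 0
  - 3
  - 2
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
  - 6
  - 7
  - 4
  - 5
  - 2
  - 3
  - 0
  - 1
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
  - 4
  - 6
  - 5
  - 7
  - 0
  - 2
  - 1
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
  - 7
  - 5
  - 6
  - 4
  - 3
  - 1
  - 2
  - 0
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
  - 1
  - 0
  - 5
  - 4
  - 3
  - 2
  - 7
  - 6
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
  - 7
  - 6
  - 3
  - 2
  - 5
  - 4
  - 1
  - 0
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
  - 2
  - 6
  - 0
  - 4
  - 3
  - 7
  - 1
  - 5
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
  - 7
  - 3
  - 5
  - 1
  - 6
  - 2
  - 4
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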