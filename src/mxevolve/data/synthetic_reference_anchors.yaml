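description: 'Canonical MXE cluster anchors as MSA column intervals on the package''s
  synthetic reference gene architecture. SYNTHETIC stand-in: the original canonical
  clusters are defined on a curated myosin alignment that is not packaged; these intervals
  refer to the reference architecture in mxevolve.synthetic_data.'
anchors:
- cluster_id: 0
  col_start: 19
  col_end: 37
  label: loop-1/switch-1 (ctenophore)
- cluster_id: 1
  col_start: 38
  col_end: 59
  label: SH3-motor junction
- cluster_id: 2
  col_start: 60
  col_end: 79
  label: P-loop/loop-1
- cluster_id: 3
  col_start: 79
  col_end: 103
  label: loop-1 to switch-1
- cluster_id: 4
  col_start: 104
  col_end: 121
  label: upper 50 kDa domain
- cluster_id: 5
  col_start: 122
  col_end: 141
  label: fiber-kinetics region
- cluster_id: 6
  col_start: 141
  col_end: 163
  label: loop-4
- cluster_id: 7
  col_start: 164
  col_end: 179
  label: relay helix/loop
- cluster_id: 8
  col_start: 180
  col_end: 199
  label: loop-2 C-terminus
- cluster_id: 9
  col_start: 199
  col_end: 217
  label: central beta-sheet strand
- cluster_id: 10
  col_start: 218
  col_end: 239
  label: converter
- cluster_id: 11
  col_start: 240
  col_end: 259
  label: coiled-coil hinge
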