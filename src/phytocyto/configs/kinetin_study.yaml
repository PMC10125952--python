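# Simulated control-vs-kinetin study.
#
# The phantom fields emulate the measured conditions of the BY-2
# kinetin experiment: a control nuclei population at subcultivation
# (60% 2C / 30% S / 10% 4C), a kinetin population shifted towards S/G2,
# an end-of-cycle AO/EB staging field, callose cross-wall fields at the
# control (mean 150, sd 30) and kinetin (mean 330, sd 50) scales, a
# calcium field with nuclear signal at twice the cytoplasmic level, and
# an Evans-Blue field with 60% stained cells.  The trait table plants a
# single-factor correlation structure in which calcium pools and dying
# stages load positively and callose, survival and the 2C fraction load
# negatively, plus control-vs-kinetin shifts in the planted directions
# (elevated calcium, more dying cells, fewer alive/2C cells).

seed: 42

fields:
  - name: control_nuclei
    kind: nuclei
    spec:
      n_cells: 30
      ploidy_mixture: [0.0, 0.60, 0.30, 0.10, 0.0]
      noise_sd: 1.0
  - name: kinetin_nuclei
    kind: nuclei
    spec:
      n_cells: 30
      ploidy_mixture: [0.05, 0.20, 0.40, 0.25, 0.10]
      noise_sd: 1.0
  - name: kinetin_aoeb
    kind: aoeb
    channel_map: {green: green, red: red}
    spec:
      n_cells: 24
      stage_mixture: [0.40, 0.45, 0.12, 0.03]
      noise_sd: 1.0
  - name: control_callose
    kind: signal
    signal_kind: callose
    region_params: {n_walls: 12, wall_mean: 150.0, wall_sd: 30.0}
    spec: {noise_sd: 2.0}
  - name: kinetin_callose
    kind: signal
    signal_kind: callose
    region_params: {n_walls: 12, wall_mean: 330.0, wall_sd: 50.0}
    spec: {noise_sd: 2.0}
  - name: kinetin_calcium
    kind: signal
    signal_kind: calcium
    region_params: {cyto_mean: 100.0, nuc_mean: 200.0}
    spec: {n_cells: 12, noise_sd: 2.0}
  - name: kinetin_evans_blue
    kind: signal
    signal_kind: evans_blue
    region_params: {stained_fraction: 0.60}
    spec: {n_cells: 40, noise_sd: 0.02}

segment:
  method: otsu
  min_area: 20
  exclude_border: true
  background: median_outside

cellcycle:
  cuts: [100, 400, 600]
  band_halfwidth: 0.25

stage:
  t_alive: 0.2
  t_dead: 1.5
  t_nco: 0.2

quantify:
  background: 0.0

traits:
  n_samples: 24
  corr:
    factor_loadings:
      cytosolic_ca: 0.85
      nuclear_ca: 0.70
      dying_I: 0.80
      dying_II: 0.70
      dead: 0.60
      callose: -0.80
      alive: -0.85
      lt2C: 0.30
      "2C": -0.70
      2_4C: 0.70
      "4C": 0.60
      gt4C: 0.40
  effects:
    cytosolic_ca: 2.0
    nuclear_ca: 1.0
    callose: 1.5
    alive: -2.0
    dying_I: 2.0
    dying_II: 1.0
    dead: 0.8
    lt2C: 0.5
    "2C": -1.5
    2_4C: 1.5
    "4C": 1.0
    gt4C: 0.5

network:
  alpha: 0.05
  window: [4.0, 7.0]
  model: linear
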