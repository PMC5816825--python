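# Perturbation scenario catalog for the synthetic gait generator.
#
# `effects` are phenomenological mean symmetry-index offsets in percent
# (left-minus-right convention; perturbations worn on the right leg carry
# negative offsets).  Magnitudes are generator defaults chosen to encode each
# perturbation's qualitative signature: leg-length increments load step-length
# asymmetry more than step-time, distal masses the reverse (with opposite
# signs on the shared parameters so combined conditions partially cancel),
# and the stroke-simulator knee orthosis adds large, highly variable
# step-length and hip-moment asymmetry.  AM/KM/HM offsets apply to
# matrix-level generation; at waveform level moments emerge from dynamics.
scenarios:
  baseline:
    description: unperturbed symmetric treadmill walking
    effects: {}

  leg-length-small:
    description: 27 mm leg length increment on the left leg
    side: left
    perturbation:
      leg_length_delta_mm: {left: 27.0}
    effects: {SL: 6.0, ST: -2.0, GRF: 1.0, PF: 2.0, BF: 2.0,
              KA: 3.0, AA: 2.0, HA: 3.0, AM: 1.5, KM: 1.5, HM: 4.0}

  leg-length-big:
    description: 52 mm leg length increment on the left leg
    side: left
    perturbation:
      leg_length_delta_mm: {left: 52.0}
    effects: {SL: 12.0, ST: -4.0, GRF: 2.0, PF: 4.0, BF: 4.0,
              KA: 5.0, AA: 4.0, HA: 6.0, AM: 3.0, KM: 3.0, HM: 8.0}

  mass-small:
    description: 2.3 kg mass at the left distal shank
    side: left
    perturbation:
      distal_mass_kg: {left: 2.3}
    effects: {SL: -1.5, ST: 6.0, GRF: 2.0, PF: 4.0, BF: 4.0,
              KA: 2.0, AA: 2.0, HA: 2.0, AM: 2.0, KM: 3.0, HM: 3.0}

  mass-big:
    description: 4.6 kg mass at the left distal shank
    side: left
    perturbation:
      distal_mass_kg: {left: 4.6}
    effects: {SL: -3.0, ST: 12.0, GRF: 4.0, PF: 7.0, BF: 7.0,
              KA: 4.0, AA: 3.0, HA: 4.0, AM: 4.0, KM: 5.0, HM: 6.0}

  leg-length-small-mass-small:
    description: 27 mm increment plus 2.3 kg distal mass, left leg
    side: left
    perturbation:
      leg_length_delta_mm: {left: 27.0}
      distal_mass_kg: {left: 2.3}
    effects: {SL: 4.5, ST: 4.0, GRF: 3.0, PF: 6.0, BF: 6.0,
              KA: 5.0, AA: 4.0, HA: 5.0, AM: 3.5, KM: 4.5, HM: 7.0}

  leg-length-small-mass-big:
    description: 27 mm increment plus 4.6 kg distal mass, left leg
    side: left
    perturbation:
      leg_length_delta_mm: {left: 27.0}
      distal_mass_kg: {left: 4.6}
    effects: {SL: 3.0, ST: 10.0, GRF: 5.0, PF: 9.0, BF: 9.0,
              KA: 7.0, AA: 5.0, HA: 7.0, AM: 5.5, KM: 6.5, HM: 10.0}

  leg-length-big-mass-small:
    description: 52 mm increment plus 2.3 kg distal mass, left leg
    side: left
    perturbation:
      leg_length_delta_mm: {left: 52.0}
      distal_mass_kg: {left: 2.3}
    effects: {SL: 10.5, ST: 2.0, GRF: 4.0, PF: 8.0, BF: 8.0,
              KA: 7.0, AA: 6.0, HA: 8.0, AM: 5.0, KM: 6.0, HM: 11.0}

  leg-length-big-mass-big:
    description: 52 mm increment plus 4.6 kg distal mass, left leg
    side: left
    perturbation:
      leg_length_delta_mm: {left: 52.0}
      distal_mass_kg: {left: 4.6}
    effects: {SL: 9.0, ST: 8.0, GRF: 6.0, PF: 11.0, BF: 11.0,
              KA: 9.0, AA: 7.0, HA: 10.0, AM: 7.0, KM: 8.0, HM: 14.0}

  stroke-simulator:
    description: variable stiffness/damping knee orthosis on the right leg
    side: right
    noise_scale: 1.8
    perturbation:
      knee_damping: true
      knee_damper_gcms_per_deg: 8898.0
      knee_spring_kg_per_mm: 0.457
    effects: {SL: -10.0, ST: -5.0, GRF: -3.0, PF: -5.0, BF: -5.0,
              KA: -8.0, AA: -3.0, HA: -4.0, AM: -3.0, KM: -6.0, HM: -9.0}

  after-stroke-simulator:
    description: residual after-effects once the orthosis is removed
    side: right
    noise_scale: 1.3
    effects: {SL: -5.0, ST: -2.5, GRF: -1.5, PF: -2.5, BF: -2.5,
              KA: -4.0, AA: -1.5, HA: -2.0, AM: -1.5, KM: -3.0, HM: -4.5}
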