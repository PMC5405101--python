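# Advanced-stage NSCLC planning wishlist: 6 hard constraints, 13 prioritized
# objectives.  Structure names refer to the derived planning structures of
# prioplan.structures.  Cord and plexus hard limits carry the
# fractionation-dependent clinical tolerances; the effective limit is the
# minimum of the wishlist value and the tolerance for the prescribed
# fractionation.  The priority-2 PTV objective is conditional: when the
# expanded spinal cord is close to or overlaps the PTV, it is applied to the
# cord-subtracted target instead, locating the acceptable underdosage next to
# the cord.
name: nsclc-advanced-stage
constraints:
- volume: patient
  metric: max
  limit: {percent_of_prescription: 107}
- volume: ctv
  metric: max
  limit: {percent_of_prescription: 107}
- volume: ptv_minus_cord5
  metric: max
  limit: {percent_of_prescription: 107}
- volume: cord_plus_3mm
  metric: max
  limit: 47.0
  fractionation_tolerance_gy: {"2.0": 50.0, "2.75": 49.3, "3.0": 46.3}
- volume: plexus
  metric: max
  limit: 63.0
  fractionation_tolerance_gy: {"2.0": 66.0, "2.75": 60.0, "3.0": 56.6}
- volume: lungs_minus_gtv
  metric: mean
  limit: 19.0
objectives:
- {priority: 1, volume: ctv, cost: ltcp, goal: 1.0, alpha: 0.8}
- {priority: 2, volume: ptv, cost: ltcp, goal: 0.5, alpha: 0.8, cord_conditional: true}
- priority: 3
  volume: patient_minus_ptv4
  cost: max
  goal: {percent_of_prescription: 60}
- {priority: 4, volume: lungs_minus_gtv, cost: mean, goal: 15.0}
- priority: 5
  volume: shell_ptv_1cm
  cost: max
  goal: {percent_of_prescription: 90}
- priority: 6
  volume: shell_ptv_3cm
  cost: max
  goal: {percent_of_prescription: 80}
- {priority: 7, volume: esophagus, cost: eud, goal: 44.0, k: 8}
- {priority: 8, volume: esophagus, cost: mean, goal: 15.0}
- {priority: 9, volume: lungs_minus_gtv, cost: mean, goal: 5.0}
- {priority: 10, volume: heart, cost: mean, goal: 15.0}
- {priority: 11, volume: cord_plus_3mm, cost: max, goal: 42.0}
- {priority: 12, volume: unspecified_tissue, cost: max, goal: 40.0}
- {priority: 13, volume: plexus, cost: mean, goal: 20.0}
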