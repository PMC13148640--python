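"""Quadrupedal versus bipedal stance inference.

Runs the three quantitative stance lines of evidence: stylopodial-
circumference allometric mass, the 22-test LDA battery on a labelled
morphometric dataset, and the static-bipedalism COM criterion.
"""

from paleolimb import stance, synthetic

mass = stance.campione_evans_mass(14.0, 13.0)
print(f"allometric body mass from humeral 14 mm + femoral 13 mm "
      f"circumferences: {mass:.2f} kg")
print(f"  ratio to a 1.2602 kg volumetric model estimate: "
      f"{100 * mass / 1.2602:.0f}%  (modest discordance between methods)\n")

dataset = synthetic.make_toy_morphometrics(seed=0)
verdict = stance.lda_stance_tests(dataset, "Focalus", seed=0)
print(f"LDA battery ({verdict.n_tests} tests on body mass, dimensionless "
      f"COM, fore- and hindlimb lengths): {verdict.summary()}")
print(verdict.per_test[["test", "p_quadrupedal", "call"]].head(6)
      .to_string(index=False))
print("...\n")

check = stance.static_bipedalism_check(com_offset_m=0.053, femur_length_m=0.080)
print(f"static criterion: COM {check.percent:.0f}% of femur length cranial "
      f"to the hips -> {check.verdict}")
print("(the COM must sit less than one femur length cranial to the hips for "
      "the knee to be positioned under it)")
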