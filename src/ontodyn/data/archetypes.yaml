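# Default temporal archetype configuration for the 12-age liver design
# (days -2, 0, 1, 3, 5, 10, 15, 20, 25, 30, 45, 60).
#
# Three orthogonal base profiles (zero mean, unit SD across ages) carry the
# early / mid / late expression programmes.  They were obtained by sketching
# qualitative early-, mid- and late-development curves, orthogonalizing them,
# and rotating the resulting basis to its varimax-optimal orientation, so the
# basis is a fixed point of the rotation used downstream.  The six archetype
# groups are the signed versions of the three bases: a gene following +base
# belongs to the first label of the pair, -base to the second.
ages: [-2, 0, 1, 3, 5, 10, 15, 20, 25, 30, 45, 60]
bases:
  early: [2.0181907172, 1.4545093406, 0.9224892905, 0.0955038765,
          -0.4523468368, -1.2067358707, -1.1692465025, -0.8703377556,
          -0.2524225837, -0.1299518575, -0.1799757690, -0.2296760489]
  mid:   [-0.0558475202, -0.2969610238, 0.3590905286, 1.6463615553,
          1.8538305797, 0.4258842453, -0.1906994215, -0.6969226070,
          -1.4174814342, -1.3049011842, -0.4485212096, 0.1261674916]
  late:  [-0.3665598734, -0.6466767658, -0.4291051974, 0.0549896846,
          0.0237170226, -0.8575494871, -0.9910441824, -0.8025000680,
          -0.1644461919, 0.3150971086, 1.5407070232, 2.3233709269]
labels:
  early: {pos: "Prenatal and Neonatal", neg: "Adolescent and Adult"}
  mid:   {pos: "Neonatal and Adolescent", neg: "Prenatal and Adult"}
  late:  {pos: "Adult", neg: "Neonatal"}
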