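# Reference weighted-local-alignment parameterization (miRanda-3.3a style).
# Scores are per aligned column; the seed window is given in 1-based miRNA
# positions counted from the miRNA 5' end, and substitution scores at those
# positions are multiplied by seed_scale.  Gap penalties are affine and are
# not scaled.  Units are dimensionless alignment score points.
match_score: 5.0
mismatch_score: -3.0
gu_wobble_score: 2.0
gap_open: -9.0
gap_extend: -4.0
seed_scale: 4.0
seed_window: [2, 8]
score_threshold: 140.0
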