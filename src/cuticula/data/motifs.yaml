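# Family-defining sequence diagnostics for insect cuticular proteins.
# Notation: uppercase letter = fixed residue; x or X = any single residue;
# x(m-n) / X5 / X_4-5_ = bounded run of wildcards; [AVL] or A/V = alternatives;
# '-' and '_' are separators.
motifs:
  rr1_consensus:
    kind: consensus
    pattern: "GxFxYxxPDGxxxxVxYxADENGYQPxGAHLP"
  rr2_consensus:
    kind: consensus
    pattern: "EYDAxPxYxFxYxDxHTGDxKSQxExRDGDVVxGxYSLxExDGxxRTVxYTADxxNGFNAVVxxE"
  # one substituted cysteine is tolerated per ChtBD2 spacing instance, so a
  # single point substitution does not erase a domain
  cpap1_spacing:
    kind: spacing
    pattern: "Cx(14-16)Cx(5)Cx(9-13)Cx(12)Cx(7-8)C"
    max_mismatches: 1
  cpap3_spacing:
    kind: spacing
    pattern: "Cx(13-24)Cx(5)Cx(9-10)Cx(12-16)Cx(7-8)C"
    max_mismatches: 1
  cpcfc_repeat:
    kind: spacing
    pattern: "C-X5-C"
  tweedle_block_1:
    kind: consensus
    pattern: "KX_2_Y/F"
  tweedle_block_2:
    kind: consensus
    pattern: "KX_4-5_FIKAP"
  tweedle_block_3:
    kind: consensus
    pattern: "TX_2_YVL"
  tweedle_block_4:
    kind: consensus
    pattern: "KPEVYXFV/IKY"
  cpg_repeat:
    kind: repeat
    pattern: "GGxGG"
  cph_repeat:
    kind: repeat
    pattern: "AAP[AVL]"
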