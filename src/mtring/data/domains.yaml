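# Tubulin domain map: secondary-structure nomenclature (T1-T7 nucleotide-
# binding loops, H1-H12 helices, S1-S10 strands, M-loop) mapped to inclusive
# residue-number ranges.  Ranges follow the standard tubulin numbering and are
# editable data, not code: adjust them to the template in use.  Residues not
# covered aggregate under the reserved "unassigned" domain.
ranges:
  alpha: &tubulin_ranges
    N-terminal loop: [[1, 37]]
    H1'-S2 loop: [[38, 61]]
    T2 loop: [[62, 70]]
    H2 helix: [[71, 84]]
    H2'' helix: [[85, 94]]
    T3 loop: [[95, 107]]
    H3 helix: [[108, 130]]
    H3-S4 loop: [[131, 140]]
    S5 strand: [[160, 170]]
    T5 loop: [[171, 180]]
    H6 helix: [[205, 216]]
    H6-H7 loop: [[217, 230]]
    H7 helix: [[231, 243]]
    T7 loop: [[244, 251]]
    H8 helix: [[252, 260]]
    H8-S7 loop: [[261, 270]]
    M-loop: [[271, 288]]
    H9 helix: [[289, 300]]
    S8 strand: [[301, 310]]
    H10 helix: [[320, 335]]
    H10-S9 loop: [[336, 350]]
    S9 strand: [[351, 359]]
    S10 strand: [[365, 375]]
    H11 helix: [[380, 396]]
    H11-H11' loop: [[397, 402]]
    H11' helix: [[403, 410]]
    H12 helix: [[418, 430]]
    C-terminal: [[431, 451]]
  beta: *tubulin_ranges
special_res_names:
  GTP: cofactor
  GDP: cofactor
  MG: Mg2+
  HOH: coordinating water
  WAT: coordinating water
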