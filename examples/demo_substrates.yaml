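# Substrate definitions for the demo experiment.  Positions are 1-based along
# the labeled strand counted from the labeled end; every probed position must
# be a thymine there.  The R-loop flank (rlf) lists the flank thymines with
# their strand assignment; the reference thymine (position 10) normalizes out
# permanganate-preparation activity across replicate sets.
substrates:
  - substrate_id: rloop3_nts
    strands:
      NTS: GCTTTTTCATGCGCA
      TS: TGCGCATGAAAAAGC
    labeled_strand: NTS
    label_end: five_prime
    quench_time: {value: 2, unit: min}
    probed_thymines: [3, 4, 5, 6, 7, 10]
    reference_thymine: 10
    rlf:
      - {label: T1, strand: NTS, position: 3}
      - {label: T2, strand: NTS, position: 4}
      - {label: T3, strand: NTS, position: 5}
      - {label: T4, strand: NTS, position: 6}
      - {label: T5, strand: NTS, position: 7}
  - substrate_id: bubble_ctrl
    strands:
      NTS: GCTTTTTCATGCGCA
      TS: TGCGCATGAAAAAGC
    labeled_strand: NTS
    label_end: five_prime
    quench_time: {value: 2, unit: min}
    probed_thymines: [3, 4, 5, 6, 7, 10]
    reference_thymine: 10
    rlf:
      - {label: T1, strand: NTS, position: 3}
      - {label: T2, strand: NTS, position: 4}
      - {label: T3, strand: NTS, position: 5}
      - {label: T4, strand: NTS, position: 6}
      - {label: T5, strand: NTS, position: 7}
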