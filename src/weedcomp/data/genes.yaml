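# Gene screen configuration for the two target-site-resistance loci.
#
# numbering_offset maps a local (1-based) codon index in the analysed in-frame
# region to the standard amino-acid numbering used in the resistance
# literature: position_standard = codon_index_local + numbering_offset.
# The synthetic reference CDS for each gene (weedcomp.simulate.reference_cds)
# is built to these dimensions; real amplicons supply their own offsets.
ALS:
  amplicon_bp: 1919
  cds_codons: 626   # in-frame region fits inside the product with both primers
  numbering_offset: 0          # local codon 197 is the canonical Pro197
  canonical:
    197: P
  known_resistance_positions:
    197: [A, T, S, Q, L, R]    # Pro197 substitutions reported to confer ALS-inhibitor resistance
ACCase:
  amplicon_bp: 2879
  cds_codons: 550              # carboxyl-transferase (CT) domain region
  ct_domain_span_bp: [1117, 2765]   # metadata: CT-domain span within the PCR product
  numbering_offset: 1550       # local codon 449 is the canonical Trp1999
  canonical:
    449: W
  known_resistance_positions:
    1999: [L, C, S]            # Trp1999 substitutions (W1999L best documented)
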