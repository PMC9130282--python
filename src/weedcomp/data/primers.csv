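gene,primer_fwd,primer_rev,amplicon_bp,annealing_c
ALS,TACCCAAACCTACTCTCCCG,TGATCAGGCACATTGCACC,1919,61.6
ACCase,AGGACACGCAGAGGAACCT,GCAGCTGCCTCAGAAGCCAA,2879,60.6
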