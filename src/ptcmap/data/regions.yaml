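# Study regions of the E. coli 23S rRNA active site, 1-based inclusive
# intervals in E. coli 23S numbering. reference_bases gives the wild-type
# identity of each interval 5'->3'. Identities follow the nucleotide names
# used for these positions in the mutational and structural literature
# (e.g. G2057, A2451, U2585, G2553); positions not individually named there
# carry the standard E. coli 23S (rrnB) identity. Override this file for
# other organisms or numbering conventions.
PTC-ring:
  ranges:
    - [2057, 2063]
    - [2447, 2456]
    - [2496, 2507]
    - [2582, 2588]
    - [2602, 2602]
    - [2606, 2611]
  reference_bases:
    - GAAAGAC
    - GAUAACACGC
    - CACAUCGAUGUC
    - GGUUUAG
    - A
    - CGGUCC
A-loop:
  ranges:
    - [2548, 2560]
  reference_bases:
    - UCGCUGUUCGCCA
P-loop:
  ranges:
    - [2250, 2254]
  reference_bases:
    - GGGGC
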