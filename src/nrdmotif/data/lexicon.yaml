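# Apical-loop motif lexicon, v1.
#
# Maps apical-loop motif patterns of class II ribonucleotide reductases
# (NrdJ) to predicted phosphate specificity: NDP = ribonucleoside
# diphosphate reducer, NTP = triphosphate reducer.  Patterns are Python
# regular expressions anchored to the whole motif and matched
# case-insensitively, first match wins.  Anything unmatched is UNKNOWN.
#
# The NDP pattern tolerates phenylalanine at position 1; the canonical
# NTP pattern tolerates serine or glycine at position 2 (the
# L. leichmannii loop P-S-G-R is the archetype).  P-S-M-R and P-[QA]-G-S-P
# are minor triphosphate-specific variants; engineered inactive loops
# such as P-A-G-S match nothing and fall to UNKNOWN.
version: 1
patterns:
  - id: PNSP
    regex: "[PF]NSP"
    label: NDP
  - id: PAGR
    regex: "P[ASG]GR"
    label: NTP
  - id: PSMR
    regex: "PSMR"
    label: NTP
  - id: PQGSP
    regex: "P[QA]GSP"
    label: NTP
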