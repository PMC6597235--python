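# Combinatorial library configuration (editable).
#
# The published scaffold and the nine R1 substituents exist only as drawings
# with no machine-readable structures, so the scaffold and R1 fragments below
# are SYNTHETIC placeholders: a quinoxaline sulfonamide core echoing the
# parent dual inhibitor, and nine aryl/heteroaryl R1 groups of the kind used
# in known PI3K/mTOR inhibitors. Replace them with the real structures if you
# have them. The five R2 groups are exactly the published small substituents:
# -O-CH3, -OH, -NH2, -F, -Br.
#
# The scaffold must carry exactly one [*:1] (R1) and one [*:2] (R2) marker;
# each fragment exactly one [*] attachment point.
scaffold: "[*:1]Nc1nc2ccccc2nc1NS(=O)(=O)c1ccc(cc1)[*:2]"
r1:
  - "[*]c1ccccc1"
  - "[*]c1ccncc1"
  - "[*]c1cccnc1"
  - "[*]c1ccc(F)cc1"
  - "[*]c1ccc(OC)cc1"
  - "[*]c1ccc(C)cc1"
  - "[*]c1ccco1"
  - "[*]c1cccs1"
  - "[*]c1ccc2ncccc2c1"
r2:
  - "[*]OC"
  - "[*]O"
  - "[*]N"
  - "[*]F"
  - "[*]Br"
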