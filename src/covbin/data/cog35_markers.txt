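# Synthetic placeholder identifiers for the 35-member single-copy
# marker set (conserved single-copy COGs). The canonical identifier lists are
# distributed with curated marker databases; edit or replace this
# file to use your own set. One marker ID per line.
SCCOG_001
SCCOG_002
SCCOG_003
SCCOG_004
SCCOG_005
SCCOG_006
SCCOG_007
SCCOG_008
SCCOG_009
SCCOG_010
SCCOG_011
SCCOG_012
SCCOG_013
SCCOG_014
SCCOG_015
SCCOG_016
SCCOG_017
SCCOG_018
SCCOG_019
SCCOG_020
SCCOG_021
SCCOG_022
SCCOG_023
SCCOG_024
SCCOG_025
SCCOG_026
SCCOG_027
SCCOG_028
SCCOG_029
SCCOG_030
SCCOG_031
SCCOG_032
SCCOG_033
SCCOG_034
SCCOG_035
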