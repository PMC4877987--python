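# Synthetic placeholder identifiers for the 107-member single-copy
# marker set (essential single-copy genes, ESCG). The canonical identifier lists are
# distributed with curated marker databases; edit or replace this
# file to use your own set. One marker ID per line.
ESCG_001
ESCG_002
ESCG_003
ESCG_004
ESCG_005
ESCG_006
ESCG_007
ESCG_008
ESCG_009
ESCG_010
ESCG_011
ESCG_012
ESCG_013
ESCG_014
ESCG_015
ESCG_016
ESCG_017
ESCG_018
ESCG_019
ESCG_020
ESCG_021
ESCG_022
ESCG_023
ESCG_024
ESCG_025
ESCG_026
ESCG_027
ESCG_028
ESCG_029
ESCG_030
ESCG_031
ESCG_032
ESCG_033
ESCG_034
ESCG_035
ESCG_036
ESCG_037
ESCG_038
ESCG_039
ESCG_040
ESCG_041
ESCG_042
ESCG_043
ESCG_044
ESCG_045
ESCG_046
ESCG_047
ESCG_048
ESCG_049
ESCG_050
ESCG_051
ESCG_052
ESCG_053
ESCG_054
ESCG_055
ESCG_056
ESCG_057
ESCG_058
ESCG_059
ESCG_060
ESCG_061
ESCG_062
ESCG_063
ESCG_064
ESCG_065
ESCG_066
ESCG_067
ESCG_068
ESCG_069
ESCG_070
ESCG_071
ESCG_072
ESCG_073
ESCG_074
ESCG_075
ESCG_076
ESCG_077
ESCG_078
ESCG_079
ESCG_080
ESCG_081
ESCG_082
ESCG_083
ESCG_084
ESCG_085
ESCG_086
ESCG_087
ESCG_088
ESCG_089
ESCG_090
ESCG_091
ESCG_092
ESCG_093
ESCG_094
ESCG_095
ESCG_096
ESCG_097
ESCG_098
ESCG_099
ESCG_100
ESCG_101
ESCG_102
ESCG_103
ESCG_104
ESCG_105
ESCG_106
ESCG_107
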