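image_id,group,detected_nuclei,nuclei_with_2_cep17,her2_signals,cep17_signals,method_ratio,expert_ratio,expert_status
168136732,non_amplified,156,75,294,155,1.90,1.7,Neg
168136787,non_amplified,165,60,217,126,1.72,1.7,Neg
168138679,non_amplified,66,57,460,287,1.60,1.2,Neg
168138726,non_amplified,36,33,219,150,1.46,1.2,Neg
169282562,non_amplified,60,44,239,235,1.02,1.5,Neg
169282603,non_amplified,204,140,895,815,1.10,1.5,Neg
169282812,non_amplified,55,46,361,258,1.40,1.2,Neg
169282871,non_amplified,29,24,254,170,1.49,1.2,Neg
169283911,non_amplified,30,14,57,41,1.39,0.6,Neg
169284039,non_amplified,39,23,75,29,2.59,0.6,Neg
169284198,non_amplified,100,62,289,212,1.36,1.3,Neg
169284222,non_amplified,78,50,191,150,1.27,1.3,Neg
168136732,non_amplified,156,75,294,158,1.86,1.7,Neg
168136787,non_amplified,165,60,228,126,1.81,1.7,Neg
169285625,non_amplified,127,110,886,569,1.56,1.4,Neg
169285655,non_amplified,118,103,920,601,1.53,1.4,Neg
169285908,non_amplified,165,124,1225,940,1.30,1.0,Neg
429477261,non_amplified,32,10,48,51,0.94,1.3,Neg
429478407,non_amplified,73,41,303,257,1.18,1.3,Neg
429488234,non_amplified,191,157,1227,970,1.26,1.5,Neg
429493014,non_amplified,114,81,347,270,1.29,1.2,Neg
429493059,non_amplified,125,83,368,361,1.02,1.20,Neg
168138203,amplified,34,26,64,54,1.19,5,Pos
168138327,amplified,34,17,44,16,2.75,5,Pos
169283028,amplified,543,168,1690,183,9.23,2.4,Pos
169283283,amplified,36,36,356,105,3.39,4.4,Pos
169283307,amplified,28,26,268,81,3.31,4.4,Pos
169284611,amplified,174,106,370,136,2.72,2.4,Pos
169284650,amplified,93,57,219,75,2.92,2.4,Pos
429489018,amplified,204,41,284,98,2.90,2.8,Pos
429489055,amplified,77,23,66,27,2.44,2.8,Pos
430537413,amplified,122,104,592,168,3.52,2.7,Pos
430537468,amplified,76,72,358,151,2.37,2.70,Pos
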