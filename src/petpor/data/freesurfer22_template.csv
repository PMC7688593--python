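# TEMPLATE (synthetic): FreeSurfer aparc+aseg (Desikan-Killiany) labels merged
# into 22 analysis regions plus the cerebellar-GM reference. The exact
# membership used in published amyloid analyses is study-specific; edit this
# table to match your protocol before running on real data.
source_label,region_id,region_name
1003,1,frontal
1012,1,frontal
1014,1,frontal
1018,1,frontal
1019,1,frontal
1020,1,frontal
1027,1,frontal
1028,1,frontal
1032,1,frontal
2003,1,frontal
2012,1,frontal
2014,1,frontal
2018,1,frontal
2019,1,frontal
2020,1,frontal
2027,1,frontal
2028,1,frontal
2032,1,frontal
1008,2,parietal
1029,2,parietal
1031,2,parietal
2008,2,parietal
2029,2,parietal
2031,2,parietal
1025,3,precuneus
2025,3,precuneus
1005,4,occipital
1011,4,occipital
1013,4,occipital
1021,4,occipital
2005,4,occipital
2011,4,occipital
2013,4,occipital
2021,4,occipital
1009,5,lateral_temporal
1015,5,lateral_temporal
1030,5,lateral_temporal
1034,5,lateral_temporal
2009,5,lateral_temporal
2015,5,lateral_temporal
2030,5,lateral_temporal
2034,5,lateral_temporal
1006,6,medial_temporal
1016,6,medial_temporal
1033,6,medial_temporal
2006,6,medial_temporal
2016,6,medial_temporal
2033,6,medial_temporal
1022,7,sensory_motor
1024,7,sensory_motor
1017,7,sensory_motor
2022,7,sensory_motor
2024,7,sensory_motor
2017,7,sensory_motor
1002,8,anterior_cingulate
1026,8,anterior_cingulate
2002,8,anterior_cingulate
2026,8,anterior_cingulate
1010,9,posterior_cingulate
1023,9,posterior_cingulate
2010,9,posterior_cingulate
2023,9,posterior_cingulate
1035,10,insula
2035,10,insula
17,11,hippocampus
53,11,hippocampus
18,12,amygdala
54,12,amygdala
10,13,thalamus
49,13,thalamus
11,14,caudate
50,14,caudate
12,15,putamen
51,15,putamen
13,16,pallidum
52,16,pallidum
26,17,accumbens
58,17,accumbens
28,18,ventral_dc
60,18,ventral_dc
16,19,brainstem
2,20,cerebral_white_matter
41,20,cerebral_white_matter
1007,21,fusiform
2007,21,fusiform
1001,21,fusiform
2001,21,fusiform
7,22,cerebellar_white_matter
46,22,cerebellar_white_matter
8,23,cerebellar_gm
47,23,cerebellar_gm
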