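# phantom-native merge table: collapses the 8 phantom labels into 4 analysis
# regions (cortex, white matter incl. deep nuclei, cerebellar GM reference,
# cerebellar WM)
source_label,region_id,region_name
1,1,white_matter
2,2,cortex
3,2,cortex
4,2,cortex
5,2,cortex
6,1,white_matter
7,3,cerebellar_gm
8,4,cerebellar_wm
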