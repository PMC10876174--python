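table,row,col,count
wc_by_mwc,benign,favorable,30
wc_by_mwc,benign,unfavorable,1
wc_by_mwc,indeterminate,favorable,7
wc_by_mwc,indeterminate,unfavorable,2
wc_by_mwc,malignant,favorable,8
wc_by_mwc,malignant,unfavorable,11
wc_by_ara,benign,benign,23
wc_by_ara,benign,malignant,8
wc_by_ara,indeterminate,benign,1
wc_by_ara,indeterminate,malignant,8
wc_by_ara,malignant,benign,1
wc_by_ara,malignant,malignant,18
wc_by_pra,benign,benign,25
wc_by_pra,benign,malignant,6
wc_by_pra,indeterminate,benign,3
wc_by_pra,indeterminate,malignant,6
wc_by_pra,malignant,benign,1
wc_by_pra,malignant,malignant,18
reticulin_by_mwc,intact,favorable,11
reticulin_by_mwc,intact,unfavorable,0
reticulin_by_mwc,quantitative,favorable,20
reticulin_by_mwc,quantitative,unfavorable,12
reticulin_by_mwc,qualitative,favorable,12
reticulin_by_mwc,qualitative,unfavorable,2
reticulin_by_mwc,both,favorable,2
reticulin_by_mwc,both,unfavorable,0
reticulin_by_ara,intact,benign,11
reticulin_by_ara,intact,malignant,0
reticulin_by_ara,quantitative,benign,4
reticulin_by_ara,quantitative,malignant,28
reticulin_by_ara,qualitative,benign,10
reticulin_by_ara,qualitative,malignant,4
reticulin_by_ara,both,benign,0
reticulin_by_ara,both,malignant,2
reticulin_by_pra,intact,benign,11
reticulin_by_pra,intact,malignant,0
reticulin_by_pra,quantitative,benign,5
reticulin_by_pra,quantitative,malignant,27
reticulin_by_pra,qualitative,benign,13
reticulin_by_pra,qualitative,malignant,1
reticulin_by_pra,both,benign,0
reticulin_by_pra,both,malignant,2
outcome_by_mwc,CR,favorable,35
outcome_by_mwc,CR,unfavorable,4
outcome_by_mwc,AWD,favorable,5
outcome_by_mwc,AWD,unfavorable,4
outcome_by_mwc,DOD,favorable,5
outcome_by_mwc,DOD,unfavorable,6
outcome_by_ara,CR,benign,24
outcome_by_ara,CR,malignant,15
outcome_by_ara,AWD,benign,1
outcome_by_ara,AWD,malignant,8
outcome_by_ara,DOD,benign,0
outcome_by_ara,DOD,malignant,11
outcome_by_pra,CR,benign,28
outcome_by_pra,CR,malignant,11
outcome_by_pra,AWD,benign,1
outcome_by_pra,AWD,malignant,8
outcome_by_pra,DOD,benign,0
outcome_by_pra,DOD,malignant,11
stage_by_mwc,I,favorable,29
stage_by_mwc,I,unfavorable,1
stage_by_mwc,II,favorable,11
stage_by_mwc,II,unfavorable,4
stage_by_mwc,III,favorable,4
stage_by_mwc,III,unfavorable,3
stage_by_mwc,IV,favorable,0
stage_by_mwc,IV,unfavorable,6
stage_by_mwc,NA,favorable,1
stage_by_mwc,NA,unfavorable,0
stage_by_ara,I,benign,18
stage_by_ara,I,malignant,12
stage_by_ara,II,benign,4
stage_by_ara,II,malignant,11
stage_by_ara,III,benign,2
stage_by_ara,III,malignant,5
stage_by_ara,IV,benign,0
stage_by_ara,IV,malignant,6
stage_by_ara,NA,benign,1
stage_by_ara,NA,malignant,0
stage_by_pra,I,benign,20
stage_by_pra,I,malignant,10
stage_by_pra,II,benign,5
stage_by_pra,II,malignant,10
stage_by_pra,III,benign,3
stage_by_pra,III,malignant,4
stage_by_pra,IV,benign,0
stage_by_pra,IV,malignant,6
stage_by_pra,NA,benign,1
stage_by_pra,NA,malignant,0
sex_by_mwc,M,favorable,17
sex_by_mwc,M,unfavorable,6
sex_by_mwc,F,favorable,28
sex_by_mwc,F,unfavorable,8
sex_by_ara,M,benign,9
sex_by_ara,M,malignant,14
sex_by_ara,F,benign,16
sex_by_ara,F,malignant,20
sex_by_pra,M,benign,10
sex_by_pra,M,malignant,13
sex_by_pra,F,benign,19
sex_by_pra,F,malignant,17
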