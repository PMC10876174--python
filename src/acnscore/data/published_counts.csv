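statistic,count,denominator,printed_percent
location_right,37,85,44
location_left,48,85,56
vascular_invasion,28,92,
capsular_invasion,17,87,
high_mitotic_count_50hpf,55,88,63
high_mitotic_count_20hpf,22,92,
atypical_mitoses,31,87,
necrosis,43,92,
ki67_gt15,15,77,
wc_benign_of_91,52,91,57
wc_indeterminate_of_91,17,91,19
wc_malignant_of_91,22,91,24
mwc_favorable_of_60,46,60,
mwc_unfavorable_of_60,14,60,
ara_benign_of_85,39,85,
ara_malignant_of_85,46,85,
pra_benign_of_85,47,85,
pra_malignant_of_85,38,85,
reticulin_intact,25,92,27
reticulin_altered,67,92,73
reticulin_qualitative_of_altered,15,67,22
reticulin_quantitative_of_altered,49,67,73
reticulin_both_of_altered,3,67,5
outcome_cr,39,59,
outcome_awd,9,59,
outcome_dod,11,59,
wc_benign_of_59,31,59,53
wc_indeterminate_of_59,9,59,15
wc_malignant_of_59,19,59,32
mwc_favorable_of_59,45,59,76
mwc_unfavorable_of_59,14,59,24
ara_benign_of_59,25,59,42
ara_malignant_of_59,34,59,58
pra_benign_of_59,29,59,49
pra_malignant_of_59,30,59,51
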