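# Three-subject thermal-comfort study: tabulated summary numbers.
# table=adjacent_diff rows: per-subject sweat-rate differences (g/m2h)
#   between consecutive thermal statuses (key: lower status code).
# table=status_summary rows: across-subject mean / sd (g/m2h) of the
#   subject-level mean sweat rate at each thermal status.
table,subject,status,quantity,value
adjacent_diff,S1,0,diff_gm2h,35.01
adjacent_diff,S1,1,diff_gm2h,4.76
adjacent_diff,S1,2,diff_gm2h,43.44
adjacent_diff,S2,0,diff_gm2h,2.46
adjacent_diff,S2,1,diff_gm2h,19.21
adjacent_diff,S2,2,diff_gm2h,78.60
adjacent_diff,S3,0,diff_gm2h,0.45
adjacent_diff,S3,1,diff_gm2h,50.74
adjacent_diff,S3,2,diff_gm2h,53.84
status_summary,,0,mean_gm2h,13.40
status_summary,,0,sd_gm2h,2.48
status_summary,,1,mean_gm2h,26.04
status_summary,,1,sd_gm2h,17.33
status_summary,,2,mean_gm2h,50.95
status_summary,,2,sd_gm2h,16.17
status_summary,,3,mean_gm2h,109.57
status_summary,,3,sd_gm2h,13.80
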