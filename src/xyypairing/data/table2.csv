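y1,y2,rdna_size_pct,n_vials,n_flies,mean_flies_per_vial,sd_flies_per_vial,statistic,pct_female,pct_aneuploid,X,12,X1,2,X2,1
B,10B,100,32,3360,105,44,pooled,49.2,41.8,15.8,8.4,16.8,23.4,16.5,19.1
B,10B,100,32,3360,105,44,vial_mean,49.3,42.8,15.2,8.7,17.8,22.4,16.2,19.6
B,10B,100,32,3360,105,44,vial_sd,6.3,10.3,7.9,4.9,6.8,8.8,6.0,7.7
B,465,83,5,522,131,12,pooled,51.4,39.5,20.4,8.5,14.7,28.0,16.3,12.1
B,465,83,5,522,131,12,vial_mean,50.7,39.8,20.0,9.1,14.3,27.8,16.4,12.5
B,465,83,5,522,131,12,vial_sd,8.2,18.0,15.2,4.8,8.3,9.8,6.0,6.6
B,183,76,4,626,125,37,pooled,50.6,42.9,16.3,8.6,14.9,21.1,19.3,19.7
B,183,76,4,626,125,37,vial_mean,50.5,43.2,16.0,8.7,15.0,21.1,19.5,19.8
B,183,76,4,626,125,37,vial_sd,4.7,7.1,5.1,3.1,5.0,3.9,2.4,2.9
B,484,55,5,847,169,58,pooled,53.5,46.9,14.8,8.1,17.2,18.4,21.5,20.0
B,484,55,5,847,169,58,vial_mean,54.3,46.9,15.9,8.5,17.0,18.0,21.4,19.2
B,484,55,5,847,169,58,vial_sd,5.5,2.4,7.3,1.7,3.1,2.1,2.0,5.0
B,503,52,15,1219,81,31,pooled,52.1,41.5,19.0,8.4,14.4,17.6,18.6,21.8
B,503,52,15,1219,81,31,vial_mean,52.4,43.2,18.1,8.9,15.7,17.5,18.6,21.3
B,503,52,15,1219,81,31,vial_sd,4.8,8.7,7.0,3.6,6.7,5.0,5.6,5.9
B,473,46,25,2738,110,53,pooled,49.7,40.8,16.7,7.8,16.7,24.4,16.3,18.0
B,473,46,25,2738,110,53,vial_mean,49.4,40.7,16.7,8.0,16.0,24.2,16.6,18.4
B,473,46,25,2738,110,53,vial_sd,5.7,10.5,10.1,3.5,5.6,6.1,5.1,6.7
ROMA,10B,100,9,1349,150,78,pooled,50.9,47.1,12.9,9.0,22.4,22.4,15.6,17.6
ROMA,10B,100,9,1349,150,78,vial_mean,52.0,48.3,12.4,8.7,25.1,22.2,14.5,17.1
ROMA,10B,100,9,1349,150,78,vial_sd,5.0,9.6,5.6,3.0,7.4,2.0,5.1,5.6
ROMA,465,83,5,978,196,76,pooled,48.1,44.6,12.0,8.5,18.8,23.8,17.3,19.6
ROMA,465,83,5,978,196,76,vial_mean,47.2,44.0,11.9,8.7,18.5,24.1,16.8,20.0
ROMA,465,83,5,978,196,76,vial_sd,3.8,4.5,0.7,1.7,2.5,2.4,2.7,2.4
ROMA,183,76,5,950,190,36,pooled,49.2,45.3,14.5,10.6,18.2,23.4,16.4,16.8
ROMA,183,76,5,950,190,36,vial_mean,48.7,45.2,14.2,10.7,18.3,23.4,16.2,17.3
ROMA,183,76,5,950,190,36,vial_sd,4.8,2.7,3.3,1.6,1.4,3.4,1.8,4.9
ROMA,484,55,5,1026,205,68,pooled,44.0,44.3,10.6,11.0,18.3,25.6,15.0,19.4
ROMA,484,55,5,1026,205,68,vial_mean,43.7,44.1,10.6,11.0,18.1,25.6,15.0,19.7
ROMA,484,55,5,1026,205,68,vial_sd,2.6,1.5,0.7,1.7,1.5,2.1,0.8,1.7
ROMA,473,46,10,1404,140,63,pooled,48.0,46.9,11.8,10.6,19.9,23.7,16.3,17.7
ROMA,473,46,10,1404,140,63,vial_mean,47.7,47.6,11.2,11.1,20.0,24.1,16.6,17.1
ROMA,473,46,10,1404,140,63,vial_sd,3.3,3.4,2.5,2.5,3.5,4.0,2.4,2.8
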