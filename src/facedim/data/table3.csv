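variable,feature_key,weight,kind,n1,loc1,spread1,n2,loc2,spread2,stat_name,stat,df,p,d,d_lo,d_hi,flags
facial_area,facial_area,,mean_sd,25,26865,4053,60,26029,3273,t,0.91,37.7,0.36,0.24,-0.24,0.71,
masculinity_score,masculinity_score,,median_iqr,25,5.17,3.27,60,3.67,2.63,W,459,,0.005,0.63,0.15,1.10,sig_prior;sig_current
alar_base_width_linear,linear_alar_base_width,,mean_sd,25,14.0,1.75,60,12.7,1.57,t,3.30,40.8,0.002,0.82,0.33,1.31,sig_prior;sig_current
nose_height_linear,linear_nose_height,,mean_sd,25,37.6,3.56,60,35.6,3.85,t,2.24,48.4,0.03,0.54,0.04,1.00,sig_prior;sig_current
upper_lip_height_linear,linear_upper_lip_height,,median_iqr,25,21.6,2.17,60,21.0,2.21,W,560,,0.07,0.41,-0.06,0.88,sig_prior
outer_canthal_width_geodesic,geodesic_outer_canthal_width,,mean_sd,25,95.4,6.59,60,93.6,7.59,t,1.12,51.5,0.27,0.25,-0.72,0.22,sig_prior;printed_ci_inconsistent
forehead_height_geodesic,geodesic_forehead_height,,mean_sd,25,53.8,7.86,60,55.8,6.57,t,1.10,38.7,0.28,0.28,-0.19,0.76,female_larger
forehead_width_geodesic,geodesic_forehead_width,,mean_sd,25,143.5,9.01,60,137.2,9.81,t,2.86,48.7,0.006,0.66,0.17,1.14,sig_current
nose_height_geodesic,geodesic_nose_height,,mean_sd,25,45.2,3.82,60,44.1,4.66,t,1.14,54.5,0.26,-0.25,-0.73,0.22,sig_prior;sign_typo
upper_lip_height_geodesic,geodesic_upper_lip_height,,median_iqr,25,25.1,4.40,60,22.8,2.47,W,351,,0.0001,0.93,0.44,1.41,sig_current
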