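variable,feature_key,weight,kind,n1,loc1,spread1,n2,loc2,spread2,stat_name,stat,df,p,d,d_lo,d_hi,flags
facial_area,facial_area,,mean_sd,30,27446,4331,69,26578,3720,t,0.95,48.5,0.34,0.22,-0.66,0.21,printed_ci_inconsistent
masculinity_score,masculinity_score,,mean_sd,30,14.0,2.81,69,11.6,3.19,t,3.89,62.3,0.0002,0.81,0.36,1.26,sig_prior;sig_current
alar_base_width_linear,linear_alar_base_width,,median_iqr,30,15.6,2.07,69,14.2,2.06,W,570,,0.0004,0.77,0.33,1.21,sig_prior;sig_current
nose_height_linear,linear_nose_height,,mean_sd,30,38.0,3.60,69,36.9,4.68,t,1.22,71.0,0.23,0.24,-0.20,0.68,sig_prior
upper_lip_height_linear,linear_upper_lip_height,,mean_sd,30,24.2,2.64,69,21.2,2.28,t,5.32,48.8,<0.001,1.23,0.76,1.70,sig_prior;sig_current
outer_canthal_width_geodesic,geodesic_outer_canthal_width,,mean_sd,30,100.7,7.19,69,95.0,8.03,t,3.50,61.3,0.0009,0.73,0.29,1.18,sig_prior;sig_current
forehead_height_geodesic,geodesic_forehead_height,,mean_sd,30,51.6,9.03,69,57.0,8.59,t,2.82,52.8,0.007,0.63,0.19,1.07,sig_current;female_larger
forehead_width_geodesic,geodesic_forehead_width,,mean_sd,30,147.9,10.9,69,142.7,12.1,t,2.10,61.1,0.04,0.44,0.002,0.88,sig_current
nose_height_geodesic,geodesic_nose_height,,mean_sd,30,49.3,4.68,69,43.9,5.78,t,4.83,67.6,<0.001,0.97,0.52,1.43,sig_prior;sig_current
upper_lip_height_geodesic,geodesic_upper_lip_height,,mean_sd,30,26.7,3.21,69,23.5,3.28,t,4.41,56.3,<0.001,0.96,0.50,1.41,sig_current
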