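variable,feature_key,weight,kind,n1,loc1,spread1,n2,loc2,spread2,stat_name,stat,df,p,d,d_lo,d_hi,flags
facial_area,facial_area,,median_iqr,40,28373,5580,40,26674,4903,W,961,,0.12,0.35,-0.09,0.79,
alar_base_width_linear,linear_alar_base_width,0.38,mean_sd,40,15.0,1.52,40,13.9,1.73,t,2.88,76.6,0.005,0.64,0.19,1.10,sig_prior;sig_current
nose_height_linear,linear_nose_height,1.54,mean_sd,40,38.7,3.28,40,37.9,4.00,t,0.96,75.1,0.34,0.21,-0.23,0.66,sig_prior
upper_lip_height_linear,linear_upper_lip_height,0.92,mean_sd,40,22.8,2.41,40,20.4,2.35,t,4.37,78.0,<0.001,0.98,0.51,1.45,sig_prior;sig_current
outer_canthal_width_geodesic,geodesic_outer_canthal_width,0.39,mean_sd,40,100.6,8.07,40,94.6,7.11,t,3.52,76.8,0.0007,0.79,0.33,1.25,sig_prior;sig_current
forehead_height_geodesic,geodesic_forehead_height,1.55,mean_sd,40,50.4,6.71,40,57.6,5.39,t,5.24,74.5,<0.001,1.17,0.69,1.65,sig_prior;sig_current;female_larger
forehead_width_geodesic,geodesic_forehead_width,0.52,mean_sd,40,147.6,9.38,40,141.6,12.1,t,2.51,73.5,0.01,0.56,0.11,1.01,sig_current
right_upper_cheek_height_geodesic,geodesic_right_upper_cheek_height,1.13,mean_sd,40,66.4,5.10,40,65.2,4.14,t,1.17,74.8,0.25,0.26,-0.19,0.71,
nasal_tip_protrusion_geodesic,geodesic_nasal_tip_protrusion,1.31,median_iqr,40,14.8,2.35,40,14.3,2.72,W,954,,0.14,0.38,-0.12,0.76,
nose_height_geodesic,geodesic_nose_height,5.42,mean_sd,40,49.4,3.93,40,45.7,4.92,t,3.66,74.3,0.0005,0.82,0.35,1.28,sig_prior;sig_current
upper_lip_height_geodesic,geodesic_upper_lip_height,0.54,mean_sd,40,25.5,3.33,40,22.4,3.34,t,4.05,78.0,0.0001,0.90,0.44,1.37,sig_current
nasal_bridge_length_geodesic,geodesic_nasal_bridge_length,3.59,mean_sd,40,33.6,3.28,40,32.5,4.33,t,1.24,72.6,0.22,0.28,-0.17,0.73,
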