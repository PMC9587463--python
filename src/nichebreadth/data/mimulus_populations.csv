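species,pair,n_families,n_individuals,pop_tbreadth,pop_tbreadth_lo,pop_tbreadth_hi,family_tbreadth,family_tbreadth_lo,family_tbreadth_hi,var_topt,var_topt_lo,var_topt_hi,var_tbreadth,var_tbreadth_lo,var_tbreadth_hi,bayesian_p
M. cardinalis,a,22,691,34.74,33.61,35.00,29.97,28.48,31.36,6.18,3.37,9.91,6.72,3.12,11.82,0.67
M. parishii,a,50,1327,34.80,33.78,35.00,26.81,25.61,28.02,11.52,8.18,15.36,11.19,7.68,15.32,0.41
M. verbenaceus,b,24,762,34.35,32.78,35.00,29.57,27.96,30.96,6.58,3.72,10.28,6.70,3.52,10.89,0.44
M. eastwoodiae,b,42,1311,33.63,32.24,35.00,26.89,25.77,28.00,8.12,5.68,10.94,7.95,5.27,10.96,0.63
M. floribundus,c,18,242,30.98,28.57,33.49,21.31,19.91,22.77,11.98,7.01,18.21,6.96,3.32,11.57,0.54
M. norrisii,c,18,268,29.42,27.14,31.92,21.09,19.70,22.45,9.77,5.60,14.79,9.95,5.58,15.25,0.71
M. bicolor,d,23,326,30.23,27.16,32.96,18.12,16.88,19.37,12.14,7.71,17.22,5.66,2.85,9.36,0.62
M. filicaulis,d,13,179,25.42,22.16,28.90,17.76,16.19,19.35,6.00,2.22,11.57,5.53,2.10,10.50,0.52
M. guttatus,e,11,175,20.44,16.65,25.59,13.55,11.64,15.43,3.96,1.28,8.75,3.92,1.02,9.69,0.51
M. laciniatus,e,14,170,22.83,18.90,27.65,14.20,12.84,15.68,5.70,2.37,11.09,4.74,1.87,8.98,0.43
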