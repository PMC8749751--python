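dataset,model,l_inf,l_inf_lo,l_inf_hi,k,k_lo,k_hi,t0,t0_lo,t0_hi,l0,log_likelihood,aic,delta_aic,akaike_weight
unadjusted,VBG3,82.09,80.59,83.69,0.165,0.17,0.173,-1.988,-2.008,-1.968,23.01,3507.23,-7008.45,0.0,1.0
unadjusted,VBG2,69.35,67.25,71.65,0.314,0.294,0.334,,,,14.5,2158.51,-4313.03,2695.43,0.0
unadjusted,GG3,73.49,72.89,74.14,0.301,0.292,0.31,0.46,0.437,0.477,23.32,3486.66,-6967.31,41.14,0.0
unadjusted,LG3,69.79,69.44,70.14,0.444,0.435,0.453,1.5,1.475,1.525,23.69,3439.89,-6873.77,134.68,0.0
adjusted_rc,VBG3,81.5,80.0,83.1,0.17,0.165,0.175,-1.363,-1.383,-1.343,16.89,3413.1,-6820.2,0.0,1.0
adjusted_rc,VBG2,75.52,74.02,77.12,0.215,0.206,0.224,,,,14.5,3352.04,-6700.08,120.11,0.0
adjusted_rc,GG3,73.16,72.51,73.81,0.308,0.299,0.317,1.02,0.999,1.039,18.6,3395.95,-6785.9,34.3,0.0
adjusted_rc,LG3,69.53,69.39,70.19,0.454,0.434,0.455,2.04,2.017,2.067,19.71,3354.06,-6702.12,118.08,0.0
adjusted_dc,VBG3,81.87,80.37,83.47,0.168,0.163,0.173,-1.384,-1.404,-1.364,16.96,3454.0,-6902.0,0.0,1.0
adjusted_dc,VBG2,75.59,74.09,77.19,0.213,0.204,0.222,,,,14.5,3386.07,-6768.15,133.85,0.0
adjusted_dc,GG3,73.36,72.71,74.01,0.305,0.296,0.314,1.03,1.011,1.051,18.65,3436.19,-6866.39,35.61,0.0
adjusted_dc,LG3,69.7,69.35,70.05,0.449,0.439,0.46,2.063,2.04,2.09,19.77,3392.8,-6779.6,122.4,0.0
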