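database,drug,event,a,ror,ror_low,ror_high,signal,prr,chi2,ic,ic025,ebgm,eb05,ror_decimals,prr_decimals,chi2_decimals
FAERS,BEVACIZUMAB,VTE,284,2.26,1.87,2.73,Yes,2.23,76.45,0.57,0.34,1.48,1.23,2,2,2
FAERS,TEMOZOLOMIDE,VTE,202,0.99,0.82,1.19,No,0.99,0.02,-0.01,-0.26,0.99,0.83,2,2,2
FAERS,LOMUSTINE,VTE,47,1.43,1.06,1.95,Yes,1.43,5.47,0.47,0.01,1.38,1.02,2,2,2
FAERS,CARMUSTINE,VTE,17,1.43,0.88,2.33,No,1.42,2.09,0.49,-0.24,1.41,0.86,2,2,2
CVARD,BEVACIZUMAB,VTE,110,1.46,1.03,2.07,Yes,1.45,4.57,0.18,-0.31,1.13,0.79,2,2,2
CVARD,TEMOZOLOMIDE,VTE,21,0.62,0.39,0.98,No,0.62,4.18,-0.56,-1.21,0.68,0.43,2,2,2
CVARD,LOMUSTINE,VTE,9,1.16,0.59,2.29,No,1.16,0.19,0.2,-0.78,1.15,0.58,2,2,2
FAERS,BEVACIZUMAB,CNS_BLEED,174,1.53,1.23,1.89,Yes,1.52,15.14,0.32,0.05,1.25,1.01,2,2,2
FAERS,BEVACIZUMAB,GI_BLEED,90,2.3,1.64,3.21,Yes,2.29,25.17,0.58,0.18,1.49,1.07,1,2,2
FAERS,TEMOZOLOMIDE,CNS_BLEED,130,0.81,0.65,1.0,No,0.81,3.69,-0.18,-0.48,0.88,0.71,2,2,2
FAERS,TEMOZOLOMIDE,GI_BLEED,76,1.4,1.01,1.94,No,1.4,4.11,0.25,-0.17,1.19,0.86,1,1,2
FAERS,LOMUSTINE,CNS_BLEED,9,0.35,0.18,0.67,No,0.35,10.79,-1.45,-2.29,0.37,0.19,2,2,2
FAERS,LOMUSTINE,GI_BLEED,5,0.45,0.18,1.1,No,0.45,3.26,-1.09,-2.17,0.47,0.19,2,2,2
FAERS,CARMUSTINE,CNS_BLEED,15,1.76,1.04,2.97,Yes,1.75,4.63,0.78,-0.03,1.71,1.02,2,2,2
FAERS,CARMUSTINE,GI_BLEED,1,0.26,0.04,1.85,No,0.26,2.12,-1.92,-3.33,0.26,0.04,2,2,2
CVARD,BEVACIZUMAB,CNS_BLEED,26,1.57,0.65,3.82,No,1.57,1.0,0.15,-0.65,1.11,0.45,2,2,1
CVARD,BEVACIZUMAB,GI_BLEED,31,3.7,1.44,9.53,Yes,3.69,8.47,0.46,-0.29,1.37,0.53,1,2,2
CVARD,TEMOZOLOMIDE,CNS_BLEED,6,0.74,0.31,1.78,No,0.74,0.46,-0.35,-1.53,0.78,0.33,2,2,2
CVARD,TEMOZOLOMIDE,GI_BLEED,17,3.33,1.73,6.42,Yes,3.31,14.55,1.15,0.19,2.22,1.15,2,2,2
CVARD,LOMUSTINE,GI_BLEED,2,1.04,0.25,4.33,No,1.04,0.0,0.05,-1.73,1.04,0.25,2,2,1
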