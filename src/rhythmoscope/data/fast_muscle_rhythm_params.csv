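gene,amplitude,p_value,mesor,acrophase,zt_h,rhythmic
arntl1,0.36,0.21,0.54,2.75,10.52,True
arntl2,0.53,0.07,0.62,1.77,6.77,True
cry1,0.44,0.17,0.52,1.66,6.33,True
cry2,0.12,0.46,0.27,2.89,11.05,False
cry3,0.15,0.49,0.48,2.39,9.14,False
npas2,0.11,0.45,0.30,2.16,8.26,False
nr1d1,0.33,0.17,0.28,1.32,5.05,True
nr1d2,0.20,0.10,0.46,5.37,20.51,True
per1,0.31,0.13,0.66,2.11,8.07,True
per2,0.39,0.06,0.34,1.26,4.83,True
per3,0.25,0.16,0.27,1.36,5.21,True
rora,0.16,0.20,0.28,2.86,10.91,True
tim,0.02,0.98,0.40,4.27,16.33,False
clock,0.25,0.10,0.23,1.41,5.40,True
crydash,0.12,0.49,0.61,2.13,8.09,False
foxk2,0.07,0.89,0.31,3.82,14.57,False
mbnl1,1.30,0.07,1.02,1.63,6.22,True
mrf4,0.26,0.04,0.55,2.82,10.77,True
mstn,0.22,0.21,0.27,0.88,3.35,True
murf1,0.04,0.91,0.30,3.52,13.46,False
myf5,0.20,0.26,0.30,0.70,2.66,True
myod,0.37,0.04,0.51,1.21,4.63,True
myog,0.30,0.01,0.29,1.47,5.61,True
pdk4,0.17,0.48,0.39,1.09,4.18,False
pcna,0.29,0.05,0.32,6.00,22.91,True
ucp3,0.05,0.91,0.28,3.38,12.92,False
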