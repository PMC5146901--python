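gene,amplitude,p_value,mesor,acrophase,zt_h,rhythmic
arntl1,0.16,0.18,0.24,0.06,0.22,True
arntl2,0.18,0.29,0.33,5.49,20.96,True
cry1,0.49,0.01,0.42,5.53,21.12,True
cry2,0.13,0.64,0.42,6.19,23.65,False
cry3,0.18,0.084,0.27,5.41,20.66,True
npas2,0.24,0.25,0.34,0.71,2.69,True
nr1d1,0.21,0.04,0.48,1.19,4.56,True
nr1d2,0.19,0.37,0.40,4.99,19.08,False
per1,0.20,0.03,0.40,5.37,20.53,True
per2,0.38,0.05,0.48,5.39,20.60,True
per3,0.19,0.38,0.40,5.10,19.50,False
rora,0.25,0.04,0.42,5.69,21.75,True
tim,0.21,0.21,0.60,0.04,0.16,True
clock,0.18,0.01,0.34,6.01,22.94,True
crydash,0.12,0.41,0.33,3.93,15.03,False
foxk2,0.14,0.29,0.23,5.58,21.32,True
mbnl1,0.19,0.31,0.31,5.44,20.77,False
mrf4,0.09,0.29,0.40,0.70,2.67,True
mstn,0.23,0.28,0.34,0.87,3.32,True
murf1,0.27,0.31,0.35,5.33,20.34,False
myf5,0.19,0.09,0.31,5.56,21.23,True
myod,0.13,0.42,0.45,5.73,21.90,False
myog,0.16,0.32,0.45,0.74,2.81,False
pdk4,0.16,0.34,0.31,5.96,22.78,False
pcna,0.26,0.02,0.35,5.25,20.05,True
ucp3,0.05,0.95,0.39,1.16,4.45,False
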