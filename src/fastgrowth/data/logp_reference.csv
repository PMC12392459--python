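name,exp,am1bcc,am1bcc_ci,resp_hf,resp_hf_ci,resp_qmmm,resp_qmmm_ci,abcg2,abcg2_ci
2PR,0.08,1.36,0.20,0.12,0.12,0.29,0.28,-0.31,0.30
3MP,1.20,3.50,0.06,1.26,0.10,1.07,0.17,0.89,0.16
ASP,1.19,1.57,0.44,0.54,0.15,1.08,0.29,0.74,0.20
CYC,1.49,3.50,0.14,0.10,0.12,1.25,0.40,1.21,0.35
DIA,4.89,5.42,0.96,3.34,0.38,5.80,0.49,5.12,0.34
IMI,-0.08,1.64,0.06,-3.04,0.05,-0.74,0.43,-0.39,0.44
KET,3.12,3.38,0.68,1.51,0.26,3.82,0.42,3.27,0.46
NIT,3.70,5.92,0.52,1.18,0.34,3.63,0.43,6.04,0.35
PRO,5.58,7.77,0.36,5.69,0.42,6.37,0.33,7.88,0.22
TER,1.89,2.19,0.41,0.52,0.17,3.82,0.74,2.61,0.31
TIO,1.81,2.79,0.06,1.79,0.09,2.89,0.07,2.04,0.07
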