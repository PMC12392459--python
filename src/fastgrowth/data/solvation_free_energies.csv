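name,exp_w,exp_o,am1bcc_w,am1bcc_w_ci,resp_hf_w,resp_hf_w_ci,resp_qmmm_w,resp_qmmm_w_ci,abcg2_w,abcg2_w_ci,am1bcc_o,am1bcc_o_ci,resp_hf_o,resp_hf_o_ci,resp_qmmm_o,resp_qmmm_o_ci,abcg2_o,abcg2_o_ci
2PR,-6.40,-6.51,-3.00,0.14,-3.32,0.08,-4.40,0.09,-5.85,0.18,-4.82,0.14,-3.49,0.09,-4.80,0.26,-5.43,0.24
3MP,-4.77,-6.41,0.41,0.03,-2.28,0.04,-4.21,0.05,-4.07,0.04,-4.39,0.05,-4.01,0.09,-5.67,0.16,-5.29,0.16
ASP,-9.94,-11.57,-9.37,0.24,-6.85,0.05,-8.29,0.06,-8.41,0.07,-11.44,0.34,-7.59,0.14,-9.77,0.28,-9.43,0.19
CYC,-4.59,-6.63,-0.41,0.09,-4.31,0.07,-5.64,0.07,-6.60,0.11,-4.36,0.11,-4.45,0.10,-7.35,0.39,-8.26,0.33
DIA,-5.74,-12.44,-11.04,0.65,-10.62,0.13,-10.23,0.16,-10.84,0.14,-20.07,0.42,-15.19,0.36,-18.17,0.46,-17.85,0.31
IMI,-9.63,-9.52,-1.64,0.03,-6.65,0.03,-10.94,0.04,-9.10,0.03,-3.90,0.06,-2.49,0.04,-9.93,0.43,-8.57,0.44
KET,-10.78,-15.05,-10.28,0.44,-9.23,0.07,-9.06,0.06,-9.65,0.09,-15.12,0.50,-11.30,0.25,-14.30,0.42,-14.13,0.45
NIT,-7.98,-13.05,-11.75,0.21,-13.89,0.10,-13.85,0.09,-9.33,0.09,-19.79,0.50,-15.50,0.32,-18.83,0.42,-17.60,0.34
PRO,-2.45,-10.09,-3.45,0.18,-6.42,0.09,-6.45,0.08,-4.08,0.08,-14.12,0.26,-14.22,0.41,-15.18,0.32,-14.88,0.20
TER,-11.14,-13.73,-15.40,0.98,-9.91,0.07,-13.65,0.08,-13.71,0.08,-18.64,0.40,-10.62,0.15,-18.88,0.74,-17.29,0.30
TIO,-1.40,-3.88,0.08,0.04,-1.12,0.04,0.14,0.03,-1.06,0.04,-3.74,0.04,-3.57,0.08,-3.82,0.06,-3.85,0.06
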