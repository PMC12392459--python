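quantity,protocol,exclude,ccc,rho,a,b,mue,tau,mse
dG_w,am1bcc,,0.58,0.68,1.15,1.83,3.43,0.49,-0.79
dG_w,resp_hf,,0.57,0.58,0.67,-2.20,2.70,0.49,-0.02
dG_w,resp_qmmm,,0.70,0.75,0.96,-1.36,2.43,0.49,1.07
dG_w,abcg2,,0.81,0.84,0.90,-1.42,1.59,0.60,0.72
logp,am1bcc,,0.73,0.90,0.98,1.30,1.25,0.62,-1.25
logp,resp_hf,,0.74,0.87,1.01,-1.10,1.12,0.64,1.08
logp,resp_qmmm,,0.92,0.95,1.17,0.01,0.62,0.89,-0.40
logp,abcg2,,0.89,0.97,1.41,-0.54,0.70,0.96,-0.38
logp,abcg2,NIT;PRO,0.97,0.98,1.15,-0.30,0.34,1.00,0.04
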