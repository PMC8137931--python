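population,psi_b50_MPa,psi_b50_disp,psi_b50_letter,theta_H_MPa_d,theta_H_disp,theta_H_letter,sigma_psib_MPa,sigma_psib_disp,sigma_psib_letter,r2
PHA,-2.59,0.11,a,23.41,0.34,ab,0.57,0.12,a,0.86
PHB,-3.14,0.46,a,30.93,5.41,b,0.91,0.11,a,0.85
SRA,-3.04,0.26,a,22.01,2.88,ab,0.83,0.09,a,0.86
SRB,-2.84,0.82,a,14.13,3.47,a,0.6,0.36,a,0.95
PA,-2.91,0.61,a,17.49,3.71,ab,0.64,0.17,a,0.93
PB,-2.69,0.04,a,13.63,0.35,a,0.58,0.14,a,0.93
JA,-2.13,0.09,a,18.55,0.67,ab,0.54,0.09,a,0.92
JB,-2.66,0.67,a,30.53,10.3,b,0.79,0.39,a,0.86
SA,-3.12,1.0,a,27.76,9.99,ab,0.74,0.27,a,0.9
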