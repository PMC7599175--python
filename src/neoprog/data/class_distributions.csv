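outcome,measure,region,delayed_mean,delayed_sd,normal_mean,normal_sd
cognitive,NAA/Cho,FWMR,0.64,0.14,0.61,0.1
cognitive,NAA/Cr,FWMR,1.47,0.31,1.31,0.36
cognitive,Cho/Cr,FWMR,2.32,0.48,2.14,0.44
cognitive,NAA/mI,FWMR,2.7,0.77,2.41,0.74
cognitive,mI/Cr,FWMR,0.57,0.16,0.52,0.19
cognitive,MD,FWMR,1.36,0.12,1.14,0.15
cognitive,FA,FWMR,0.18,0.03,0.16,0.02
cognitive,NAA/Cho,FWML,0.61,0.19,0.61,0.15
cognitive,NAA/Cr,FWML,1.18,0.56,1.29,0.41
cognitive,Cho/Cr,FWML,1.88,0.62,2.13,0.49
cognitive,NAA/mI,FWML,2.58,1.2,2.41,0.96
cognitive,mI/Cr,FWML,0.48,0.19,0.54,0.19
cognitive,MD,FWML,1.35,0.12,1.39,0.15
cognitive,FA,FWML,0.17,0.04,0.15,0.02
cognitive,NAA/Cho,CWMR,0.82,0.15,0.72,0.14
cognitive,NAA/Cr,CWMR,1.42,0.28,1.28,0.22
cognitive,Cho/Cr,CWMR,1.75,0.25,1.78,0.13
cognitive,NAA/mI,CWMR,3.82,1.4,3.21,0.94
cognitive,mI/Cr,CWMR,0.36,0.14,0.41,0.08
cognitive,MD,CWMR,1.31,0.15,1.32,0.15
cognitive,FA,CWMR,0.23,0.05,0.23,0.04
cognitive,NAA/Cho,CWML,0.8,0.14,0.72,0.14
cognitive,NAA/Cr,CWML,1.42,0.29,1.28,0.22
cognitive,Cho/Cr,CWML,1.79,0.13,1.78,0.13
cognitive,NAA/mI,CWML,3.82,1.4,3.21,0.94
cognitive,mI/Cr,CWML,0.36,0.14,0.41,0.08
cognitive,MD,CWML,1.31,0.2,1.31,0.16
cognitive,FA,CWML,0.23,0.07,0.23,0.04
cognitive,NAA/Cho,PWMR,0.89,0.14,0.92,0.23
cognitive,NAA/Cr,PWMR,1.56,0.13,1.61,0.43
cognitive,Cho/Cr,PWMR,1.76,0.19,1.68,0.44
cognitive,NAA/mI,PWMR,4.13,1.07,3.71,1.65
cognitive,mI/Cr,PWMR,0.39,0.07,0.37,0.15
cognitive,MD,PWMR,1.39,0.22,1.39,0.14
cognitive,FA,PWMR,0.18,0.05,0.17,0.03
cognitive,NAA/Cho,PWML,0.88,0.1,0.92,0.15
cognitive,NAA/Cr,PWML,1.55,0.21,1.59,0.32
cognitive,Cho/Cr,PWML,1.76,0.19,1.74,0.28
cognitive,NAA/mI,PWML,3.96,0.72,3.92,1.51
cognitive,mI/Cr,PWML,0.39,0.06,0.36,0.15
cognitive,MD,PWML,1.37,0.23,1.36,0.13
cognitive,FA,PWML,0.18,0.04,0.17,0.03
motor,NAA/Cho,FWMR,0.6,0.12,0.62,0.1
motor,NAA/Cr,FWMR,1.23,0.31,1.33,0.36
motor,Cho/Cr,FWMR,2.05,0.39,2.16,0.45
motor,NAA/mI,FWMR,2.47,0.68,2.44,0.76
motor,mI/Cr,FWMR,0.49,0.18,0.53,0.19
motor,MD,FWMR,1.33,0.11,1.42,0.15
motor,FA,FWMR,0.16,0.03,0.16,0.02
motor,NAA/Cho,FWML,0.66,0.17,0.61,0.14
motor,NAA/Cr,FWML,1.29,0.55,1.28,0.4
motor,Cho/Cr,FWML,1.93,0.51,2.13,0.49
motor,NAA/mI,FWML,2.82,0.99,2.37,0.95
motor,mI/Cr,FWML,0.46,0.13,0.55,0.19
motor,MD,FWML,1.31,0.11,1.04,0.15
motor,FA,FWML,0.16,0.03,0.15,0.02
motor,NAA/Cho,CWMR,0.76,0.15,0.61,0.15
motor,NAA/Cr,CWMR,1.34,0.25,1.28,0.29
motor,Cho/Cr,CWMR,1.76,0.21,2.13,0.25
motor,NAA/mI,CWMR,3.28,0.89,2.37,1.42
motor,mI/Cr,CWMR,0.42,0.08,0.55,0.14
motor,MD,CWMR,1.26,0.16,1.32,0.16
motor,FA,CWMR,0.22,0.04,0.23,0.04
motor,NAA/Cho,CWML,0.77,0.09,0.78,0.01
motor,NAA/Cr,CWML,1.39,0.19,1.39,0.21
motor,Cho/Cr,CWML,1.81,0.14,1.79,0.25
motor,NAA/mI,CWML,3.3,0.53,3.65,1.32
motor,mI/Cr,CWML,0.43,0.05,0.37,0.13
motor,MD,CWML,1.28,0.18,1.32,0.16
motor,FA,CWML,0.23,0.05,0.23,0.04
motor,NAA/Cho,PWMR,0.95,0.22,0.92,0.22
motor,NAA/Cr,PWMR,1.64,0.33,1.61,0.43
motor,Cho/Cr,PWMR,1.61,0.39,1.68,0.44
motor,NAA/mI,PWMR,3.79,1.42,3.75,1.64
motor,mI/Cr,PWMR,0.37,0.12,0.37,0.15
motor,MD,PWMR,1.31,0.12,1.4,0.15
motor,FA,PWMR,0.17,0.03,0.17,0.03
motor,NAA/Cho,PWML,0.87,0.1,0.92,0.16
motor,NAA/Cr,PWML,1.55,0.32,1.59,0.32
motor,Cho/Cr,PWML,1.74,0.28,1.74,0.28
motor,NAA/mI,PWML,3.89,0.71,3.92,1.53
motor,mI/Cr,PWML,0.41,0.07,0.35,0.15
motor,MD,PWML,1.34,0.18,1.36,0.13
motor,FA,PWML,0.17,0.04,0.17,0.03
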