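location,scenario,period,n_mean,n_se,gt_mean,gt_se
Bhubaneswar,BL,1975,4.66,0.00,28.35,0.00
Junagadh,BL,1975,3.71,0.00,35.87,0.00
Jalgaon,BL,1975,3.67,0.00,35.85,0.00
Raichur,BL,1975,4.38,0.00,30.45,0.00
Tirupathi,BL,1975,4.39,0.00,29.66,0.00
Vridhachalam,BL,1975,3.88,0.00,34.02,0.00
Bhubaneswar,A2,2020,4.81,0.05,24.90,2.89
Junagadh,A2,2020,4.01,0.05,29.58,0.58
Jalgaon,A2,2020,4.59,0.07,28.92,1.20
Raichur,A2,2020,4.51,0.05,29.49,0.37
Tirupathi,A2,2020,4.83,0.05,27.00,0.36
Vridhachalam,A2,2020,5.16,0.05,25.18,0.21
Bhubaneswar,A2,2050,5.00,0.08,26.47,0.40
Junagadh,A2,2050,4.78,0.13,27.63,0.93
Jalgaon,A2,2050,4.11,0.19,32.43,0.87
Raichur,A2,2050,4.75,0.10,28.01,0.71
Tirupathi,A2,2050,5.03,0.10,26.35,0.53
Vridhachalam,A2,2050,5.29,0.09,25.04,0.49
Bhubaneswar,A2,2080,5.33,0.13,24.88,0.69
Junagadh,A2,2080,5.14,0.98,25.94,1.29
Jalgaon,A2,2080,4.47,0.21,29.65,0.47
Raichur,A2,2080,5.12,0.14,26.09,0.73
Tirupathi,A2,2080,5.36,0.15,24.66,0.79
Vridhachalam,A2,2080,5.61,0.14,23.55,0.54
Bhubaneswar,A1B,2020,4.81,0.06,27.22,0.29
Junagadh,A1B,2020,4.06,0.81,32.05,4.81
Jalgaon,A1B,2020,4.85,0.24,27.65,2.30
Raichur,A1B,2020,4.54,0.06,29.28,0.45
Tirupathi,A1B,2020,4.54,0.18,28.67,1.29
Vridhachalam,A1B,2020,4.57,0.37,29.02,2.64
Bhubaneswar,A1B,2050,5.05,0.08,26.30,0.42
Junagadh,A1B,2050,4.82,0.11,27.46,0.81
Jalgaon,A1B,2050,4.11,0.07,32.16,0.63
Raichur,A1B,2050,4.78,0.07,27.68,0.57
Tirupathi,A1B,2050,5.06,0.07,26.22,0.39
Vridhachalam,A1B,2050,5.32,0.07,24.90,0.36
Bhubaneswar,A1B,2080,5.28,0.13,25.12,0.80
Junagadh,A1B,2080,5.07,0.21,26.21,1.52
Jalgaon,A1B,2080,4.50,0.11,29.42,0.49
Raichur,A1B,2080,5.08,0.08,26.15,0.41
Tirupathi,A1B,2080,5.30,0.12,24.97,0.68
Vridhachalam,A1B,2080,5.54,0.10,23.78,0.51
Bhubaneswar,B1,2020,4.82,0.50,25.80,2.57
Junagadh,B1,2020,4.02,0.28,29.80,2.02
Jalgaon,B1,2020,4.60,0.03,28.78,0.64
Raichur,B1,2020,4.54,0.05,29.28,0.34
Tirupathi,B1,2020,4.87,0.05,25.93,0.94
Vridhachalam,B1,2020,5.18,0.05,25.04,0.25
Bhubaneswar,B1,2050,4.96,0.08,26.65,0.37
Junagadh,B1,2050,4.72,0.10,28.21,0.74
Jalgaon,B1,2050,4.03,0.06,32.97,0.35
Raichur,B1,2050,4.70,0.08,28.37,0.52
Tirupathi,B1,2050,4.99,0.08,26.53,0.31
Vridhachalam,B1,2050,5.24,0.07,25.30,0.38
Bhubaneswar,B1,2080,5.09,0.10,26.07,0.57
Junagadh,B1,2080,4.86,0.16,27.28,1.22
Jalgaon,B1,2080,4.18,0.10,31.72,0.63
Raichur,B1,2080,4.83,0.09,27.61,0.57
Tirupathi,B1,2080,5.11,0.06,26.02,0.36
Vridhachalam,B1,2080,5.36,0.06,24.70,0.34
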