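location,variable,scenario,period,value
Bhubaneswar,tmax,BL,1975,31.34
Jalgaon,tmax,BL,1975,30.97
Junagadh,tmax,BL,1975,29.93
Raichur,tmax,BL,1975,33.10
Tirupathi,tmax,BL,1975,32.56
Vridhachalam,tmax,BL,1975,32.88
Bhubaneswar,tmax,A2,2020,32.20
Jalgaon,tmax,A2,2020,31.71
Junagadh,tmax,A2,2020,30.71
Raichur,tmax,A2,2020,33.78
Tirupathi,tmax,A2,2020,33.29
Vridhachalam,tmax,A2,2020,33.59
Bhubaneswar,tmax,A2,2050,32.94
Jalgaon,tmax,A2,2050,32.74
Junagadh,tmax,A2,2050,33.68
Raichur,tmax,A2,2050,34.69
Tirupathi,tmax,A2,2050,34.06
Vridhachalam,tmax,A2,2050,34.34
Bhubaneswar,tmax,A2,2080,34.29
Jalgaon,tmax,A2,2080,34.39
Junagadh,tmax,A2,2080,33.06
Raichur,tmax,A2,2080,36.18
Tirupathi,tmax,A2,2080,35.38
Vridhachalam,tmax,A2,2080,35.61
Bhubaneswar,tmax,A1B,2020,32.36
Jalgaon,tmax,A1B,2020,31.84
Junagadh,tmax,A1B,2020,30.79
Raichur,tmax,A1B,2020,33.90
Tirupathi,tmax,A1B,2020,33.35
Vridhachalam,tmax,A1B,2020,33.62
Bhubaneswar,tmax,A1B,2050,33.12
Jalgaon,tmax,A1B,2050,32.86
Junagadh,tmax,A1B,2050,31.75
Raichur,tmax,A1B,2050,34.79
Tirupathi,tmax,A1B,2050,34.16
Vridhachalam,tmax,A1B,2050,34.43
Bhubaneswar,tmax,A1B,2080,34.08
Jalgaon,tmax,A1B,2080,34.11
Junagadh,tmax,A1B,2080,32.88
Raichur,tmax,A1B,2080,35.84
Tirupathi,tmax,A1B,2080,35.14
Vridhachalam,tmax,A1B,2080,35.35
Bhubaneswar,tmax,B1,2020,31.85
Jalgaon,tmax,B1,2020,31.71
Junagadh,tmax,B1,2020,29.11
Raichur,tmax,B1,2020,33.79
Tirupathi,tmax,B1,2020,33.76
Vridhachalam,tmax,B1,2020,33.42
Bhubaneswar,tmax,B1,2050,32.85
Jalgaon,tmax,B1,2050,32.51
Junagadh,tmax,B1,2050,31.33
Raichur,tmax,B1,2050,34.49
Tirupathi,tmax,B1,2050,33.88
Vridhachalam,tmax,B1,2050,34.12
Bhubaneswar,tmax,B1,2080,33.39
Jalgaon,tmax,B1,2080,33.23
Junagadh,tmax,B1,2080,31.97
Raichur,tmax,B1,2080,35.06
Tirupathi,tmax,B1,2080,34.41
Vridhachalam,tmax,B1,2080,34.62
Bhubaneswar,tmin,BL,1975,22.77
Jalgaon,tmin,BL,1975,17.61
Junagadh,tmin,BL,1975,21.14
Raichur,tmin,BL,1975,22.17
Tirupathi,tmin,BL,1975,22.34
Vridhachalam,tmin,BL,1975,23.84
Bhubaneswar,tmin,A2,2020,23.26
Jalgaon,tmin,A2,2020,18.64
Junagadh,tmin,A2,2020,22.00
Raichur,tmin,A2,2020,23.13
Tirupathi,tmin,A2,2020,23.26
Vridhachalam,tmin,A2,2020,24.70
Bhubaneswar,tmin,A2,2050,24.14
Jalgaon,tmin,A2,2050,19.91
Junagadh,tmin,A2,2050,22.88
Raichur,tmin,A2,2050,28.28
Tirupathi,tmin,A2,2050,24.22
Vridhachalam,tmin,A2,2050,25.61
Bhubaneswar,tmin,A2,2080,25.53
Jalgaon,tmin,A2,2080,21.83
Junagadh,tmin,A2,2080,24.50
Raichur,tmin,A2,2080,25.97
Tirupathi,tmin,A2,2080,25.74
Vridhachalam,tmin,A2,2080,27.03
Bhubaneswar,tmin,A1B,2020,23.44
Jalgaon,tmin,A1B,2020,18.83
Junagadh,tmin,A1B,2020,22.09
Raichur,tmin,A1B,2020,23.31
Tirupathi,tmin,A1B,2020,23.39
Vridhachalam,tmin,A1B,2020,24.81
Bhubaneswar,tmin,A1B,2050,24.32
Jalgaon,tmin,A1B,2050,20.08
Junagadh,tmin,A1B,2050,23.10
Raichur,tmin,A1B,2050,24.41
Tirupathi,tmin,A1B,2050,24.37
Vridhachalam,tmin,A1B,2050,25.74
Bhubaneswar,tmin,A1B,2080,25.30
Jalgaon,tmin,A1B,2080,21.44
Junagadh,tmin,A1B,2080,24.24
Raichur,tmin,A1B,2080,25.57
Tirupathi,tmin,A1B,2080,25.44
Vridhachalam,tmin,A1B,2080,26.74
Bhubaneswar,tmin,B1,2020,23.63
Jalgaon,tmin,B1,2020,18.68
Junagadh,tmin,B1,2020,19.74
Raichur,tmin,B1,2020,22.98
Tirupathi,tmin,B1,2020,23.29
Vridhachalam,tmin,B1,2020,25.20
Bhubaneswar,tmin,B1,2050,23.97
Jalgaon,tmin,B1,2050,19.54
Junagadh,tmin,B1,2050,22.67
Raichur,tmin,B1,2050,23.95
Tirupathi,tmin,B1,2050,23.94
Vridhachalam,tmin,B1,2050,25.32
Bhubaneswar,tmin,B1,2080,24.50
Jalgaon,tmin,B1,2080,20.30
Junagadh,tmin,B1,2080,23.31
Raichur,tmin,B1,2080,24.61
Tirupathi,tmin,B1,2080,24.54
Vridhachalam,tmin,B1,2080,25.90
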