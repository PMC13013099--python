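weight,dose_krad,mu,sigma
-1.0,0.0,0.0,0.02
-1.0,100.0,0.045,0.026
-1.0,200.0,0.09,0.032
-1.0,300.0,0.135,0.038
-1.0,400.0,0.18,0.044
-1.0,500.0,0.225,0.05
-1.0,600.0,0.27,0.056
-1.0,700.0,0.315,0.062
-1.0,800.0,0.36,0.068
-1.0,900.0,0.405,0.074
-1.0,1000.0,0.45,0.08
-0.75,0.0,0.0,0.02
-0.75,100.0,0.03,0.0255
-0.75,200.0,0.06,0.031
-0.75,300.0,0.09,0.0365
-0.75,400.0,0.12,0.042
-0.75,500.0,0.15,0.0475
-0.75,600.0,0.18,0.053
-0.75,700.0,0.21,0.0585
-0.75,800.0,0.24,0.064
-0.75,900.0,0.27,0.0695
-0.75,1000.0,0.3,0.075
-0.5,0.0,0.0,0.02
-0.5,100.0,0.015,0.025
-0.5,200.0,0.03,0.03
-0.5,300.0,0.045,0.035
-0.5,400.0,0.06,0.04
-0.5,500.0,0.075,0.045
-0.5,600.0,0.09,0.05
-0.5,700.0,0.105,0.055
-0.5,800.0,0.12,0.06
-0.5,900.0,0.135,0.065
-0.5,1000.0,0.15,0.07
-0.25,0.0,0.0,0.02
-0.25,100.0,0.0,0.0245
-0.25,200.0,0.0,0.029
-0.25,300.0,0.0,0.0335
-0.25,400.0,0.0,0.038
-0.25,500.0,0.0,0.0425
-0.25,600.0,0.0,0.047
-0.25,700.0,0.0,0.0515
-0.25,800.0,0.0,0.056
-0.25,900.0,0.0,0.0605
-0.25,1000.0,0.0,0.065
0.0,0.0,-0.0,0.02
0.0,100.0,-0.015,0.024
0.0,200.0,-0.03,0.028
0.0,300.0,-0.045,0.032
0.0,400.0,-0.06,0.036
0.0,500.0,-0.075,0.04
0.0,600.0,-0.09,0.044
0.0,700.0,-0.105,0.048
0.0,800.0,-0.12,0.052
0.0,900.0,-0.135,0.056
0.0,1000.0,-0.15,0.06
0.25,0.0,-0.0,0.02
0.25,100.0,-0.03,0.0245
0.25,200.0,-0.06,0.029
0.25,300.0,-0.09,0.0335
0.25,400.0,-0.12,0.038
0.25,500.0,-0.15,0.0425
0.25,600.0,-0.18,0.047
0.25,700.0,-0.21,0.0515
0.25,800.0,-0.24,0.056
0.25,900.0,-0.27,0.0605
0.25,1000.0,-0.3,0.065
0.5,0.0,-0.0,0.02
0.5,100.0,-0.045,0.025
0.5,200.0,-0.09,0.03
0.5,300.0,-0.135,0.035
0.5,400.0,-0.18,0.04
0.5,500.0,-0.225,0.045
0.5,600.0,-0.27,0.05
0.5,700.0,-0.315,0.055
0.5,800.0,-0.36,0.06
0.5,900.0,-0.405,0.065
0.5,1000.0,-0.45,0.07
0.75,0.0,-0.0,0.02
0.75,100.0,-0.06,0.0255
0.75,200.0,-0.12,0.031
0.75,300.0,-0.18,0.0365
0.75,400.0,-0.24,0.042
0.75,500.0,-0.3,0.0475
0.75,600.0,-0.36,0.053
0.75,700.0,-0.42,0.0585
0.75,800.0,-0.48,0.064
0.75,900.0,-0.54,0.0695
0.75,1000.0,-0.6,0.075
1.0,0.0,-0.0,0.02
1.0,100.0,-0.075,0.026
1.0,200.0,-0.15,0.032
1.0,300.0,-0.225,0.038
1.0,400.0,-0.3,0.044
1.0,500.0,-0.375,0.05
1.0,600.0,-0.45,0.056
1.0,700.0,-0.525,0.062
1.0,800.0,-0.6,0.068
1.0,900.0,-0.675,0.074
1.0,1000.0,-0.75,0.08
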