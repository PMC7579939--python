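age,ser,k_mean,sex,dal_dage
6,-1.00,40.00,1,0.089
18,-1.00,40.00,1,0.024
6,-2.00,40.00,1,0.094
18,-2.00,40.00,1,0.028
6,-3.00,40.00,1,0.100
18,-3.00,40.00,1,0.032
6,-4.00,40.00,1,0.105
18,-4.00,40.00,1,0.037
6,-5.00,40.00,1,0.111
18,-5.00,40.00,1,0.041
6,-6.00,40.00,1,0.116
18,-6.00,40.00,1,0.045
6,-1.00,40.00,0,0.083
18,-1.00,40.00,0,0.018
6,-2.00,40.00,0,0.088
18,-2.00,40.00,0,0.022
6,-3.00,40.00,0,0.094
18,-3.00,40.00,0,0.026
6,-4.00,40.00,0,0.099
18,-4.00,40.00,0,0.030
6,-5.00,40.00,0,0.104
18,-5.00,40.00,0,0.034
6,-6.00,40.00,0,0.110
18,-6.00,40.00,0,0.038
6,-1.00,42.00,1,0.082
18,-1.00,42.00,1,0.020
6,-2.00,42.00,1,0.087
18,-2.00,42.00,1,0.024
6,-3.00,42.00,1,0.098
18,-3.00,42.00,1,0.032
6,-4.00,42.00,1,0.098
18,-4.00,42.00,1,0.032
6,-5.00,42.00,1,0.104
18,-5.00,42.00,1,0.036
6,-6.00,42.00,1,0.109
18,-6.00,42.00,1,0.040
6,-1.00,42.00,0,0.076
18,-1.00,42.00,0,0.013
6,-2.00,42.00,0,0.081
18,-2.00,42.00,0,0.017
6,-3.00,42.00,0,0.086
18,-3.00,42.00,0,0.021
6,-4.00,42.00,0,0.092
18,-4.00,42.00,0,0.025
6,-5.00,42.00,0,0.097
18,-5.00,42.00,0,0.029
6,-6.00,42.00,0,0.103
18,-6.00,42.00,0,0.033
6,-1.00,44.00,1,0.074
18,-1.00,44.00,1,0.015
6,-2.00,44.00,1,0.080
18,-2.00,44.00,1,0.019
6,-3.00,44.00,1,0.085
18,-3.00,44.00,1,0.027
6,-4.00,44.00,1,0.091
18,-4.00,44.00,1,0.027
6,-5.00,44.00,1,0.096
18,-5.00,44.00,1,0.031
6,-6.00,44.00,1,0.101
18,-6.00,44.00,1,0.035
6,-1.00,44.00,0,0.068
18,-1.00,44.00,0,0.008
6,-2.00,44.00,0,0.073
18,-2.00,44.00,0,0.012
6,-3.00,44.00,0,0.079
18,-3.00,44.00,0,0.016
6,-4.00,44.00,0,0.084
18,-4.00,44.00,0,0.020
6,-5.00,44.00,0,0.090
18,-5.00,44.00,0,0.024
6,-6.00,44.00,0,0.095
18,-6.00,44.00,0,0.028
6,-1.00,46.00,1,0.066
18,-1.00,46.00,1,0.010
6,-2.00,46.00,1,0.072
18,-2.00,46.00,1,0.014
6,-3.00,46.00,1,0.077
18,-3.00,46.00,1,0.022
6,-4.00,46.00,1,0.083
18,-4.00,46.00,1,0.022
6,-5.00,46.00,1,0.088
18,-5.00,46.00,1,0.026
6,-6.00,46.00,1,0.093
18,-6.00,46.00,1,0.030
6,-1.00,46.00,0,0.060
18,-1.00,46.00,0,0.003
6,-2.00,46.00,0,0.065
18,-2.00,46.00,0,0.007
6,-3.00,46.00,0,0.071
18,-3.00,46.00,0,0.011
6,-4.00,46.00,0,0.076
18,-4.00,46.00,0,0.015
6,-5.00,46.00,0,0.081
18,-5.00,46.00,0,0.019
6,-6.00,46.00,0,0.087
18,-6.00,46.00,0,0.023
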