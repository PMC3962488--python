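chromosome_set,subset,class,mean,sd
ROMA/10B,123,X,0.123,0.020
ROMA/10B,123,12,0.092,0.028
ROMA/10B,123,X1,0.225,0.003
ROMA/10B,123,2,0.203,0.040
ROMA/10B,123,X2,0.182,0.010
ROMA/10B,123,1,0.223,0.020
ROMA/10B,1,X,0.145,0.058
ROMA/10B,1,12,0.070,0.016
ROMA/10B,1,X1,0.230,0.026
ROMA/10B,1,2,0.126,0.210
ROMA/10B,1,X2,0.183,0.033
ROMA/10B,1,1,0.231,0.105
ROMA/10B,2,X,0.119,0.012
ROMA/10B,2,12,0.128,0.039
ROMA/10B,2,X1,0.226,0.042
ROMA/10B,2,2,0.149,0.112
ROMA/10B,2,X2,0.166,0.058
ROMA/10B,2,1,0.205,0.056
ROMA/10B,3,X,0.114,0.037
ROMA/10B,3,12,0.088,0.049
ROMA/10B,3,X1,0.227,0.073
ROMA/10B,3,2,0.183,0.087
ROMA/10B,3,X2,0.189,0.012
ROMA/10B,3,1,0.226,0.044
ROMA/10B,0.1,X,0.103,0.019
ROMA/10B,0.1,12,0.065,0.026
ROMA/10B,0.1,X1,0.256,0.051
ROMA/10B,0.1,2,0.147,0.116
ROMA/10B,0.1,X2,0.218,0.015
ROMA/10B,0.1,1,0.205,0.058
ROMA/10B,0.2,X,0.140,0.062
ROMA/10B,0.2,12,0.105,0.028
ROMA/10B,0.2,X1,0.202,0.035
ROMA/10B,0.2,2,0.150,0.126
ROMA/10B,0.2,X2,0.159,0.034
ROMA/10B,0.2,1,0.213,0.063
ROMA/10B,0.3,X,0.135,0.018
ROMA/10B,0.3,12,0.116,0.056
ROMA/10B,0.3,X1,0.225,0.043
ROMA/10B,0.3,2,0.155,0.179
ROMA/10B,0.3,X2,0.161,0.016
ROMA/10B,0.3,1,0.245,0.090
ROMA/473,123,X,0.117,0.017
ROMA/473,123,12,0.187,0.016
ROMA/473,123,X1,0.150,0.024
ROMA/473,123,2,0.191,0.036
ROMA/473,123,X2,0.249,0.048
ROMA/473,123,1,0.105,0.013
ROMA/473,1,X,0.140,0.048
ROMA/473,1,12,0.164,0.064
ROMA/473,1,X1,0.158,0.010
ROMA/473,1,2,0.236,0.042
ROMA/473,1,X2,0.188,0.059
ROMA/473,1,1,0.113,0.044
ROMA/473,2,X,0.110,0.061
ROMA/473,2,12,0.192,0.090
ROMA/473,2,X1,0.122,0.053
ROMA/473,2,2,0.182,0.023
ROMA/473,2,X2,0.281,0.065
ROMA/473,2,1,0.113,0.034
ROMA/473,3,X,0.112,0.059
ROMA/473,3,12,0.190,0.050
ROMA/473,3,X1,0.169,0.056
ROMA/473,3,2,0.157,0.026
ROMA/473,3,X2,0.282,0.078
ROMA/473,3,1,0.089,0.022
ROMA/473,0.1,X,0.127,0.045
ROMA/473,0.1,12,0.167,0.045
ROMA/473,0.1,X1,0.187,0.042
ROMA/473,0.1,2,0.174,0.049
ROMA/473,0.1,X2,0.241,0.049
ROMA/473,0.1,1,0.104,0.033
ROMA/473,0.2,X,0.095,0.046
ROMA/473,0.2,12,0.216,0.068
ROMA/473,0.2,X1,0.137,0.029
ROMA/473,0.2,2,0.194,0.007
ROMA/473,0.2,X2,0.246,0.070
ROMA/473,0.2,1,0.112,0.019
ROMA/473,0.3,X,0.141,0.066
ROMA/473,0.3,12,0.162,0.077
ROMA/473,0.3,X1,0.126,0.046
ROMA/473,0.3,2,0.208,0.068
ROMA/473,0.3,X2,0.265,0.121
ROMA/473,0.3,1,0.098,0.050
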