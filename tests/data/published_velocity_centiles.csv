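biometry,ga,c3,c5,c10,c50,c90,c95,c97
HC,16,10.62,10.82,11.14,12.24,13.34,13.65,13.85
HC,17,10.52,10.73,11.06,12.22,13.37,13.7,13.91
HC,18,10.39,10.62,10.96,12.17,13.38,13.72,13.94
HC,19,10.23,10.47,10.83,12.09,13.35,13.71,13.94
HC,20,10.04,10.28,10.66,11.97,13.29,13.67,13.91
HC,21,9.81,10.06,10.45,11.82,13.2,13.59,13.84
HC,22,9.54,9.8,10.21,11.64,13.06,13.47,13.73
HC,23,9.24,9.51,9.93,11.41,12.89,13.32,13.59
HC,24,8.89,9.18,9.61,11.15,12.68,13.12,13.4
HC,25,8.51,8.8,9.26,10.85,12.43,12.89,13.18
HC,26,8.08,8.39,8.86,10.5,12.14,12.61,12.91
HC,27,7.62,7.93,8.41,10.11,11.81,12.29,12.61
HC,28,7.1,7.43,7.93,9.68,11.43,11.93,12.25
HC,29,6.55,6.88,7.39,9.2,11.01,11.52,11.86
HC,30,5.94,6.29,6.82,8.68,10.54,11.07,11.41
HC,31,5.29,5.65,6.19,8.11,10.02,10.57,10.92
HC,32,4.6,4.96,5.52,7.49,9.46,10.02,10.39
HC,33,3.85,4.22,4.8,6.82,8.85,9.43,9.8
HC,34,3.05,3.44,4.03,6.11,8.19,8.78,9.16
HC,35,2.21,2.6,3.21,5.34,7.48,8.08,8.48
HC,36,1.31,1.71,2.34,4.52,6.71,7.34,7.74
HC,37,0.36,0.77,1.41,3.65,5.9,6.54,6.95
HC,38,-0.64,-0.22,0.44,2.73,5.03,5.68,6.11
BPD,16,2.4,2.5,2.6,3.2,3.7,3.9,4.0
BPD,17,2.4,2.5,2.7,3.2,3.8,3.9,4.0
BPD,18,2.4,2.5,2.7,3.2,3.8,3.9,4.0
BPD,19,2.4,2.5,2.7,3.2,3.8,4.0,4.1
BPD,20,2.4,2.5,2.7,3.2,3.8,4.0,4.1
BPD,21,2.4,2.5,2.7,3.2,3.8,3.9,4.1
BPD,22,2.4,2.5,2.7,3.2,3.8,3.9,4.0
BPD,23,2.3,2.5,2.6,3.2,3.7,3.9,4.0
BPD,24,2.3,2.4,2.6,3.1,3.7,3.9,4.0
BPD,25,2.2,2.3,2.5,3.1,3.6,3.8,3.9
BPD,26,2.2,2.3,2.4,3.0,3.6,3.7,3.8
BPD,27,2.1,2.2,2.3,2.9,3.5,3.6,3.8
BPD,28,2.0,2.1,2.2,2.8,3.4,3.5,3.7
BPD,29,1.8,1.9,2.1,2.7,3.3,3.4,3.5
BPD,30,1.7,1.8,2.0,2.6,3.1,3.3,3.4
BPD,31,1.6,1.7,1.8,2.4,3.0,3.2,3.3
BPD,32,1.4,1.5,1.7,2.3,2.8,3.0,3.1
BPD,33,1.2,1.3,1.5,2.1,2.7,2.8,3.0
BPD,34,1.0,1.1,1.3,1.9,2.5,2.7,2.8
BPD,35,0.8,0.9,1.1,1.7,2.3,2.4,2.6
BPD,36,0.6,0.7,0.9,1.5,2.1,2.2,2.3
BPD,37,0.3,0.4,0.6,1.2,1.8,2.0,2.1
BPD,38,0.1,0.2,0.4,1.0,1.6,1.7,1.8
OFD,16,3.9,4.0,4.1,4.5,4.9,5.0,5.1
OFD,17,3.8,3.9,4.0,4.5,4.9,5.0,5.1
OFD,18,3.7,3.8,3.9,4.4,4.9,5.0,5.1
OFD,19,3.6,3.7,3.9,4.4,4.9,5.0,5.1
OFD,20,3.5,3.6,3.8,4.3,4.9,5.0,5.1
OFD,21,3.4,3.5,3.6,4.2,4.8,5.0,5.1
OFD,22,3.2,3.3,3.5,4.1,4.8,4.9,5.0
OFD,23,3.1,3.2,3.4,4.0,4.7,4.9,5.0
OFD,24,2.9,3.0,3.2,3.9,4.6,4.8,4.9
OFD,25,2.7,2.9,3.1,3.8,4.5,4.7,4.9
OFD,26,2.5,2.7,2.9,3.7,4.4,4.6,4.8
OFD,27,2.3,2.5,2.7,3.5,4.3,4.5,4.7
OFD,28,2.1,2.3,2.5,3.3,4.2,4.4,4.6
OFD,29,1.9,2.0,2.3,3.2,4.0,4.3,4.4
OFD,30,1.6,1.8,2.1,3.0,3.9,4.1,4.3
OFD,31,1.4,1.6,1.8,2.8,3.7,4.0,4.1
OFD,32,1.1,1.3,1.6,2.5,3.5,3.8,4.0
OFD,33,0.8,1.0,1.3,2.3,3.3,3.6,3.8
OFD,34,0.5,0.7,1.0,2.1,3.1,3.4,3.6
OFD,35,0.2,0.4,0.7,1.8,2.9,3.2,3.4
OFD,36,-0.1,0.1,0.4,1.5,2.6,2.9,3.1
OFD,37,-0.5,-0.3,0.1,1.2,2.4,2.7,2.9
OFD,38,-0.8,-0.6,-0.3,0.9,2.1,2.4,2.6
AC,16,9.4,9.7,10.1,11.8,13.4,13.9,14.2
AC,17,9.1,9.5,9.9,11.6,13.3,13.8,14.1
AC,18,8.9,9.2,9.7,11.5,13.2,13.7,14.0
AC,19,8.7,9.1,9.6,11.3,13.1,13.6,13.9
AC,20,8.5,8.9,9.4,11.2,13.0,13.5,13.9
AC,21,8.3,8.7,9.2,11.1,12.9,13.5,13.8
AC,22,8.1,8.5,9.0,11.0,12.9,13.5,13.8
AC,23,7.9,8.3,8.9,10.9,12.9,13.4,13.8
AC,24,7.7,8.1,8.7,10.8,12.8,13.4,13.8
AC,25,7.5,7.9,8.5,10.7,12.8,13.4,13.8
AC,26,7.3,7.7,8.3,10.6,12.8,13.5,13.9
AC,27,7.0,7.5,8.1,10.5,12.8,13.5,13.9
AC,28,6.8,7.2,7.9,10.4,12.8,13.5,14.0
AC,29,6.5,7.0,7.7,10.3,12.8,13.6,14.0
AC,30,6.3,6.8,7.5,10.2,12.8,13.6,14.1
AC,31,6.0,6.5,7.3,10.1,12.9,13.7,14.2
AC,32,5.7,6.2,7.0,10.0,12.9,13.7,14.3
AC,33,5.4,5.9,6.8,9.9,12.9,13.8,14.4
AC,34,5.0,5.6,6.5,9.7,13.0,13.9,14.5
AC,35,4.7,5.3,6.3,9.6,13.0,14.0,14.6
AC,36,4.3,5.0,6.0,9.5,13.0,14.1,14.7
AC,37,3.9,4.6,5.7,9.4,13.1,14.2,14.8
AC,38,3.5,4.2,5.3,9.2,13.2,14.3,15.0
FL,16,2.7,2.8,2.9,3.2,3.6,3.7,3.7
FL,17,2.6,2.7,2.8,3.1,3.5,3.6,3.6
FL,18,2.5,2.6,2.7,3.0,3.4,3.5,3.5
FL,19,2.4,2.5,2.6,2.9,3.3,3.4,3.4
FL,20,2.3,2.4,2.5,2.8,3.2,3.3,3.3
FL,21,2.2,2.3,2.4,2.7,3.1,3.2,3.3
FL,22,2.1,2.2,2.3,2.6,3.0,3.1,3.2
FL,23,2.0,2.1,2.2,2.6,2.9,3.0,3.1
FL,24,1.9,2.0,2.1,2.5,2.9,3.0,3.0
FL,25,1.8,1.9,2.0,2.4,2.8,2.9,3.0
FL,26,1.7,1.8,1.9,2.3,2.7,2.9,2.9
FL,27,1.7,1.7,1.9,2.3,2.7,2.8,2.9
FL,28,1.6,1.6,1.8,2.2,2.6,2.7,2.8
FL,29,1.5,1.6,1.7,2.1,2.6,2.7,2.8
FL,30,1.4,1.5,1.6,2.0,2.5,2.6,2.7
FL,31,1.3,1.4,1.5,2.0,2.4,2.6,2.6
FL,32,1.2,1.3,1.4,1.9,2.4,2.5,2.6
FL,33,1.1,1.2,1.3,1.8,2.3,2.5,2.5
FL,34,1.0,1.1,1.3,1.8,2.3,2.4,2.5
FL,35,0.9,1.0,1.2,1.7,2.2,2.3,2.4
FL,36,0.8,0.9,1.1,1.6,2.1,2.3,2.4
FL,37,0.7,0.8,1.0,1.5,2.1,2.2,2.3
FL,38,0.6,0.7,0.9,1.4,2.0,2.2,2.3
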