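parameter,lr_mean,lr_lo,lr_hi,br_mean,br_lo,br_hi,lr_re_mean,lr_re_lo,lr_re_hi,br_re_mean,br_re_lo,br_re_hi,lr_re_cov_mean,lr_re_cov_lo,lr_re_cov_hi,br_re_cov_mean,br_re_cov_lo,br_re_cov_hi
intercept,0.964,0.916,1.012,2.024,1.795,2.254,0.938,0.894,0.981,2.175,1.941,2.443,0.857,0.726,0.998,1.666,1.045,2.443
PF2,-0.043,-0.079,-0.006,-0.199,-0.371,-0.028,-0.047,-0.072,-0.022,-0.255,-0.410,-0.096,-0.046,-0.072,-0.021,-0.252,-0.406,-0.098
PF3,-0.044,-0.081,-0.007,-0.204,-0.379,-0.025,-0.046,-0.072,-0.021,-0.243,-0.402,-0.083,-0.046,-0.071,-0.020,-0.238,-0.395,-0.080
PF4,-0.057,-0.094,-0.020,-0.276,-0.447,-0.101,-0.059,-0.084,-0.033,-0.343,-0.497,-0.187,-0.059,-0.084,-0.033,-0.343,-0.502,-0.190
PF5,-0.094,-0.131,-0.057,-0.408,-0.580,-0.236,-0.096,-0.122,-0.071,-0.515,-0.667,-0.363,-0.095,-0.121,-0.069,-0.511,-0.663,-0.359
PF6,-0.171,-0.206,-0.137,-0.740,-0.898,-0.582,-0.165,-0.189,-0.141,-0.797,-0.940,-0.659,-0.165,-0.189,-0.141,-0.796,-0.934,-0.660
RL2,-0.041,-0.070,-0.011,-0.190,-0.326,-0.053,-0.042,-0.075,-0.009,-0.194,-0.377,-0.006,-0.042,-0.075,-0.009,-0.183,-0.374,0.007
RL3,0.005,-0.025,0.035,0.002,-0.136,0.140,-0.024,-0.054,0.006,-0.118,-0.294,0.054,-0.024,-0.054,0.006,-0.110,-0.277,0.063
RL4,-0.056,-0.090,-0.022,-0.227,-0.382,-0.072,-0.109,-0.141,-0.077,-0.488,-0.673,-0.303,-0.108,-0.141,-0.076,-0.475,-0.657,-0.298
SF2,-0.051,-0.081,-0.021,-0.216,-0.360,-0.072,-0.040,-0.062,-0.019,-0.224,-0.361,-0.086,-0.040,-0.062,-0.019,-0.223,-0.359,-0.089
SF3,-0.094,-0.131,-0.058,-0.390,-0.563,-0.216,-0.037,-0.066,-0.009,-0.224,-0.397,-0.052,-0.037,-0.066,-0.008,-0.220,-0.397,-0.045
SF4,-0.110,-0.146,-0.073,-0.468,-0.638,-0.296,-0.058,-0.088,-0.028,-0.333,-0.519,-0.153,-0.058,-0.088,-0.028,-0.331,-0.514,-0.151
SF5,-0.169,-0.203,-0.135,-0.724,-0.883,-0.570,-0.105,-0.133,-0.076,-0.529,-0.693,-0.369,-0.105,-0.133,-0.077,-0.530,-0.692,-0.363
PAIN2,-0.021,-0.058,0.015,-0.102,-0.272,0.072,-0.003,-0.029,0.023,-0.074,-0.231,0.081,-0.003,-0.030,0.023,-0.078,-0.234,0.083
PAIN3,-0.006,-0.043,0.030,-0.042,-0.214,0.129,0.014,-0.012,0.040,0.002,-0.156,0.160,0.013,-0.013,0.039,-0.006,-0.164,0.157
PAIN4,-0.020,-0.057,0.016,-0.091,-0.263,0.085,-0.011,-0.038,0.016,-0.088,-0.252,0.073,-0.011,-0.038,0.016,-0.091,-0.256,0.078
PAIN5,-0.052,-0.089,-0.016,-0.228,-0.397,-0.057,-0.010,-0.039,0.017,-0.132,-0.296,0.031,-0.011,-0.039,0.018,-0.139,-0.303,0.024
PAIN6,-0.107,-0.142,-0.072,-0.481,-0.634,-0.326,-0.086,-0.110,-0.061,-0.428,-0.572,-0.286,-0.086,-0.111,-0.062,-0.434,-0.578,-0.293
MH2,-0.001,-0.030,0.029,0.005,-0.134,0.148,-0.001,-0.023,0.022,-0.027,-0.161,0.108,-0.001,-0.024,0.022,-0.028,-0.163,0.107
MH3,-0.014,-0.051,0.022,-0.086,-0.253,0.087,-0.026,-0.051,-0.000,-0.152,-0.308,0.005,-0.026,-0.052,-0.000,-0.153,-0.308,0.001
MH4,-0.088,-0.124,-0.052,-0.388,-0.558,-0.220,-0.075,-0.101,-0.048,-0.392,-0.548,-0.239,-0.075,-0.102,-0.049,-0.395,-0.547,-0.241
MH5,-0.069,-0.104,-0.035,-0.341,-0.491,-0.187,-0.076,-0.102,-0.051,-0.392,-0.539,-0.248,-0.077,-0.103,-0.051,-0.397,-0.544,-0.250
VIT2,0.001,-0.029,0.030,0.020,-0.119,0.160,0.011,-0.011,0.033,0.016,-0.113,0.144,0.012,-0.010,0.033,0.023,-0.109,0.154
VIT3,0.016,-0.021,0.052,0.091,-0.084,0.264,-0.001,-0.027,0.026,-0.037,-0.199,0.125,0.000,-0.027,0.027,-0.030,-0.191,0.137
VIT4,-0.034,-0.070,0.002,-0.131,-0.300,0.040,-0.017,-0.043,0.009,-0.126,-0.276,0.028,-0.017,-0.043,0.009,-0.127,-0.284,0.028
VIT5,-0.037,-0.072,-0.003,-0.152,-0.304,0.002,-0.051,-0.077,-0.026,-0.246,-0.391,-0.102,-0.050,-0.076,-0.024,-0.240,-0.391,-0.089
AGE,,,,,,,,,,,,,0.001,-0.002,0.003,0.006,-0.007,0.019
GENDER,,,,,,,,,,,,,-0.025,-0.072,0.022,-0.096,-0.317,0.157
DEGREE,,,,,,,,,,,,,0.060,-0.022,0.139,0.298,-0.025,0.633
HOUSING1,,,,,,,,,,,,,-0.029,-0.097,0.041,-0.083,-0.426,0.252
HOUSING2,,,,,,,,,,,,,-0.014,-0.089,0.060,-0.006,-0.382,0.355
INCOME1,,,,,,,,,,,,,0.003,-0.086,0.090,-0.013,-0.417,0.376
INCOME2,,,,,,,,,,,,,0.002,-0.066,0.066,-0.026,-0.317,0.243
MS1,,,,,,,,,,,,,0.067,-0.004,0.141,0.358,-0.006,0.715
MS2,,,,,,,,,,,,,0.069,-0.126,0.270,0.380,-0.527,1.338
phi,,,,6.924,6.334,7.531,,,,9.943,9.793,9.999,,,,9.944,9.794,9.999
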