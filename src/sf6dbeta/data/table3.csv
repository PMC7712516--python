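state_code,observed_mean,lr_re_mean,lr_re_sd,lr_re_sr,br_re_mean,br_re_sd,br_re_sr
121212,0.842,0.876,0.032,-1.129,0.849,0.024,-0.368
132524,0.763,0.841,0.034,-2.367,0.830,0.028,-2.555
211111,0.890,0.909,0.029,-0.637,0.866,0.021,1.172
232111,0.858,0.805,0.033,1.705,0.798,0.031,1.983
321122,0.858,0.848,0.032,0.364,0.842,0.026,0.694
412152,0.793,0.733,0.035,1.606,0.724,0.040,1.666
432621,0.743,0.647,0.039,2.385,0.664,0.054,1.388
523551,0.670,0.701,0.048,-1.920,0.677,0.062,-1.072
614434,0.561,0.742,0.058,-3.123,0.669,0.062,-1.756
642612,0.685,0.458,0.032,6.924,0.462,0.046,4.728
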