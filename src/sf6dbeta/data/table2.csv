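state_code,observed_mean,lr_re_mean,lr_re_sd,br_re_mean,br_re_sd
111621,0.824,0.852,0.023,0.847,0.017
113411,0.854,0.890,0.023,0.865,0.016
115653,0.730,0.671,0.024,0.687,0.028
121212,0.842,0.904,0.023,0.872,0.014
122233,0.869,0.826,0.024,0.816,0.021
122425,0.758,0.793,0.023,0.801,0.021
124125,0.848,0.786,0.023,0.797,0.021
131542,0.828,0.841,0.022,0.824,0.019
132524,0.763,0.846,0.023,0.824,0.019
133132,0.858,0.862,0.022,0.844,0.017
135312,0.756,0.835,0.024,0.824,0.019
142154,0.791,0.696,0.024,0.719,0.027
144341,0.742,0.711,0.026,0.723,0.028
211111,0.890,0.891,0.021,0.872,0.014
212145,0.785,0.725,0.025,0.742,0.027
213323,0.783,0.866,0.026,0.836,0.021
221452,0.824,0.773,0.025,0.778,0.024
224612,0.646,0.717,0.026,0.726,0.029
232111,0.858,0.827,0.022,0.828,0.018
235224,0.767,0.741,0.026,0.739,0.028
241531,0.785,0.746,0.026,0.758,0.028
312332,0.864,0.851,0.025,0.828,0.021
315515,0.698,0.726,0.027,0.735,0.029
321122,0.858,0.861,0.022,0.848,0.016
323644,0.571,0.635,0.029,0.638,0.036
332411,0.844,0.817,0.024,0.817,0.021
334251,0.734,0.730,0.027,0.733,0.030
341123,0.831,0.782,0.027,0.798,0.025
412152,0.793,0.774,0.024,0.773,0.023
414522,0.755,0.821,0.028,0.794,0.026
421314,0.811,0.835,0.025,0.819,0.022
425131,0.658,0.707,0.026,0.722,0.029
431443,0.824,0.770,0.027,0.767,0.027
432621,0.743,0.729,0.024,0.737,0.026
443215,0.731,0.679,0.027,0.689,0.032
511114,0.858,0.825,0.024,0.822,0.020
512242,0.603,0.735,0.025,0.728,0.028
522321,0.777,0.773,0.023,0.771,0.022
523551,0.607,0.676,0.027,0.671,0.032
531635,0.786,0.656,0.026,0.671,0.031
534113,0.723,0.759,0.025,0.763,0.026
545422,0.700,0.628,0.026,0.632,0.032
611221,0.821,0.769,0.024,0.781,0.023
614434,0.561,0.661,0.028,0.663,0.034
622513,0.707,0.680,0.024,0.687,0.029
625141,0.510,0.552,0.026,0.565,0.034
631355,0.741,0.636,0.025,0.650,0.031
633122,0.714,0.722,0.023,0.735,0.025
642612,0.685,0.550,0.022,0.563,0.028
645655,0.322,0.346,0.015,0.331,0.017
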