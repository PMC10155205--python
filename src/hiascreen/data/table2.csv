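threshold,precision,true_positive,false_positive,true_positive_rate
0.5082,0.782,61,17,0.910
0.525,0.779,60,17,0.897
0.55,0.779,60,17,0.896
0.575,0.787,55,15,0.821
0.6,0.779,53,15,0.791
0.625,0.845,49,9,0.731
0.65,0.842,48,9,0.716
0.675,0.849,45,8,0.672
0.7,0.851,40,7,0.597
0.725,0.884,38,5,0.568
0.75,0.909,30,3,0.448
0.775,0.964,27,1,0.403
0.8,0.962,25,1,0.373
0.825,1.0,19,0,0.285
0.85,1.0,16,0,0.239
0.875,1.0,12,0,0.179
0.9,1.0,7,0,0.104

n_positives,67
n_negatives,31
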