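effect_z,se_z,n,significance,country,group
0.268,0.051,387,significant,China,1
0.604,0.050,397,significant,China,1
0.387,0.080,158,significant,China,1
0.165,0.046,469,significant,China,1
0.086,0.053,357,significant,China,1
0.230,0.051,386,significant,China,1
0.727,0.065,243,significant,China,1
0.224,0.036,769,significant,China,1
0.186,0.058,304,significant,China,1
0.149,0.113,81,nonsignificant,China,1
0.333,0.071,201,significant,China,1
0.472,0.050,406,significant,China,1
0.205,0.056,325,significant,China,1
0.198,0.054,345,significant,China,1
0.217,0.086,139,significant,China,1
0.950,0.084,146,significant,China,1
0.406,0.065,237,significant,China,1
0.471,0.072,197,significant,China,1
0.519,0.065,239,significant,China,1
0.180,0.047,462,significant,China,1
0.105,0.071,201,nonsignificant,China,1
0.289,0.040,624,significant,China,1
0.286,0.064,247,significant,China,1
0.377,0.039,668,significant,China,1
0.446,0.051,386,significant,China,1
0.157,0.043,552,nonsignificant,China,1
0.258,0.047,450,significant,China,1
0.401,0.096,111,significant,China,1
1.040,0.077,171,significant,China,1
0.586,0.028,1292,significant,China,1
0.224,0.046,475,significant,China,1
0.236,0.037,725,significant,China,1
0.422,0.033,913,significant,Bangladesh,2
0.586,0.075,181,significant,France,2
0.132,0.062,267,nonsignificant,France,2
0.202,0.125,67,nonsignificant,France,2
0.633,0.070,206,significant,multiple,2
0.102,0.056,320,nonsignificant,Ghana,2
0.319,0.039,645,significant,Ghana,2
0.401,0.050,400,significant,India,2
0.421,0.086,139,significant,India,2
0.283,0.043,534,significant,India,2
0.150,0.052,372,significant,India,2
0.119,0.082,153,nonsignificant,India,2
0.306,0.065,238,significant,India,2
0.415,0.036,772,significant,Indonesia,2
0.549,0.054,341,significant,Iraq,2
0.245,0.069,212,significant,Italy,2
0.413,0.066,233,significant,Japan,2
0.265,0.071,200,significant,Jordan,2
0.205,0.051,389,significant,Korea,2
0.321,0.080,159,significant,Korea,2
0.084,0.029,1158,nonsignificant,Korea,2
0.239,0.060,280,significant,Nepal,2
0.190,0.063,259,significant,Oman,2
0.321,0.045,495,significant,Pakistan,2
0.284,0.046,486,significant,The Kingdom of Saudi Arabia,2
0.229,0.046,473,significant,The Kingdom of Saudi Arabia,2
0.189,0.063,256,significant,The Kingdom of Saudi Arabia,2
0.553,0.046,477,significant,South Korea,2
0.574,0.045,487,significant,South Korea,2
0.523,0.034,877,significant,South Korea,2
0.518,0.097,110,significant,Switzerland,2
0.485,0.055,335,significant,Taiwan,2
0.393,0.061,268,significant,Taiwan,2
0.149,0.047,458,significant,Taiwan,2
0.321,0.091,125,significant,Taiwan,2
0.245,0.113,81,significant,Taiwan,2
0.688,0.065,243,significant,Turkey,2
0.041,0.049,426,nonsignificant,Turkey,2
0.230,0.099,106,significant,The United Arab Emirates,2
0.141,0.050,407,nonsignificant,The United States,2
1.157,0.052,376,significant,The United States,2
0.167,0.060,277,significant,The United States,2
0.266,0.092,120,significant,The United States,2
0.848,0.047,450,significant,The United States,2
0.321,0.056,322,significant,Worldwide,2
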