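model,mpe,rmse,dic
LR,0.128,0.053,-689.1
BR,0.126,0.049,-1069
LR+RE,0.089,0.064,-1325
BR+RE,0.084,0.058,-1621
LR+RE+COV,0.089,0.116,-1306
BR+RE+COV,0.084,0.113,-1605
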