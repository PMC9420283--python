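outcome_id,dalys
breast_cancer,1292000
colorectal_cancer,1397600
cvd,16900400
t2d,4275100
stroke,3473500
hypertension,1342400
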