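set,actual,DI0,DI1,DI2,DI3,DI4,DI5
calibration,0,29,1,0,0,0,0
calibration,1,4,42,0,0,0,0
calibration,2,0,1,45,0,0,0
calibration,3,0,0,1,44,1,0
calibration,4,0,1,0,2,43,0
calibration,5,0,0,0,0,1,28
prediction,0,15,0,0,0,0,0
prediction,1,4,19,0,0,0,0
prediction,2,0,1,22,0,0,0
prediction,3,0,0,0,23,0,0
prediction,4,0,0,0,1,22,0
prediction,5,0,0,0,0,0,15
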