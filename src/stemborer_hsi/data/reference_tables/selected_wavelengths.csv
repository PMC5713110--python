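set,actual,DI0,DI1,DI2,DI3,DI4,DI5
calibration,0,24,2,1,0,3,0
calibration,1,5,40,0,0,1,0
calibration,2,0,0,45,1,0,0
calibration,3,0,0,1,44,0,1
calibration,4,0,1,0,0,44,1
calibration,5,0,0,0,0,1,28
prediction,0,13,0,1,0,1,0
prediction,1,4,18,0,0,1,0
prediction,2,0,0,22,1,0,0
prediction,3,0,0,0,22,0,1
prediction,4,0,0,0,0,22,1
prediction,5,0,0,0,0,1,14
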