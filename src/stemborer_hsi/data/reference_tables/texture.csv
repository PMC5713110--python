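set,actual,DI0,DI1,DI2,DI3,DI4,DI5
calibration,0,30,0,0,0,0,0
calibration,1,9,25,3,5,3,1
calibration,2,0,1,32,10,1,2
calibration,3,0,5,10,26,2,3
calibration,4,0,0,2,1,38,5
calibration,5,0,0,0,4,2,23
prediction,0,15,0,0,0,0,0
prediction,1,3,12,2,3,3,0
prediction,2,0,0,16,4,1,2
prediction,3,0,2,6,14,0,1
prediction,4,0,0,1,0,19,3
prediction,5,0,0,0,2,0,13
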