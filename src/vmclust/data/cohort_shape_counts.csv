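sex,phase,shape,count
boy,1,downslope,276
boy,1,early_peak,575
boy,1,early_trough,42
boy,1,peak,154
boy,1,trough,160
boy,1,upslope,305
girl,1,downslope,698
girl,1,early_peak,642
girl,1,early_trough,80
girl,1,peak,272
girl,1,trough,278
girl,1,upslope,532
boy,2,downslope,207
boy,2,early_peak,78
boy,2,early_trough,4
boy,2,peak,10
boy,2,trough,55
boy,2,upslope,10
girl,2,downslope,152
girl,2,early_peak,178
girl,2,early_trough,3
girl,2,peak,38
girl,2,trough,28
girl,2,upslope,20
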