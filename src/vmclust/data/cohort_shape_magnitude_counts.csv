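sex,phase,shape,magnitude,count
boy,1,early_peak,small,291
boy,1,early_peak,large,284
boy,1,peak,small,101
boy,1,peak,large,53
boy,1,downslope,small,198
boy,1,downslope,large,78
boy,1,upslope,small,166
boy,1,upslope,large,139
boy,1,trough,small,114
boy,1,trough,medium,43
boy,1,trough,large,3
boy,1,early_trough,small,31
boy,1,early_trough,medium,9
boy,1,early_trough,large,2
girl,1,early_peak,small,335
girl,1,early_peak,large,307
girl,1,peak,small,206
girl,1,peak,large,66
girl,1,downslope,small,478
girl,1,downslope,large,220
girl,1,upslope,small,328
girl,1,upslope,large,204
girl,1,trough,small,199
girl,1,trough,medium,70
girl,1,trough,large,9
girl,1,early_trough,small,67
girl,1,early_trough,medium,12
girl,1,early_trough,large,1
boy,2,early_peak,small,58
boy,2,early_peak,large,20
boy,2,peak,small,10
boy,2,peak,large,0
boy,2,downslope,small,83
boy,2,downslope,large,124
boy,2,upslope,small,7
boy,2,upslope,large,3
boy,2,trough,small,14
boy,2,trough,medium,24
boy,2,trough,large,17
boy,2,early_trough,small,3
boy,2,early_trough,medium,1
boy,2,early_trough,large,0
girl,2,early_peak,small,130
girl,2,early_peak,large,48
girl,2,peak,small,33
girl,2,peak,large,5
girl,2,downslope,small,77
girl,2,downslope,large,75
girl,2,upslope,small,18
girl,2,upslope,large,2
girl,2,trough,small,15
girl,2,trough,medium,9
girl,2,trough,large,4
girl,2,early_trough,small,3
girl,2,early_trough,medium,0
girl,2,early_trough,large,0
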