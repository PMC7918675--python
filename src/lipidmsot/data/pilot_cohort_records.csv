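subject,compartment,peak_time_min,relative_increase_pct
1,vein,240,32.1
2,vein,180,170
3,vein,90,95.1
4,vein,240,38.5
1,artery,180,46.4
2,artery,270,0.9
3,artery,240,69.3
4,artery,240,136.9
1,muscle,210,49
2,muscle,270,170.8
3,muscle,120,145.5
4,muscle,120,117.7
1,fat,180,39.7
2,fat,270,25
3,fat,240,11.3
4,fat,180,55.2
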