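instance_id,n_items,sahni_k,dc_complexity,minizinc_props
trial-1,10,1,109,3577
trial-2,10,3,100,1117
trial-3,12,2,117,25961
trial-4,10,0,105,4133
trial-5,12,1,46,6278
trial-6,12,1,143,19417
trial-7,12,4,124,16498
trial-8,10,3,80,9155
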