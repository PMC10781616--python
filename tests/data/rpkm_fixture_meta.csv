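sample,treatment,line,regime,tissue,pool_id
s0,Alone,1,polarization,telencephalon,0
s1,Alone,1,polarization,telencephalon,1
s2,Alone,2,polarization,telencephalon,2
s3,Alone,2,polarization,telencephalon,3
s4,Group,1,polarization,telencephalon,4
s5,Group,1,polarization,telencephalon,5
s6,Group,2,polarization,telencephalon,6
s7,Group,2,polarization,telencephalon,7
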