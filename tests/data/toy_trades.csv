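reporter,partner,year,quantity
AAA,BBB,1990,120.5
AAA,BBB,1991,90.0
AAA,BBB,1992,150.2
CCC,DDD,1990,40.0
CCC,DDD,1992,55.0
EEE,FFF,1991,500.0
EEE,FFF,1992,480.0
EEE,FFF,1993,510.0
EEE,FFF,1994,495.0
EEE,FFF,1995,505.0
GGG,HHH,1994,10.0
AAA,DDD,1993,75.0
AAA,DDD,1994,80.0
AAA,DDD,1995,85.0
BBB,AAA,1990,30.0
BBB,AAA,1991,25.0
CCC,BBB,1991,0.0
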