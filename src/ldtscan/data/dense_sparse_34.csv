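marker,chromosome,position_cM
m001,1,0
m002,1,2
m003,1,4
m004,1,6
m005,1,8
m006,1,10
m007,1,12
m008,1,14
m009,1,16
m010,1,18
m011,1,20
m012,1,22
m013,1,38
m014,1,54
m015,1,70
m016,1,86
m017,1,102
m018,1,118
m019,1,134
m020,1,150
m021,1,166
m022,1,182
m023,1,184
m024,1,186
m025,1,188
m026,1,190
m027,1,192
m028,1,194
m029,1,196
m030,1,198
m031,1,200
m032,1,202
m033,1,204
m034,1,206
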