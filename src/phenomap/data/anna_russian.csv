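num,perimeter,area,max_width,max_height,curved_height,shape_index_1,shape_index_2,curved_shape_index
01,787.2,41884,228,237,252.3,1.04,0.98,1.12
02,813.1,43809,230,245,268.6,1.07,1.04,1.22
03,719.4,34326,192,237,261.4,1.23,1.23,1.37
04,719.4,34807,189,238,262.9,1.26,1.27,1.42
05,762.4,39612,218,248,276.9,1.14,1.14,1.28
06,793.6,41503,221,256,286.0,1.16,1.15,1.33
07,753.1,37440,221,224,266.4,1.01,0.98,1.22
08,746.7,38172,220,220,263.9,1.00,0.99,1.23
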