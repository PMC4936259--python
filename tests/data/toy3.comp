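Order  = A C D E F G H I K L M N P Q R S T V W Y
Mixture= 0.350000
Alpha= 0.400000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000 0.020000
Mixture= 0.450000
Alpha= 10.000000 0.830000 0.140000 0.540000 0.670000 0.390000 0.710000 0.220000 0.580000 0.580000 0.970000 0.240000 0.410000 0.470000 0.390000 0.550000 0.660000 0.530000 0.690000 0.110000 0.320000
Mixture= 0.200000
Alpha= 20.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000 1.000000
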