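# 32-channel 10-20 montage, unit-sphere positions (label x y z)
Fp1 -0.329991 0.940726 -0.078359
Fpz 0.001272 0.999811 -0.019408
Fp2 0.330899 0.940402 -0.078426
F7 -0.847627 0.512395 -0.137767
F3 -0.595220 0.629189 0.499834
Fz 0.003526 0.660786 0.750566
F4 0.606623 0.635512 0.477633
F8 0.846108 0.514567 -0.139004
FC5 -0.929019 0.224309 0.294293
FC1 -0.375357 0.286639 0.881445
FC2 0.386023 0.293400 0.874587
FC6 0.929583 0.233006 0.285628
T7 -0.976571 -0.185874 -0.108447
C3 -0.706876 -0.125802 0.696060
Cz 0.003983 -0.091066 0.995837
C4 0.720988 -0.117092 0.682983
T8 0.978884 -0.172815 -0.109187
CP5 -0.818335 -0.478616 0.318205
CP1 -0.326425 -0.434692 0.839339
CPz 0.003504 -0.429705 0.902963
CP2 0.351645 -0.431251 0.830884
CP6 0.831488 -0.460056 0.311412
P7 -0.701950 -0.711819 -0.024101
P3 -0.480960 -0.714878 0.507570
Pz 0.002804 -0.700597 0.713552
P4 0.498504 -0.703519 0.506513
P8 0.706832 -0.706954 -0.024575
POz 0.001891 -0.896107 0.443835
O1 -0.252329 -0.964666 0.075827
Oz 0.000929 -0.991960 0.126546
O2 0.256398 -0.963610 0.075607
AFz 0.002623 0.915822 0.401576
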