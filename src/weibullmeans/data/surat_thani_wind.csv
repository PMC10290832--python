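group,value
khiri_rat_nikhom,1.0289
khiri_rat_nikhom,1.0289
khiri_rat_nikhom,1.1832
khiri_rat_nikhom,0.9774
khiri_rat_nikhom,0.9260
khiri_rat_nikhom,0.6688
khiri_rat_nikhom,0.7717
khiri_rat_nikhom,0.7717
khiri_rat_nikhom,0.8231
khiri_rat_nikhom,0.8746
khiri_rat_nikhom,1.0803
khiri_rat_nikhom,0.8746
khiri_rat_nikhom,1.0803
khiri_rat_nikhom,0.9260
khiri_rat_nikhom,1.0289
khiri_rat_nikhom,0.8231
khiri_rat_nikhom,0.6688
khiri_rat_nikhom,0.9774
khiri_rat_nikhom,1.2347
khiri_rat_nikhom,0.7717
khiri_rat_nikhom,0.9774
khiri_rat_nikhom,0.7202
khiri_rat_nikhom,1.1832
khiri_rat_nikhom,1.0289
khiri_rat_nikhom,0.7717
khiri_rat_nikhom,0.6688
khiri_rat_nikhom,0.9774
khiri_rat_nikhom,0.8746
khiri_rat_nikhom,1.0803
khiri_rat_nikhom,1.0803
khiri_rat_nikhom,0.7717
khiri_rat_nikhom,0.8746
khiri_rat_nikhom,0.8746
khiri_rat_nikhom,0.8746
khiri_rat_nikhom,0.6688
khiri_rat_nikhom,0.5659
khiri_rat_nikhom,0.9774
khiri_rat_nikhom,0.6173
khiri_rat_nikhom,0.7202
khiri_rat_nikhom,0.6173
khiri_rat_nikhom,0.8231
khiri_rat_nikhom,0.7202
khiri_rat_nikhom,0.5659
khiri_rat_nikhom,0.5144
khiri_rat_nikhom,0.5144
khiri_rat_nikhom,0.6173
khiri_rat_nikhom,0.6688
khiri_rat_nikhom,0.5659
khiri_rat_nikhom,0.6173
khiri_rat_nikhom,0.4116
koh_samui,0.9774
koh_samui,0.7717
koh_samui,0.5659
koh_samui,0.5659
koh_samui,1.2347
koh_samui,1.2347
koh_samui,1.3376
koh_samui,0.9260
koh_samui,0.9774
koh_samui,1.0289
koh_samui,0.5659
koh_samui,0.7717
koh_samui,0.4630
koh_samui,0.5144
koh_samui,1.3890
koh_samui,1.2861
koh_samui,1.3376
koh_samui,1.0289
koh_samui,1.2347
koh_samui,1.1318
koh_samui,0.6173
koh_samui,0.9774
koh_samui,0.9260
koh_samui,0.8746
koh_samui,1.4919
koh_samui,1.2347
koh_samui,1.6462
koh_samui,1.1832
koh_samui,1.2347
koh_samui,1.1318
koh_samui,0.2572
koh_samui,0.7202
koh_samui,0.8231
koh_samui,0.9774
koh_samui,1.2347
koh_samui,1.3890
koh_samui,1.7491
koh_samui,1.2347
koh_samui,1.2347
koh_samui,1.1832
koh_samui,0.6688
koh_samui,1.2347
koh_samui,0.8746
koh_samui,1.0803
koh_samui,1.2861
koh_samui,1.1318
koh_samui,1.8520
koh_samui,1.0803
koh_samui,1.2347
koh_samui,1.3376
kanchanadit,0.2572
kanchanadit,0.3601
kanchanadit,0.6173
kanchanadit,1.0289
kanchanadit,0.9260
kanchanadit,0.4116
kanchanadit,0.9774
kanchanadit,0.8746
kanchanadit,0.9260
kanchanadit,0.8746
kanchanadit,0.2572
kanchanadit,0.3601
kanchanadit,0.5659
kanchanadit,0.8231
kanchanadit,1.1318
kanchanadit,0.7202
kanchanadit,0.8231
kanchanadit,1.1318
kanchanadit,1.3890
kanchanadit,0.8231
kanchanadit,0.2572
kanchanadit,0.3601
kanchanadit,0.7202
kanchanadit,0.8231
kanchanadit,0.7202
kanchanadit,0.5659
kanchanadit,1.1832
kanchanadit,1.0289
kanchanadit,1.0289
kanchanadit,1.2861
kanchanadit,0.1029
kanchanadit,0.4630
kanchanadit,0.7202
kanchanadit,0.6173
kanchanadit,0.6173
kanchanadit,0.6173
kanchanadit,1.2347
kanchanadit,0.8231
kanchanadit,0.4630
kanchanadit,0.5659
kanchanadit,0.1543
kanchanadit,0.3087
kanchanadit,0.3087
kanchanadit,0.3601
kanchanadit,0.3087
kanchanadit,0.4630
kanchanadit,0.8746
kanchanadit,0.6173
kanchanadit,0.3087
kanchanadit,0.2572
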