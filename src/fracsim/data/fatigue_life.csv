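sigma_MPa,temperature_C,rho_g_cm3,cycles_to_failure
35,21,1.4,1.90108e+07
35,21,1.7,8.10961e+07
35,21,1.95,2.71644e+08
35,37,1.4,1.86638e+06
35,37,1.7,7.96159e+06
35,37,1.95,2.66686e+07
35,45,1.4,584790
35,45,1.7,2.49459e+06
35,45,1.95,8.35603e+06
45,21,1.4,1.39316e+06
45,21,1.7,5.94292e+06
45,21,1.95,1.99067e+07
45,37,1.4,136773
45,37,1.7,583445
45,37,1.95,1.95434e+06
45,45,1.4,42854.9
45,45,1.7,182810
45,45,1.95,612350
60,21,1.4,69823.2
60,21,1.7,297852
60,21,1.95,997700
60,37,1.4,6854.88
60,37,1.7,29241.5
60,37,1.95,97949
60,45,1.4,2147.83
60,45,1.7,9162.2
60,45,1.95,30690.2
80,21,1.4,3507.52
80,21,1.7,14962.4
80,21,1.95,50118.7
80,37,1.4,344.35
80,37,1.7,1468.93
80,37,1.95,4920.4
80,45,1.4,107.895
80,45,1.7,460.257
80,45,1.95,1541.7
100,21,1.4,344.35
100,21,1.7,1468.93
100,21,1.95,4920.4
100,37,1.4,33.8065
100,37,1.7,144.212
100,37,1.95,483.059
100,45,1.4,10.5925
100,45,1.7,45.1856
100,45,1.95,151.356
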