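"1","2","3","4"
0,0,0,0
5.1936501e-05,-0.017163241449,0.051489724348,-0.034326482899
0.000415492009,-0.034168463221,0.102505389663,-0.068336926442
0.001402285531,-0.050857645637,0.152572936912,-0.101715291275
0.003323936073,-0.067072769021,0.201218307062,-0.134145538041
0.006492062642,-0.082655813693,0.247967441079,-0.165311627386
0.011218284245,-0.097448759977,0.292346279932,-0.194897519955
0.017814219889,-0.111293588195,0.333880764586,-0.222587176391
0.026591488581,-0.12403227867,0.372096836009,-0.24806455734
0.037861709328,-0.135506811723,0.406520435168,-0.271013623445
0.051936501135,-0.145559167677,0.43667750303,-0.291118335353
0.069127483011,-0.154031326854,0.462093980561,-0.308062653707
0.089746273962,-0.160765269576,0.482295808729,-0.321530539153
0.114104492994,-0.165602976167,0.496808928501,-0.331205952334
0.142513759115,-0.168386426948,0.505159280843,-0.336772853895
0.1752824453,-0.168957877472,0.506876066939,-0.337917377959
0.212326154735,-0.167192886239,0.501882974153,-0.334588649435
0.252797673245,-0.163031691023,0.490869840693,-0.327246560462
0.295762143809,-0.156421960834,0.474614530611,-0.316409687074
0.340284709407,-0.147311364682,0.453894907957,-0.302596605305
0.385430513019,-0.135647571578,0.429488836783,-0.286325891188
0.430264697624,-0.121378250532,0.402174181139,-0.268116120759
0.473852406202,-0.104451070554,0.372728805077,-0.248485870051
0.515258781732,-0.084813700654,0.341930572648,-0.227953715098
0.553548967194,-0.062413809842,0.310557347902,-0.207038231935
0.587788105567,-0.037199067129,0.279386994891,-0.186257996594
0.617041339832,-0.009117141525,0.249197377665,-0.16613158511
0.640373812967,0.021884297961,0.220766360276,-0.147177573517
0.656850667952,0.055857582318,0.194871806775,-0.12991453785
0.665537047767,0.092855042535,0.172291581212,-0.114861054141
0.665537047767,0.132910552943,0.153781012867,-0.102514183182
0.656850667952,0.175633484696,0.139577131255,-0.092876135145
0.640373812967,0.220208705772,0.129398666132,-0.085454269591
0.617041339832,0.265802627492,0.122941812479,-0.079734430833
0.587788105567,0.311581661173,0.119902765278,-0.075202463186
0.553548967194,0.356712218134,0.119977719511,-0.071344210964
0.515258781732,0.400360709695,0.12286287016,-0.067645518483
0.473852406202,0.441693547174,0.128254412208,-0.063592230056
0.430264697624,0.47987714189,0.135848540636,-0.058670189998
0.385430513019,0.514077905162,0.145341450427,-0.052365242624
0.340284709407,0.543462248309,0.156429336562,-0.044163232248
0.295762143809,0.56719658265,0.168808394023,-0.033550003185
0.252797673245,0.584447319503,0.182174817793,-0.020011399749
0.212326154735,0.594380870188,0.196224802853,-0.003033266255
0.1752824453,0.596163646023,0.210654544186,0.017898552983
0.142513759115,0.589064491455,0.225181598063,0.043240151367
0.114104492994,0.573243798515,0.239709443099,0.072942265391
0.089746273962,0.549321011398,0.254237288136,0.106695426504
0.069127483011,0.517919368118,0.268765133172,0.144188015699
0.051936501135,0.479662106688,0.283292978208,0.185108413968
0.037861709328,0.435172465122,0.297820823245,0.229145002306
0.026591488581,0.385073681433,0.312348668281,0.275986161705
0.017814219889,0.329988993635,0.326876513317,0.325320273158
0.011218284245,0.270541639742,0.341404358354,0.376835717659
0.006492062642,0.207354857767,0.35593220339,0.430220876201
0.003323936073,0.141051885724,0.370460048426,0.485164129777
0.001402285531,0.072255961626,0.384987893462,0.541353859381
0.000415492009,0.001590323488,0.399515738499,0.598478446004
5.1936501e-05,-0.070321790678,0.414043583535,0.656226270642
0,-0.142857142857,0.428571428571,0.714285714286
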