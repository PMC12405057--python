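1.525878906250000000e-05
5.086263020833333051e-06
1.017252604166666610e-05
1.017252604166666610e-05
2.034505208333333220e-05
3.051757812500000000e-05
3.560384114583333559e-05
1.525878906250000000e-05
7.120768229166667118e-05
4.069010416666666441e-05
7.120768229166667118e-05
8.646647135416667118e-05
2.593994140625000000e-04
1.373291015625000000e-04
1.576741536458333424e-04
1.322428385416666576e-04
2.237955729166666576e-04
1.881917317708333424e-04
2.848307291666666847e-04
3.356933593750000000e-04
3.153483072916666847e-04
4.069010416666666847e-04
4.119873046875000000e-04
4.323323567708333153e-04
4.272460937500000000e-04
4.526774088541666847e-04
4.730224609375000000e-04
5.391438802083333695e-04
5.238850911458333695e-04
4.882812500000000000e-04
5.086263020833333695e-04
4.984537760416666305e-04
6.713867187500000000e-04
6.001790364583333695e-04
6.103515625000000000e-04
6.764729817708333695e-04
6.205240885416666305e-04
6.612141927083333695e-04
6.459554036458333695e-04
5.950927734375000000e-04
6.205240885416666305e-04
5.696614583333333695e-04
6.357828776041666305e-04
4.984537760416666305e-04
5.035400390625000000e-04
5.594889322916666305e-04
5.849202473958333695e-04
5.645751953125000000e-04
6.408691406250000000e-04
7.629394531250000000e-04
7.222493489583333695e-04
6.713867187500000000e-04
6.713867187500000000e-04
7.476806640625000000e-04
8.036295572916666305e-04
7.476806640625000000e-04
7.832845052083333695e-04
8.138020833333333695e-04
8.036295572916666305e-04
8.036295572916666305e-04
8.900960286458333695e-04
8.290608723958333695e-04
9.206136067708333695e-04
8.544921875000000000e-04
1.012166341145833261e-03
8.138020833333333695e-04
9.104410807291666305e-04
8.392333984375000000e-04
9.663899739583333695e-04
9.460449218750000000e-04
8.036295572916666305e-04
8.239746093750000000e-04
7.629394531250000000e-04
8.188883463541666305e-04
7.781982421875000000e-04
6.612141927083333695e-04
6.459554036458333695e-04
6.001790364583333695e-04
6.103515625000000000e-04
5.950927734375000000e-04
4.781087239583333153e-04
4.933675130208333695e-04
4.475911458333333153e-04
3.509521484375000000e-04
3.407796223958333153e-04
2.593994140625000000e-04
2.644856770833333153e-04
2.644856770833333153e-04
1.983642578125000000e-04
2.441406250000000000e-04
1.831054687500000000e-04
2.288818359375000000e-04
1.627604166666666576e-04
2.187093098958333424e-04
1.729329427083333424e-04
1.068115234375000000e-04
8.138020833333332882e-05
7.120768229166667118e-05
8.646647135416667118e-05
7.120768229166667118e-05
8.138020833333332882e-05
5.086263020833333559e-05
8.138020833333332882e-05
3.560384114583333559e-05
5.086263020833333559e-05
4.069010416666666441e-05
4.069010416666666441e-05
4.069010416666666441e-05
2.034505208333333220e-05
2.034505208333333220e-05
2.034505208333333220e-05
5.086263020833333051e-06
1.525878906250000000e-05
2.034505208333333220e-05
5.086263020833333051e-06
5.086263020833333051e-06
1.017252604166666610e-05
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
5.086263020833333051e-06
0.000000000000000000e+00
5.086263020833333051e-06
0.000000000000000000e+00
5.086263020833333051e-06
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
5.086263020833333051e-06
5.086263020833333051e-06
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
5.086263020833333051e-06
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
5.086263020833333051e-06
0.000000000000000000e+00
2.034505208333333220e-05
5.086263020833333051e-06
1.525878906250000000e-05
5.086263020833333051e-06
5.086263020833333051e-06
6.103515625000000000e-05
4.577636718750000000e-05
3.051757812500000000e-05
4.577636718750000000e-05
5.594889322916666441e-05
3.051757812500000000e-05
8.646647135416667118e-05
7.120768229166667118e-05
1.271565755208333424e-04
5.594889322916666441e-05
1.118977864583333288e-04
1.271565755208333424e-04
1.424153645833333424e-04
1.424153645833333424e-04
1.220703125000000000e-04
1.678466796875000000e-04
1.881917317708333424e-04
2.492268880208333153e-04
2.237955729166666576e-04
1.983642578125000000e-04
1.729329427083333424e-04
1.831054687500000000e-04
2.797444661458333153e-04
2.950032552083333153e-04
2.797444661458333153e-04
3.000895182291666847e-04
3.865559895833333153e-04
3.560384114583333153e-04
4.170735677083333153e-04
4.933675130208333695e-04
4.577636718750000000e-04
4.272460937500000000e-04
6.052652994791666305e-04
6.866455078125000000e-04
5.493164062500000000e-04
7.222493489583333695e-04
7.222493489583333695e-04
7.069905598958333695e-04
7.375081380208333695e-04
8.036295572916666305e-04
8.799235026041666305e-04
7.934570312500000000e-04
1.073201497395833261e-03
9.562174479166666305e-04
9.867350260416667389e-04
1.251220703125000000e-03
1.312255859375000000e-03
1.403808593750000000e-03
1.500447591145833261e-03
1.953125000000000000e-03
1.983642578125000000e-03
2.380371093750000000e-03
2.766927083333333478e-03
3.362019856770833478e-03
4.084269205729166956e-03
4.674275716145833044e-03
5.488077799479166956e-03
6.632486979166666956e-03
7.522583007812500000e-03
8.565266927083333912e-03
1.025390625000000000e-02
1.172383626302083391e-02
1.275634765625000000e-02
1.436869303385416609e-02
1.607259114583333218e-02
1.725769042968750000e-02
1.881917317708333218e-02
2.051798502604166782e-02
2.064005533854166782e-02
2.242533365885416782e-02
2.411905924479166782e-02
2.519226074218750000e-02
2.578226725260416782e-02
2.612304687500000000e-02
2.688598632812500000e-02
2.813720703125000000e-02
2.785237630208333218e-02
2.801513671875000000e-02
2.761840820312500000e-02
2.747090657552083218e-02
2.861531575520833218e-02
2.833048502604166782e-02
2.798461914062500000e-02
2.768961588541666782e-02
2.756245930989583218e-02
2.689615885416666782e-02
2.556864420572916782e-02
2.440897623697916782e-02
2.310689290364583218e-02
2.231343587239583218e-02
2.155558268229166782e-02
1.988728841145833218e-02
1.872253417968750000e-02
1.764424641927083218e-02
1.640319824218750000e-02
1.415506998697916609e-02
1.318868001302083391e-02
1.111348470052083391e-02
9.892781575520833912e-03
4.385375976562500000e-02
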