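0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
0.000000000000000000e+00
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
5.086263020833333051e-06
0.000000000000000000e+00
5.086263020833333051e-06
0.000000000000000000e+00
5.086263020833333051e-06
5.086263020833333051e-06
1.017252604166666610e-05
5.086263020833333051e-06
0.000000000000000000e+00
1.525878906250000000e-05
1.525878906250000000e-05
1.017252604166666610e-05
5.086263020833333051e-06
1.525878906250000000e-05
1.525878906250000000e-05
1.525878906250000000e-05
1.525878906250000000e-05
3.560384114583333559e-05
5.086263020833333051e-06
2.034505208333333220e-05
1.525878906250000000e-05
2.034505208333333220e-05
1.525878906250000000e-05
1.017252604166666610e-05
1.017252604166666610e-05
3.560384114583333559e-05
3.051757812500000000e-05
4.577636718750000000e-05
3.051757812500000000e-05
7.629394531250000000e-05
9.155273437500000000e-05
1.118977864583333288e-04
1.881917317708333424e-04
1.322428385416666576e-04
1.271565755208333424e-04
1.780192057291666576e-04
2.034505208333333424e-04
1.932779947916666576e-04
2.441406250000000000e-04
2.593994140625000000e-04
2.543131510416666847e-04
2.339680989583333424e-04
2.492268880208333153e-04
3.356933593750000000e-04
3.000895182291666847e-04
3.356933593750000000e-04
3.255208333333333153e-04
3.712972005208333153e-04
3.153483072916666847e-04
3.204345703125000000e-04
3.458658854166666847e-04
3.763834635416666847e-04
4.069010416666666847e-04
3.560384114583333153e-04
4.730224609375000000e-04
4.730224609375000000e-04
5.289713541666666305e-04
4.730224609375000000e-04
6.205240885416666305e-04
5.391438802083333695e-04
5.696614583333333695e-04
6.459554036458333695e-04
6.764729817708333695e-04
6.561279296875000000e-04
6.459554036458333695e-04
6.357828776041666305e-04
7.476806640625000000e-04
8.138020833333333695e-04
6.968180338541666305e-04
7.985432942708333695e-04
7.629394531250000000e-04
7.781982421875000000e-04
6.917317708333333695e-04
6.764729817708333695e-04
7.069905598958333695e-04
7.731119791666666305e-04
7.985432942708333695e-04
9.206136067708333695e-04
7.273356119791666305e-04
8.748372395833333695e-04
6.968180338541666305e-04
9.002685546875000000e-04
7.120768229166666305e-04
8.188883463541666305e-04
7.324218750000000000e-04
8.341471354166666305e-04
7.985432942708333695e-04
6.561279296875000000e-04
7.680257161458333695e-04
6.866455078125000000e-04
7.883707682291666305e-04
6.561279296875000000e-04
6.663004557291666305e-04
7.324218750000000000e-04
7.680257161458333695e-04
5.594889322916666305e-04
6.713867187500000000e-04
6.205240885416666305e-04
5.696614583333333695e-04
7.527669270833333695e-04
7.069905598958333695e-04
5.950927734375000000e-04
5.950927734375000000e-04
6.052652994791666305e-04
6.917317708333333695e-04
6.968180338541666305e-04
6.713867187500000000e-04
6.357828776041666305e-04
6.306966145833333695e-04
6.459554036458333695e-04
6.764729817708333695e-04
5.594889322916666305e-04
5.696614583333333695e-04
6.866455078125000000e-04
5.900065104166666305e-04
5.544026692708333695e-04
4.933675130208333695e-04
6.154378255208333695e-04
5.289713541666666305e-04
5.238850911458333695e-04
5.747477213541666305e-04
5.493164062500000000e-04
6.001790364583333695e-04
5.187988281250000000e-04
5.391438802083333695e-04
4.374186197916666847e-04
4.272460937500000000e-04
5.035400390625000000e-04
5.696614583333333695e-04
4.984537760416666305e-04
5.137125651041666305e-04
5.391438802083333695e-04
6.306966145833333695e-04
5.849202473958333695e-04
5.035400390625000000e-04
4.984537760416666305e-04
5.035400390625000000e-04
4.933675130208333695e-04
4.221598307291666847e-04
5.696614583333333695e-04
6.256103515625000000e-04
5.442301432291666305e-04
6.764729817708333695e-04
5.035400390625000000e-04
5.493164062500000000e-04
5.187988281250000000e-04
5.950927734375000000e-04
5.544026692708333695e-04
6.561279296875000000e-04
5.391438802083333695e-04
6.663004557291666305e-04
6.001790364583333695e-04
7.222493489583333695e-04
8.138020833333333695e-04
6.663004557291666305e-04
5.849202473958333695e-04
7.120768229166666305e-04
7.883707682291666305e-04
7.425944010416666305e-04
7.120768229166666305e-04
7.985432942708333695e-04
8.646647135416666305e-04
8.341471354166666305e-04
7.832845052083333695e-04
1.047770182291666739e-03
8.239746093750000000e-04
9.511311848958333695e-04
8.900960286458333695e-04
8.595784505208333695e-04
8.341471354166666305e-04
7.985432942708333695e-04
7.731119791666666305e-04
8.850097656250000000e-04
8.544921875000000000e-04
9.918212890625000000e-04
1.368204752604166739e-03
1.693725585937500000e-03
2.304077148437500000e-03
3.117879231770833478e-03
4.074096679687500000e-03
5.345662434895833044e-03
6.591796875000000000e-03
8.021036783854166088e-03
9.887695312500000000e-03
1.123555501302083391e-02
1.219177246093750000e-02
1.275634765625000000e-02
1.391092936197916609e-02
1.434326171875000000e-02
1.442972819010416609e-02
1.442972819010416609e-02
1.374308268229166609e-02
1.372782389322916609e-02
1.386006673177083391e-02
1.386515299479166609e-02
1.421101888020833391e-02
1.381937662760416609e-02
1.364135742187500000e-02
1.411437988281250000e-02
1.471964518229166609e-02
1.492818196614583391e-02
1.453653971354166609e-02
1.422119140625000000e-02
1.472981770833333391e-02
1.465352376302083391e-02
1.433308919270833391e-02
1.432800292968750000e-02
1.426696777343750000e-02
1.451110839843750000e-02
1.431274414062500000e-02
1.439412434895833391e-02
1.407877604166666609e-02
1.411946614583333391e-02
1.433817545572916609e-02
1.443481445312500000e-02
1.391601562500000000e-02
1.396179199218750000e-02
1.427205403645833391e-02
1.374308268229166609e-02
1.321919759114583391e-02
1.333109537760416609e-02
1.309712727864583391e-02
1.307678222656250000e-02
1.301574707031250000e-02
1.316833496093750000e-02
1.319376627604166609e-02
1.316324869791666609e-02
1.304117838541666609e-02
1.303609212239583391e-02
1.393636067708333391e-02
1.381937662760416609e-02
1.346842447916666609e-02
1.359558105468750000e-02
1.383463541666666609e-02
1.791534423828125000e-01
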