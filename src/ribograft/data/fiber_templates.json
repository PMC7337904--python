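{
 "comment": "Synthetic idealized fiber templates derived by restrained least squares from CCD ideal base geometry and standard nucleic-acid restraint dictionaries. Standard reference frame: pair plane z=0, +x into the major groove, pair dyad = x axis, C1' anchored at x = -2.476. Backbone solved under each form's helical symmetry (see scripts/build_templates.py). No experimental coordinates.",
 "c1_anchor": [
  -2.476,
  5.39536651154694,
  0.0
 ],
 "forms": {
  "A": {
   "twist": 32.7,
   "rise": 2.548,
   "xdisp": -4.4,
   "inclination": 19.0,
   "pucker_P": 18.0,
   "pucker_amp": 38.0,
   "chi": -157.0
  },
  "B": {
   "twist": 36.0,
   "rise": 3.375,
   "xdisp": 0.2,
   "inclination": -6.0,
   "pucker_P": 155.0,
   "pucker_amp": 38.0,
   "chi": -98.0,
   "p_anchor": [
    8.91,
    95.2,
    -2.08
   ]
  }
 },
 "bases": {
  "G": {
   "N9": [
    -1.31388610143822,
    4.54908908116733,
    0.0
   ],
   "C8": [
    -0.004849416683165408,
    4.932169917258187,
    0.0
   ],
   "N7": [
    0.7630304910026409,
    3.8811884381461823,
    0.0
   ],
   "C5": [
    -0.0053969389305343896,
    2.7647030135740933,
    0.0
   ],
   "C6": [
    0.2720547873875736,
    1.3776421721441372,
    0.0
   ],
   "O6": [
    1.4210725361107235,
    0.9710071502340312,
    0.0
   ],
   "N1": [
    -0.7680190067664099,
    0.5159084542830181,
    0.0
   ],
   "C2": [
    -2.048047776862771,
    0.9813684862158407,
    0.0
   ],
   "N2": [
    -3.08416985849371,
    0.0823257266109394,
    0.0
   ],
   "N3": [
    -2.318913327062279,
    2.267256752339167,
    0.0
   ],
   "C4": [
    -1.3419613091311278,
    3.1812347016045415,
    0.0
   ],
   "C1'": [
    -2.476,
    5.439401538268845,
    0.0
   ]
  },
  "A": {
   "N9": [
    -1.3230151605675096,
    4.461805306410174,
    0.0
   ],
   "C8": [
    -0.011380519463975336,
    4.828246133308083,
    0.0
   ],
   "N7": [
    0.7457266877564508,
    3.7699632260238154,
    0.0
   ],
   "C5": [
    -0.0302561325289723,
    2.6595772072994457,
    0.0
   ],
   "C6": [
    0.22116026560336266,
    1.2776097982681525,
    0.0
   ],
   "N6": [
    1.517804942084366,
    0.7939093585596524,
    0.0
   ],
   "N1": [
    -0.8149671774329865,
    0.44513722436983727,
    0.0
   ],
   "C2": [
    -2.0542365983355433,
    0.8974955695427425,
    0.0
   ],
   "N3": [
    -2.338271405275109,
    2.1823979162614675,
    0.0
   ],
   "C4": [
    -1.3677438311687116,
    3.090907790106669,
    0.0
   ],
   "C1'": [
    -2.476,
    5.366472594856093,
    0.0
   ]
  },
  "C": {
   "N1": [
    -1.3197502641604397,
    4.542479597442752,
    0.0
   ],
   "C2": [
    -1.513017827784448,
    3.2120414984376042,
    0.0
   ],
   "O2": [
    -2.650583595201033,
    2.7707949553433515,
    0.0
   ],
   "N3": [
    -0.4827786716828666,
    2.367654511239217,
    0.0
   ],
   "C4": [
    0.7636570839118448,
    2.8196577447184854,
    0.0
   ],
   "N4": [
    1.8201830944270405,
    1.9385194884412014,
    0.0
   ],
   "C5": [
    0.9997174813781822,
    4.209394232520802,
    0.0
   ],
   "C6": [
    -0.057261748001532276,
    5.054607764846654,
    0.0
   ],
   "C1'": [
    -2.472507773194916,
    5.446011022005107,
    0.0
   ]
  },
  "T": {
   "N1": [
    -1.3353824219259365,
    4.471509039110484,
    0.0
   ],
   "C2": [
    -1.5043947924516294,
    3.0703562543820238,
    0.0
   ],
   "O2": [
    -2.603054356573902,
    2.511967284688925,
    0.0
   ],
   "N3": [
    -0.3173427169445624,
    2.330609503461298,
    0.0
   ],
   "C4": [
    0.9764848876527963,
    2.8295560303965925,
    0.0
   ],
   "O4": [
    1.9784772578774241,
    2.1198993203313767,
    0.0
   ],
   "C5": [
    1.0738067452982443,
    4.313567379804037,
    0.0
   ],
   "C7": [
    2.436043399459244,
    4.9294025953680105,
    0.0
   ],
   "C6": [
    -0.061275392258110184,
    5.024781428271169,
    0.0
   ],
   "C1'": [
    -2.463632738657334,
    5.356768862238144,
    0.0
   ]
  },
  "U": {
   "N1": [
    -1.3048627273108455,
    4.487158570212227,
    0.0
   ],
   "C2": [
    -1.4745181921805424,
    3.1544258640589993,
    0.0
   ],
   "O2": [
    -2.5984685149111253,
    2.69292080304509,
    0.0
   ],
   "N3": [
    -0.4155149117193919,
    2.322380451064302,
    0.0
   ],
   "C4": [
    0.8382720295705619,
    2.818585579370344,
    0.0
   ],
   "O4": [
    1.7962233740620728,
    2.0663242906467034,
    0.0
   ],
   "C5": [
    1.029775418836652,
    4.2201987145448125,
    0.0
   ],
   "C6": [
    -0.04961638135367075,
    5.031605521661604,
    0.0
   ],
   "C1'": [
    -2.475992341203824,
    5.368178540366511,
    0.0
   ]
  }
 },
 "backbones": {
  "A": {
   "P": [
    1.2619406752048545,
    9.329589542113496,
    0.9750045439011348
   ],
   "OP1": [
    2.465087464826505,
    8.552279588569975,
    1.3667340917967812
   ],
   "OP2": [
    0.9397185180721397,
    10.593992780060516,
    1.6840054841999392
   ],
   "O5'": [
    -0.004531364567382742,
    8.365560031015095,
    1.0650743503810303
   ],
   "C5'": [
    -1.2600728279642865,
    8.752942363076082,
    0.47381662001996955
   ],
   "C4'": [
    -2.3032794797590737,
    7.661773800752872,
    0.5419015038188951
   ],
   "O4'": [
    -2.0396761932780683,
    6.655262409355205,
    -0.4744040266412864
   ],
   "C3'": [
    -2.3963994669429645,
    6.869724554794259,
    1.8407154903376586
   ],
   "O3'": [
    -3.1885779674150725,
    7.522493650954383,
    2.8259617485053656
   ],
   "C2'": [
    -3.0719633496546086,
    5.579808190634166,
    1.3940167966739765
   ],
   "O2'": [
    -4.47268615340854,
    5.751244586179198,
    1.3222241136796504
   ]
  },
  "B": {
   "P": [
    -0.9757809435962783,
    9.221867393901144,
    -1.1131454287448643
   ],
   "OP1": [
    -1.132346317472505,
    10.610634739028681,
    -1.6151788388278865
   ],
   "OP2": [
    -0.006424992598960219,
    8.951160886334325,
    -0.021224173698103508
   ],
   "O5'": [
    -2.4062692895726654,
    8.715063234828326,
    -0.6352219243419094
   ],
   "C5'": [
    -3.3154917055861683,
    8.175967032554754,
    -1.6113527453874648
   ],
   "C4'": [
    -3.919415043770455,
    6.921760309980196,
    -1.0361524219743476
   ],
   "O4'": [
    -2.8678387864114727,
    5.941393434304155,
    -1.2425153511740108
   ],
   "C3'": [
    -4.080489143276433,
    6.986453797499782,
    0.47824110972259176
   ],
   "O3'": [
    -5.214998451898006,
    6.197503511054866,
    0.8113138662071201
   ],
   "C2'": [
    -2.7871887354127964,
    6.438677017295209,
    1.0648580905491478
   ],
   "O2'": [
    -3.0289916147465825,
    5.824047431355199,
    2.31399012516092
   ]
  }
 }
}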