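# Synthetic standard-daylight illuminant expressed as normalised quanta.
# Photon flux of a 6500 K Planckian radiator, peak-normalised; 5 nm steps.
# Generated by flybait.fixtures.synthetic_daylight_quanta(); a stand-in
# for measured D65 quanta tables (excitations are invariant to scale).
wavelength_nm,daylight_quanta
300,0.3875221
305,0.40940072
310,0.43129678
315,0.45315339
320,0.47491644
325,0.49653481
330,0.51796044
335,0.53914845
340,0.56005716
345,0.58064806
350,0.60088586
355,0.62073839
360,0.64017655
365,0.65917422
370,0.67770817
375,0.69575796
380,0.7133058
385,0.73033643
390,0.74683703
395,0.76279702
400,0.77820798
405,0.79306352
410,0.8073591
415,0.82109196
420,0.83426094
425,0.8468664
430,0.85891006
435,0.87039494
440,0.88132517
445,0.89170598
450,0.90154353
455,0.91084482
460,0.91961764
465,0.92787044
470,0.9356123
475,0.94285279
480,0.94960196
485,0.95587025
490,0.9616684
495,0.96700747
500,0.97189871
505,0.97635354
510,0.98038352
515,0.98400029
520,0.98721555
525,0.99004101
530,0.99248836
535,0.99456925
540,0.99629526
545,0.99767789
550,0.9987285
555,0.99945835
560,0.99987854
565,1
570,0.9998335
575,0.99938962
580,0.99867875
585,0.99771106
590,0.99649654
595,0.99504494
600,0.99336581
605,0.99146846
610,0.98936198
615,0.98705525
620,0.9845569
625,0.98187535
630,0.97901877
635,0.97599513
640,0.97281216
645,0.96947735
650,0.96599801
655,0.9623812
660,0.95863376
665,0.95476234
670,0.95077336
675,0.94667305
680,0.94246743
685,0.93816232
690,0.93376334
695,0.92927595
700,0.92470537
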