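# Synthetic typical green-leaf background reflectance (fractions).
# Flat ~5% base + chlorophyll reflectance peak at 555 nm + red edge; 10 nm steps.
# Generated by flybait.fixtures.synthetic_leaf_reflectance(); a stand-in
# for measured leaf reflectance tables.
wavelength_nm,leaf
300,0.05
310,0.05
320,0.05
330,0.05
340,0.05
350,0.05
360,0.05
370,0.050000001
380,0.050000004
390,0.050000027
400,0.05000016
410,0.050000846
420,0.050004007
430,0.050016986
440,0.050064438
450,0.050218749
460,0.050664501
470,0.051806301
480,0.054393693
490,0.059563444
500,0.068627046
510,0.082465247
520,0.10063356
530,0.12066483
540,0.13824969
550,0.14862071
560,0.14862072
570,0.13824971
580,0.12066489
590,0.10063376
600,0.082465945
610,0.068629483
620,0.05957195
630,0.054423377
640,0.051909886
650,0.051025782
660,0.05147651
670,0.054415516
680,0.06474769
690,0.096541491
700,0.17202664
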