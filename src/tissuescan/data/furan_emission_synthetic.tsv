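# furan emission synthetic
# SYNTHETIC parametric stand-in (Gaussian mixture), not measured data;
# replace via a user library directory to use measured spectra.
# columns: wavelength_nm	value (emission shape, unit area (nm^-1))
340.0	4.4638013e-06
342.0	6.6925884e-06
344.0	9.9343724e-06
346.0	1.4599696e-05
348.0	2.1242432e-05
350.0	3.0600021e-05
352.0	4.3641158e-05
354.0	6.1620876e-05
356.0	8.6142311e-05
358.0	0.0001192236
360.0	0.00016336725
362.0	0.00022162809
364.0	0.00029767453
366.0	0.00039583629
368.0	0.00052113061
370.0	0.00067925778
372.0	0.0008765561
374.0	0.0011199068
376.0	0.0014165799
378.0	0.0017740152
380.0	0.0021995338
382.0	0.0026999829
384.0	0.0032813188
386.0	0.0039481433
388.0	0.0047032108
390.0	0.0055469345
392.0	0.0064769222
394.0	0.0074875783
396.0	0.0085698088
398.0	0.0097108656
400.0	0.010894362
402.0	0.012100484
404.0	0.013306404
406.0	0.014486909
408.0	0.01561521
410.0	0.016663912
412.0	0.0176061
414.0	0.018416471
416.0	0.01907246
418.0	0.019555282
420.0	0.019850822
422.0	0.019950325
424.0	0.019850822
426.0	0.019555282
428.0	0.01907246
430.0	0.018416471
432.0	0.0176061
434.0	0.016663912
436.0	0.01561521
438.0	0.014486909
440.0	0.013306404
442.0	0.012100484
444.0	0.010894362
446.0	0.0097108656
448.0	0.0085698088
450.0	0.0074875783
452.0	0.0064769222
454.0	0.0055469345
456.0	0.0047032108
458.0	0.0039481433
460.0	0.0032813188
462.0	0.0026999829
464.0	0.0021995338
466.0	0.0017740152
468.0	0.0014165799
470.0	0.0011199068
472.0	0.0008765561
474.0	0.00067925778
476.0	0.00052113061
478.0	0.00039583629
480.0	0.00029767453
482.0	0.00022162809
484.0	0.00016336725
486.0	0.0001192236
488.0	8.6142311e-05
490.0	6.1620876e-05
492.0	4.3641158e-05
494.0	3.0600021e-05
496.0	2.1242432e-05
498.0	1.4599696e-05
500.0	9.9343724e-06
502.0	6.6925884e-06
504.0	4.4638013e-06
506.0	2.9476278e-06
508.0	1.92707e-06
510.0	1.2473243e-06
512.0	7.993157e-07
514.0	5.0712422e-07
516.0	3.1854253e-07
518.0	1.9809684e-07
520.0	1.2196767e-07
522.0	7.4347941e-08
524.0	4.4869397e-08
526.0	2.6809491e-08
528.0	1.5859298e-08
530.0	9.2883041e-09
532.0	5.3857468e-09
534.0	3.0918078e-09
536.0	1.7572604e-09
538.0	9.8881896e-10
540.0	5.5087684e-10
542.0	3.0384304e-10
544.0	1.6592092e-10
546.0	8.9703632e-11
548.0	4.8014894e-11
550.0	2.5444797e-11
552.0	1.3349932e-11
554.0	6.934516e-12
556.0	3.566238e-12
558.0	1.815773e-12
560.0	9.1531342e-13
562.0	4.5680954e-13
564.0	2.2571351e-13
566.0	1.1041727e-13
568.0	5.3477796e-14
570.0	2.5642895e-14
572.0	1.2173562e-14
574.0	5.7217033e-15
576.0	2.6625027e-15
578.0	1.2266251e-15
580.0	5.5948786e-16
582.0	2.5265422e-16
584.0	1.1295865e-16
586.0	4.9999941e-17
588.0	2.1911724e-17
590.0	9.5069377e-18
592.0	4.0837751e-18
594.0	1.7367609e-18
596.0	7.3126587e-19
598.0	3.0483697e-19
600.0	1.2581054e-19
602.0	5.1407141e-20
604.0	2.0796342e-20
606.0	8.3292807e-21
608.0	3.3028215e-21
610.0	1.296641e-21
612.0	5.0397788e-22
614.0	1.9393681e-22
616.0	7.3886666e-23
618.0	2.7869485e-23
620.0	1.0407559e-23
622.0	3.8479186e-24
624.0	1.40851e-24
626.0	5.1044743e-25
628.0	1.8314673e-25
630.0	6.5058552e-26
632.0	2.288056e-26
634.0	7.9668379e-27
636.0	2.7463909e-27
638.0	9.3733706e-28
640.0	3.1672787e-28
642.0	1.0595802e-28
644.0	3.5094448e-29
646.0	1.1508006e-29
648.0	3.7361024e-30
650.0	1.200866e-30
652.0	3.8214427e-31
654.0	1.2039743e-31
656.0	3.7554688e-32
658.0	1.15976e-32
660.0	3.545922e-33
662.0	1.0733646e-33
664.0	3.2167879e-34
666.0	9.5445318e-35
668.0	2.8037797e-35
670.0	8.154366e-36
672.0	2.3479756e-36
674.0	6.6935113e-37
676.0	1.8891719e-37
678.0	5.2789313e-38
680.0	1.4604194e-38
682.0	4.0000577e-39
684.0	1.0847058e-39
686.0	2.9121565e-40
688.0	7.7405981e-41
690.0	2.0370017e-41
692.0	5.3071982e-42
694.0	1.3689774e-42
696.0	3.4961038e-43
698.0	8.8395347e-44
700.0	2.2127459e-44
702.0	5.4839154e-45
704.0	1.3455722e-45
706.0	3.2687395e-46
708.0	7.861595e-47
710.0	1.8719666e-47
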