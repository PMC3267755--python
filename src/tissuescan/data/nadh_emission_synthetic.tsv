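# nadh emission synthetic
# SYNTHETIC parametric stand-in (Gaussian mixture), not measured data;
# replace via a user library directory to use measured spectra.
# columns: wavelength_nm	value (emission shape, unit area (nm^-1))
340.0	0.00016104675
342.0	0.0001843093
344.0	0.00021045427
346.0	0.00023976371
348.0	0.0002725363
350.0	0.0003090868
352.0	0.00034974521
354.0	0.00039485559
356.0	0.00044477464
358.0	0.00049986985
360.0	0.00056051738
362.0	0.00062709945
364.0	0.00070000149
366.0	0.00077960877
368.0	0.00086630271
370.0	0.00096045679
372.0	0.0010624321
374.0	0.0011725727
376.0	0.0012912001
378.0	0.0014186084
380.0	0.0015550584
382.0	0.001700772
384.0	0.0018559262
386.0	0.0020206473
388.0	0.002195005
390.0	0.0023790071
392.0	0.0025725934
394.0	0.0027756313
396.0	0.0029879106
398.0	0.0032091398
400.0	0.0034389422
402.0	0.0036768535
404.0	0.0039223195
406.0	0.0041746957
408.0	0.0044332466
410.0	0.004697147
412.0	0.0049654844
414.0	0.005237262
416.0	0.0055114032
418.0	0.0057867573
420.0	0.0060621065
422.0	0.0063361735
424.0	0.0066076307
426.0	0.0068751103
428.0	0.0071372151
430.0	0.0073925301
432.0	0.0076396353
434.0	0.0078771181
436.0	0.0081035868
438.0	0.0083176842
440.0	0.0085181008
442.0	0.008703588
444.0	0.0088729713
446.0	0.0090251627
448.0	0.0091591718
450.0	0.0092741171
452.0	0.0093692354
454.0	0.0094438903
456.0	0.0094975791
458.0	0.0095299388
460.0	0.0095407499
462.0	0.0095299388
464.0	0.0094975791
466.0	0.0094438903
468.0	0.0093692354
470.0	0.0092741171
472.0	0.0091591718
474.0	0.0090251627
476.0	0.0088729713
478.0	0.008703588
480.0	0.0085181008
482.0	0.0083176842
484.0	0.0081035868
486.0	0.0078771181
488.0	0.0076396353
490.0	0.0073925301
492.0	0.0071372151
494.0	0.0068751103
496.0	0.0066076307
498.0	0.0063361735
500.0	0.0060621065
502.0	0.0057867573
504.0	0.0055114032
506.0	0.005237262
508.0	0.0049654844
510.0	0.004697147
512.0	0.0044332466
514.0	0.0041746957
516.0	0.0039223195
518.0	0.0036768535
520.0	0.0034389422
522.0	0.0032091398
524.0	0.0029879106
526.0	0.0027756313
528.0	0.0025725934
530.0	0.0023790071
532.0	0.002195005
534.0	0.0020206473
536.0	0.0018559262
538.0	0.001700772
540.0	0.0015550584
542.0	0.0014186084
544.0	0.0012912001
546.0	0.0011725727
548.0	0.0010624321
550.0	0.00096045679
552.0	0.00086630271
554.0	0.00077960877
556.0	0.00070000149
558.0	0.00062709945
560.0	0.00056051738
562.0	0.00049986985
564.0	0.00044477464
566.0	0.00039485559
568.0	0.00034974521
570.0	0.0003090868
572.0	0.0002725363
574.0	0.00023976371
576.0	0.00021045427
578.0	0.0001843093
580.0	0.00016104675
582.0	0.00014040155
584.0	0.00012212569
586.0	0.00010598816
588.0	9.1774679e-05
590.0	7.9287297e-05
592.0	6.8343869e-05
594.0	5.8777446e-05
596.0	5.0435585e-05
598.0	4.3179601e-05
600.0	3.6883777e-05
602.0	3.1434558e-05
604.0	2.6729728e-05
606.0	2.2677591e-05
608.0	1.9196166e-05
610.0	1.6212399e-05
612.0	1.3661403e-05
614.0	1.1485727e-05
616.0	9.6346713e-06
618.0	8.0636285e-06
620.0	6.7334762e-06
622.0	5.6100064e-06
624.0	4.6633991e-06
626.0	3.8677377e-06
628.0	3.200565e-06
630.0	2.6424787e-06
632.0	2.176765e-06
634.0	1.7890678e-06
636.0	1.4670917e-06
638.0	1.2003363e-06
640.0	9.7985948e-07
642.0	7.9806796e-07
644.0	6.4853162e-07
646.0	5.2582066e-07
648.0	4.2536263e-07
650.0	3.4331773e-07
652.0	2.764702e-07
654.0	2.2213431e-07
656.0	1.7807303e-07
658.0	1.4242816e-07
660.0	1.136603e-07
662.0	9.0497571e-08
664.0	7.1891949e-08
666.0	5.6982145e-08
668.0	4.5062215e-08
670.0	3.5555066e-08
672.0	2.7990177e-08
674.0	2.1984926e-08
676.0	1.722898e-08
678.0	1.3471295e-08
680.0	1.0509313e-08
682.0	8.1800224e-09
684.0	6.3525761e-09
686.0	4.9222138e-09
688.0	3.8052769e-09
690.0	2.9351295e-09
692.0	2.2588296e-09
694.0	1.7344225e-09
696.0	1.3287446e-09
698.0	1.0156483e-09
700.0	7.7456944e-10
702.0	5.8937619e-10
704.0	4.4744538e-10
706.0	3.3892427e-10
708.0	2.5614184e-10
710.0	1.931406e-10
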