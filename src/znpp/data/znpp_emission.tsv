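# znpp-spectrum/1
# excitation_nm=none
# integration_time_ms=1.0
# calibrated=true
# rows=251
wavelength_nm	intensity
500.0	2.1722311239216316e-17
501.0	4.9354362533108567e-17
502.0	1.1114549843773263e-16
503.0	2.480875811610649e-16
504.0	5.4886430518307965e-16
505.0	1.2035711441528452e-15
506.0	2.6159254437625122e-15
507.0	5.635413308158616e-15
508.0	1.2032974614762216e-14
509.0	2.546636995137464e-14
510.0	5.342049441577224e-14
511.0	1.1106969482306533e-13
512.0	2.2889171336749797e-13
513.0	4.67532039081593e-13
514.0	9.465411542071139e-13
515.0	1.8993912843019283e-12
516.0	3.777775941752355e-12
517.0	7.44740150651118e-12
518.0	1.455191522836691e-11
519.0	2.818268457388244e-11
520.0	5.409926688347002e-11
521.0	1.0293124264479285e-10
522.0	1.941108752727633e-10
523.0	3.6282678118930323e-10
524.0	6.721955299546273e-10
525.0	1.2343511338619926e-09
526.0	2.246614908725379e-09
527.0	4.052895153398838e-09
528.0	7.24684407869198e-09
529.0	1.2843378502206577e-08
530.0	2.2560902160967893e-08
531.0	3.928081216939855e-08
532.0	6.778775813884843e-08
533.0	1.1594950525907111e-07
534.0	1.9657729044276196e-07
535.0	3.303274047954769e-07
536.0	5.501773183430473e-07
537.0	9.082545350259826e-07
538.0	1.4861384957513797e-06
539.0	2.4102262324491164e-06
540.0	3.874388348235755e-06
541.0	6.1729862135725535e-06
542.0	9.748421081053307e-06
543.0	1.5258789062500007e-05
544.0	2.3672966015087482e-05
545.0	3.6402574213729437e-05
546.0	5.5482795298915545e-05
547.0	8.381685994807313e-05
548.0	0.00012550217610547687
549.0	0.0001862592893935315
550.0	0.00027398793760787855
551.0	0.00039947698271489954
552.0	0.0005772964603312737
553.0	0.000826899719104031
554.0	0.0011739608396918672
555.0	0.0016519663326170382
556.0	0.00230406957944172
557.0	0.0031852007107601747
558.0	0.004364402883094613
559.0	0.00592733782208442
560.0	0.007978869137696798
561.0	0.010645592071341942
562.0	0.014078134649397724
563.0	0.018453010334836414
564.0	0.023973759890837196
565.0	0.030871085015924945
566.0	0.03940165393078941
567.0	0.04984525553268852
568.0	0.0625
569.0	0.0776753151503949
570.0	0.09568257327893695
571.0	0.11682330416812702
572.0	0.1413751049191573
573.0	0.169575540930959
574.0	0.20160453540977194
575.0	0.23756595385686818
576.0	0.2774692881749866
577.0	0.3212125130009017
578.0	0.3685673043227753
579.0	0.41916785810013035
580.0	0.47250450840610564
581.0	0.5279232099232789
582.0	0.5846317152228222
583.0	0.6417129487814521
584.0	0.6981456723153691
585.0	0.7528320741440238
586.0	0.8046314312209424
587.0	0.852398523948498
588.0	0.8950250709279725
589.0	0.9314821318134288
590.0	0.9608612343271888
591.0	0.982411939933184
592.0	0.9955736831881946
593.0	1.0
594.0	0.9955736831881946
595.0	0.982411939933184
596.0	0.9608612343271888
597.0	0.9314821318134288
598.0	0.8950250709279725
599.0	0.852398523948498
600.0	0.8046314312209424
601.0	0.7528320741440238
602.0	0.6981456723153691
603.0	0.6417129487814521
604.0	0.5846317152228222
605.0	0.5279232099232789
606.0	0.47250450840610564
607.0	0.41916785810013035
608.0	0.3685673043227753
609.0	0.3212125130009017
610.0	0.2774692881749866
611.0	0.23756595385686818
612.0	0.20160453540977194
613.0	0.169575540930959
614.0	0.1413751049191573
615.0	0.11682330416812702
616.0	0.09568257327893695
617.0	0.0776753151503949
618.0	0.0625
619.0	0.04984525553268852
620.0	0.03940165393078941
621.0	0.030871085015924945
622.0	0.023973759890837196
623.0	0.018453010334836414
624.0	0.014078134649397724
625.0	0.010645592071341942
626.0	0.007978869137696798
627.0	0.00592733782208442
628.0	0.004364402883094613
629.0	0.0031852007107601747
630.0	0.00230406957944172
631.0	0.0016519663326170382
632.0	0.0011739608396918672
633.0	0.000826899719104031
634.0	0.0005772964603312737
635.0	0.00039947698271489954
636.0	0.00027398793760787855
637.0	0.0001862592893935315
638.0	0.00012550217610547687
639.0	8.381685994807313e-05
640.0	5.5482795298915545e-05
641.0	3.6402574213729437e-05
642.0	2.3672966015087482e-05
643.0	1.5258789062500007e-05
644.0	9.748421081053307e-06
645.0	6.1729862135725535e-06
646.0	3.874388348235755e-06
647.0	2.4102262324491164e-06
648.0	1.4861384957513797e-06
649.0	9.082545350259826e-07
650.0	5.501773183430473e-07
651.0	3.303274047954769e-07
652.0	1.9657729044276196e-07
653.0	1.1594950525907111e-07
654.0	6.778775813884843e-08
655.0	3.928081216939855e-08
656.0	2.2560902160967893e-08
657.0	1.2843378502206577e-08
658.0	7.24684407869198e-09
659.0	4.052895153398838e-09
660.0	2.246614908725379e-09
661.0	1.2343511338619926e-09
662.0	6.721955299546273e-10
663.0	3.6282678118930323e-10
664.0	1.941108752727633e-10
665.0	1.0293124264479285e-10
666.0	5.409926688347002e-11
667.0	2.818268457388244e-11
668.0	1.455191522836691e-11
669.0	7.44740150651118e-12
670.0	3.777775941752355e-12
671.0	1.8993912843019283e-12
672.0	9.465411542071139e-13
673.0	4.67532039081593e-13
674.0	2.2889171336749797e-13
675.0	1.1106969482306533e-13
676.0	5.342049441577224e-14
677.0	2.546636995137464e-14
678.0	1.2032974614762216e-14
679.0	5.635413308158616e-15
680.0	2.6159254437625122e-15
681.0	1.2035711441528452e-15
682.0	5.4886430518307965e-16
683.0	2.480875811610649e-16
684.0	1.1114549843773263e-16
685.0	4.9354362533108567e-17
686.0	2.1722311239216316e-17
687.0	9.476180690651256e-18
688.0	4.0973913894762906e-18
689.0	1.7560156566026372e-18
690.0	7.459266662728298e-19
691.0	3.1405860588848805e-19
692.0	1.3106057831509317e-19
693.0	5.42101086242753e-20
694.0	2.2224668462506137e-20
695.0	9.031026584720402e-21
696.0	3.637355643549656e-21
697.0	1.4520488531870052e-21
698.0	5.745442808679718e-22
699.0	2.2532667067316254e-22
700.0	8.758878655449286e-23
701.0	3.37466941675316e-23
702.0	1.2887265555627981e-23
703.0	4.8779476569076904e-24
704.0	1.8300388517838784e-24
705.0	6.80503401083817e-25
706.0	2.508113041199421e-25
707.0	9.162431243642195e-26
708.0	3.3175781878515594e-26
709.0	1.1906343871372477e-26
710.0	4.235283554391227e-27
711.0	1.4932529397077552e-27
712.0	5.2183244867157455e-28
713.0	1.8074887363782194e-28
714.0	6.205359320053154e-29
715.0	2.1115680643037674e-29
716.0	7.121804567457426e-30
717.0	2.380794083982512e-30
718.0	7.888609052210105e-31
719.0	2.5907520386288558e-31
720.0	8.433310286206866e-32
721.0	2.7209284814299084e-32
722.0	8.701276908093833e-33
723.0	2.7580089361240468e-33
724.0	8.6647325923394e-34
725.0	2.6981213315789807e-34
726.0	8.327499262072911e-35
727.0	2.547502074218255e-35
728.0	7.724338648495368e-36
729.0	2.321426197978088e-36
730.0	6.915049174907336e-37
731.0	2.0416555822474646e-37
732.0	5.974705512201072e-38
733.0	1.7329951365169102e-38
734.0	4.98224407898767e-39
735.0	1.4197094448577871e-39
736.0	4.0097819770674745e-40
737.0	1.1225064972115445e-40
738.0	3.1146107875309116e-41
739.0	8.565752457618176e-42
740.0	2.334931110161555e-42
741.0	6.308548406908844e-43
742.0	1.689396632218448e-43
743.0	4.484155085839485e-44
744.0	1.1797132051751022e-44
745.0	3.076231912331628e-45
746.0	7.950757756988082e-46
747.0	2.036783115574971e-46
748.0	5.171635008875304e-47
749.0	1.3015407300177447e-47
750.0	3.2466425490437835e-48
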