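# znpp-spectrum/1
# excitation_nm=none
# integration_time_ms=1.0
# calibrated=true
# rows=251
wavelength_nm	intensity
500.0	7.089310753690655e-33
501.0	1.4411264861824643e-32
502.0	2.92059794522825e-32
503.0	5.90220653865883e-32
504.0	1.189834097536343e-31
505.0	2.39401535978984e-31
506.0	4.811687004630111e-31
507.0	9.672439270406046e-31
508.0	1.9481813228259417e-30
509.0	3.941821849590882e-30
510.0	8.040357299111412e-30
511.0	1.6609904210326216e-29
512.0	3.494595359007065e-29
513.0	7.533570287678003e-29
514.0	1.6734442715503247e-28
515.0	3.8450640665007064e-28
516.0	9.14773861282624e-28
517.0	2.248399424877293e-27
518.0	5.6814603534456e-27
519.0	1.4666253198970212e-26
520.0	3.8424418163776747e-26
521.0	1.01570791347071e-25
522.0	2.6959381673231846e-25
523.0	7.158449739388422e-25
524.0	1.8962982068792577e-24
525.0	5.001716697596228e-24
526.0	1.3117592821473421e-23
527.0	3.417366650435093e-23
528.0	8.837712214807477e-23
529.0	2.267760880366781e-22
530.0	5.77197245252089e-22
531.0	1.4568813436247547e-21
532.0	3.646111663215788e-21
533.0	9.04679776849029e-21
534.0	2.2252883228923877e-20
535.0	5.426018681125935e-20
536.0	1.3114862391785474e-19
537.0	3.142116171642642e-19
538.0	7.461887139140071e-19
539.0	1.756455963197476e-18
540.0	4.0981123362898186e-18
541.0	9.477318322038555e-18
542.0	2.1724006863732627e-17
543.0	4.9356650444435694e-17
544.0	1.1114797742190093e-16
545.0	2.480885646439934e-16
546.0	5.488587680290986e-16
547.0	1.2035459786015529e-15
548.0	2.615848844495977e-15
549.0	5.635211604404608e-15
550.0	1.2032482721599644e-14
551.0	2.546522722129984e-14
552.0	5.341792904564105e-14
553.0	1.1106408370431149e-13
554.0	2.2887969493873897e-13
555.0	4.675067466997382e-13
556.0	9.46488738476952e-13
557.0	1.899284142853719e-12
558.0	3.7775596809159155e-12
559.0	7.446970095988928e-12
560.0	1.4551064147295827e-11
561.0	2.818102335649087e-11
562.0	5.4096057537723444e-11
563.0	1.0292510412014361e-10
564.0	1.9409924835092935e-10
565.0	3.628049692673931e-10
566.0	6.721549967492774e-10
567.0	1.234276512526952e-09
568.0	2.2464787994022796e-09
569.0	4.0526491643052936e-09
570.0	7.24640355280892e-09
571.0	1.284259674037608e-08
572.0	2.25595273559307e-08
573.0	3.927841618158323e-08
574.0	6.778361989785687e-08
575.0	1.1594242182979293e-07
576.0	1.9656527401641174e-07
577.0	3.303072017341508e-07
578.0	5.50143653686661e-07
579.0	9.081989381294731e-07
580.0	1.4860474939952633e-06
581.0	2.4100786023981683e-06
582.0	3.874150977072833e-06
583.0	6.172607935349776e-06
584.0	9.747823596658498e-06
585.0	1.5257853710704717e-05
586.0	2.367151471348566e-05
587.0	3.6400342309842944e-05
588.0	5.547939333997248e-05
589.0	8.381172047179954e-05
590.0	0.00012549448045816796
591.0	0.00018624786829064482
592.0	0.00027397113767805144
593.0	0.0003994524896464343
594.0	0.000577261067539221
595.0	0.0008268490291660921
596.0	0.0011738888843225233
597.0	0.0016518650958783987
598.0	0.0023039284085033117
599.0	0.0031850055991528912
600.0	0.004364135613439342
601.0	0.005926974959126187
602.0	0.00797838086855368
603.0	0.010644940898557283
604.0	0.014077273953945722
605.0	0.01845188284080641
606.0	0.023972296081029548
607.0	0.030869201567679035
608.0	0.039399252263361016
609.0	0.04984222058038573
610.0	0.06249619934772409
611.0	0.07767059868857924
612.0	0.09567677355130948
613.0	0.11681623759637921
614.0	0.14136657409178907
615.0	0.1695653381379876
616.0	0.2015924475900164
617.0	0.23755176910043788
618.0	0.27745280389185883
619.0	0.3211935458298223
620.0	0.3685457018172879
621.0	0.419143512195792
622.0	0.47247737065144774
623.0	0.5278933084541924
624.0	0.5845991734834545
625.0	0.6416780060518352
626.0	0.6981087062034079
627.0	0.7527936253422369
628.0	0.8045922310195077
629.0	0.8523595252363068
630.0	0.8949874837004408
631.0	0.931447464534942
632.0	0.9608313428599367
633.0	0.982389086133312
634.0	0.9955606056736255
635.0	1.0
636.0	0.9955907287805292
637.0	0.9824507923485647
638.0	0.9609276003413986
639.0	0.9315828465446424
640.0	0.8951683156007926
641.0	0.8525940833680107
642.0	0.8048909958105089
643.0	0.7531695914296138
644.0	0.6985777526755454
645.0	0.642259330111895
646.0	0.5853157908710143
647.0	0.5287726238130815
648.0	0.47355182067088475
649.0	0.4204512837518779
650.0	0.3701315264768673
651.0	0.3231095709252613
652.0	0.2797595389137604
653.0	0.2403191043714455
654.0	0.20490074006946976
655.0	0.17350655676601492
656.0	0.14604549432493794
657.0	0.12235167174009894
658.0	0.1022028201966579
659.0	0.08533789106607215
660.0	0.07147312879137915
661.0	0.06031610763775806
662.0	0.051577434397519155
663.0	0.04498000299531995
664.0	0.04026584221217453
665.0	0.0372007191762866
666.0	0.035576747311860044
667.0	0.03521329963850301
668.0	0.03595655051962923
669.0	0.0376779664839006
670.0	0.04027204559053343
671.0	0.0436535709958361
672.0	0.047754603427426386
673.0	0.052521393866897886
674.0	0.057911355541417776
675.0	0.06389019592391958
676.0	0.07042927643230897
677.0	0.07750324062763175
678.0	0.08508793097906034
679.0	0.09315859923119375
680.0	0.10168840529973013
681.0	0.11064719349649972
682.0	0.12000053176885095
683.0	0.12970899861082624
684.0	0.13972770255801506
685.0	0.1500060200543557
686.0	0.16048753847420413
687.0	0.17111019184497303
688.0	0.18180657712894588
689.0	0.19250443868690742
690.0	0.2031273077523991
691.0	0.2135952824543987
692.0	0.22382593224728653
693.0	0.23373530867991116
694.0	0.2432390424156551
695.0	0.25225350446109546
696.0	0.2606970078240743
697.0	0.268491024440553
698.0	0.2755613913014601
699.0	0.28183947936970033
700.0	0.2872632991703927
701.0	0.29177851790233134
702.0	0.29533936456427373
703.0	0.29790940189562853
704.0	0.29946214684942674
705.0	0.299981524772825
706.0	0.29946214637137153
707.0	0.29790940076427835
708.0	0.2953393623718931
709.0	0.29177851387786674
710.0	0.287263291938546
711.0	0.28183946653455966
712.0	0.2755613687457249
713.0	0.2684909851640592
714.0	0.26069694004143734
715.0	0.25225338851919843
716.0	0.24323884585069983
717.0	0.23373497837296076
718.0	0.22382538210390446
719.0	0.2135943742558243
720.0	0.2031258217054397
721.0	0.1925020286091151
722.0	0.18180270297920564
723.0	0.17110401923892585
724.0	0.16047779065348305
725.0	0.14999076220501054
726.0	0.1397040310499068
727.0	0.12967259827847605
728.0	0.11994505239047665
729.0	0.11056338179843812
730.0	0.10156291085271381
731.0	0.09297235141263442
732.0	0.08481395991508177
733.0	0.07710378824682664
734.0	0.06985201552495335
735.0	0.06306334712968276
736.0	0.05673746700045633
737.0	0.05086952927112292
738.0	0.04545067574480078
739.0	0.04046856644661704
740.0	0.035907911490499385
741.0	0.03175099369869375
742.0	0.027978172762981396
743.0	0.02456836317914173
744.0	0.02149947966860718
745.0	0.018748845275626286
746.0	0.01629355875253069
747.0	0.014110819184424915
748.0	0.012178207029404862
749.0	0.010473921840081677
750.0	0.00897697787262485
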