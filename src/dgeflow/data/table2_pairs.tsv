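row	mirna_id	mirna_direction	gene_id	gene_direction
1	osa-miR156l	up	LOC_Os02g34860.1	down
1	osa-miR156l	up	LOC_Os03g26044.1	down
1	osa-miR156l	up	LOC_Os09g31970.1	down
1	osa-miR156l	up	LOC_Os04g34570.1	down
1	osa-miR156l	up	LOC_Os01g06550.1	down
1	osa-miR156l	up	LOC_Os07g29224.1	down
1	osa-miR156l	up	LOC_Os03g24960.1	down
1	osa-miR156l	up	LOC_Os06g05790.1	down
2	osa-miR530-5p	up	LOC_Os04g56980.1	down
2	osa-miR530-5p	up	LOC_Os03g17570.6	down
2	osa-miR530-5p	up	LOC_Os04g02880.1	down
3	oru-miR135	up	LOC_Os05g27930.1	down
3	oru-miR135	up	LOC_Os01g67240.1	down
3	oru-miR135	up	LOC_Os03g41080.1	down
3	oru-miR135	up	LOC_Os07g38800.1	down
3	oru-miR135	up	LOC_Os08g23180.1	down
3	oru-miR135	up	LOC_Os11g45740.1	down
4	oru-miR139	up	LOC_Os01g10580.1	down
4	oru-miR139	up	LOC_Os01g13760.1	down
4	oru-miR139	up	LOC_Os01g32130.1	down
5	oru-miR177	up	LOC_Os09g39462.1	down
6	oru-miR180	up	LOC_Os06g24070.1	down
6	oru-miR180	up	LOC_Os01g31890.1	down
6	oru-miR180	up	LOC_Os01g31940.1	down
6	oru-miR180	up	LOC_Os01g55450.1	down
6	oru-miR180	up	LOC_Os02g47510.1	down
6	oru-miR180	up	LOC_Os01g26000.1	down
7	osa-miR160f	down	LOC_Os04g43910.1	up
7	osa-miR160f	down	LOC_Os06g49840.1	up
7	osa-miR160f	down	LOC_Os02g39080.1	up
7	osa-miR160f	down	LOC_Os10g31864.1	up
8	osa-miR164a	down	LOC_Os05g18604.1	up
8	osa-miR164a	down	LOC_Os08g10080.1	up
8	osa-miR164a	down	LOC_Os01g62660.1	up
8	osa-miR164a	down	LOC_Os12g05260.1	up
8	osa-miR164a	down	LOC_Os09g08130.2	up
8	osa-miR164a	down	LOC_Os02g19924.1	up
8	osa-miR164a	down	LOC_Os06g46270.1	up
8	osa-miR164a	down	LOC_Os06g49660.1	up
8	osa-miR164a	down	LOC_Os09g37700.1	up
8	osa-miR164a	down	LOC_Os04g38720.1	up
8	osa-miR164a	down	LOC_Os12g41680.1	up
9	osa-miR164b	down	LOC_Os12g05260.1	up
9	osa-miR164b	down	LOC_Os06g46270.1	up
9	osa-miR164b	down	LOC_Os06g49660.1	up
9	osa-miR164b	down	LOC_Os04g38720.1	up
10	osa-miR164d	down	LOC_Os08g10080.1	up
10	osa-miR164d	down	LOC_Os12g05260.1	up
10	osa-miR164d	down	LOC_Os09g08130.2	up
10	osa-miR164d	down	LOC_Os06g46270.1	up
10	osa-miR164d	down	LOC_Os06g49660.1	up
11	osa-miR164f	down	LOC_Os06g46270.1	up
11	osa-miR164f	down	LOC_Os12g41680.1	up
11	osa-miR164f	down	LOC_Os12g05260.1	up
11	osa-miR164f	down	LOC_Os04g41540.1	up
12	osa-miR166a	down	LOC_Os04g48290.1	up
13	osa-miR166b	down	LOC_Os08g34740.1	up
14	osa-miR166d	down	LOC_Os08g34740.1	up
15	osa-miR166f	down	LOC_Os08g34740.1	up
16	osa-miR166m	down	LOC_Os04g48290.1	up
17	osa-miR167d	down	LOC_Os06g03830.1	up
18	osa-miR167f	down	LOC_Os06g03830.1	up
19	osa-miR167h	down	LOC_Os03g29240.1	up
20	osa-miR172a	down	LOC_Os03g60430.2	up
20	osa-miR172a	down	LOC_Os03g47650.1	up
20	osa-miR172a	down	LOC_Os02g56320.1	up
20	osa-miR172a	down	LOC_Os06g49500.3	up
20	osa-miR172a	down	LOC_Os04g55560.4	up
21	osa-miR172b	down	LOC_Os04g55560.2	up
22	osa-miR172d	down	LOC_Os06g06050.1	up
22	osa-miR172d	down	LOC_Os04g05650.1	up
23	osa-miR2123c	down	LOC_Os02g49880.1	up
24	osa-miR390	down	LOC_Os02g10100.1	up
24	osa-miR390	down	LOC_Os06g03970.1	up
24	osa-miR390	down	LOC_Os01g33110.1	up
24	osa-miR390	down	LOC_Os02g10100.1	up
24	osa-miR390	down	LOC_Os05g33160.1	up
24	osa-miR390	down	LOC_Os06g03970.1	up
24	osa-miR390	down	LOC_Os04g45170.1	up
25	osa-miR408	down	LOC_Os03g15600.1	up
25	osa-miR408	down	LOC_Os09g36860.1	up
25	osa-miR408	down	LOC_Os08g37670.1	up
25	osa-miR408	down	LOC_Os01g54430.1	up
26	osa-miR5161	down	LOC_Os05g47560.1	up
26	osa-miR5161	down	LOC_Os05g03884.1	up
26	osa-miR5161	down	LOC_Os11g01074.1	up
26	osa-miR5161	down	LOC_Os03g64320.1	up
27	osa-miR818b	down	LOC_Os01g10580.1	up
27	osa-miR818b	down	LOC_Os10g11200.1	up
27	osa-miR818b	down	LOC_Os02g54640.1	up
27	osa-miR818b	down	LOC_Os05g03640.1	up
28	oru-miR4	down	LOC_Os05g31530.1	up
28	oru-miR4	down	LOC_Os09g39410.1	up
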