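id	chrom	start	end	score	location	set	activity	chromatin_state
E1	chr16	30009196	30009301	3.07	intronic_TBX6	prediction	yes	no
E7	chr10	82023331	82023434	2.60	intergenic_MAT1A_3UTR	prediction	no	yes
E2	chr17	69962795	69962894	2.21	intergenic_GPRC5C_down	prediction	no	no
E8	chr1	31679029	31679149	1.94	intronic_SERINC2	prediction	yes	yes
E12	chr3	134934910	134935091	1.81	intronic_TF	prediction	yes	yes
E4	chr11	72138831	72139119	1.83	intronic_ARAP1	prediction	yes	no
E5	chr17	69957920	69958023	1.30	intergenic_GPRC5C_3UTR	prediction	yes	no
E10	chr17	69951075	69951329	1.57	intronic_GPRC5C	prediction	yes	yes
E3	chr11	72162941	72163179	1.47	intronic_STARD10	prediction	no	no
E9	chr11	72168911	72169046	1.33	intronic_STARD10	prediction	no	yes
E11	chr11	72166224	72166509	1.36	intronic_STARD10	prediction	yes	yes
E6	chr17	17439719	17439913	1.04	intergenic_PEMT_up	prediction	no	no
C1	chr15	56263226	56263340	-2.22	intronic_AQP9	control	no	.
C2	chr6	26030368	26030485	-2.03	intronic_SLC17A2	control	no	.
C3	chr22	19494974	19495083	-1.26	intronic_PI4KA	control	no	.
C4	chr5	138482621	138482789	-1.67	intronic_SIL1	control	no	.
C5	chr9	96485497	96485627	-1.32	intergenic_FBP1_up	control	no	.
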