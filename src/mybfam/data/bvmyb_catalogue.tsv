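# Catalogue of the 75 multi-repeat MYB genes of the sugar-beet reference
# genome (KWS2320 annotation), transcribed from the published gene table.
# Coordinates are printed pseudochromosome positions, 1-based inclusive,
# in transcription order (start > end on the minus strand). "un"-suffixed
# chromosome labels mean chromosome-assigned without position; "rnd"
# labels are unanchored scaffolds. Exon counts for huqy and qcwx follow
# the stated per-category totals (53/11/4/2 over the two-repeat genes)
# where the printed per-row digits are ambiguous.
gene_id	gene_code	chromosome	start	end	clade	subgroup	landmarks	function	protein_length	n_exons
iquc	Bv1g001230_iquc	1	1379505	1381156	C14	S4	AtMYB4, HvMYB5	Metabolism	341	3
owzx	Bv1g001750_owzx	1	1903239	1898047	C8	S3	AtMYB58, AtMYB63	Metabolism	316	3
dwki	Bv1g002800_dwki	1	3065434	3067536	C18	S5	VvMYBPA	Metabolism	335	2
qxpi	Bv1g006050_qxpi	1	6597147	6601421	C3		AtLMI2	Development	303	3
ksfi	Bv1g014750_ksfi	1	32690615	32692641	C12	S14	SlBLIND, AtRAX1	Development	363	3
zqor	Bv1ug018140_zqor	1un	38330908	38328715	C28	S18	HvGAMYB, AtDUO1	Development	303	3
jxgt	Bv1ug021520_jxgt	1un	45201741	45199866	C36	S21	AtLOF1, AtMYB52	Devel., metab.	350	2
uksi	Bv2g023560_uksi	2	127507	126341	C35	S23			253	1
wdyc	Bv2g024650_wdyc	2	1373912	1378227	C35	S23			416	2
ihfg	Bv2g027580_ihfg	2	4418041	4424427	C15		FaMYB1	Metabolism	199	3
jkkr	Bv2g027795_jkkr	2	4723639	4720911	C21			metabolism	224	3
mxck	Bv2g027990_mxck	2	4981898	4984692	C29				286	4
xprd	Bv2g029260_xprd	2	6275539	6272224	C27		EgMYB2, PtMYB4	Metabolism	422	2
ralf	Bv2g030925_ralf	2	8431718	8435595	C21			metabolism	237	3
ghua	Bv2g031800_ghua	2	9813407	9800544	C37	MYB3R	AtMYB3R1	Cell cycle	1050	11
huqy	Bv2g039110_huqy	2	27806443	27798295	C26		AtMYB26	Development	329	3
dcmm	Bv2g040720_dcmm	2	33641162	33643072	C1	S9	AmMIXTA, AtNOK	differentiation	454	3
mxwz	Bv2g041120_mxwz	2	34717448	34719429	C11		AtTDF1	Development	331	3
nqis	Bv2ug047120_nqis	2un	45488410	45491366	C4	S1	AtMYB30	Defense	344	3
urrg	Bv3g049510_urrg	3	1126350	1124818	C9	S2	NtMYB1, AtMYB13	Defense	288	3
hwcc	Bv3g050090_hwcc	3	1847195	1845526	C6	S24			360	3
cwtt	Bv3ug070140_cwtt	3un	35695445	35697294	C29				242	3
cjuq	Bv4g071740_cjuq	4	221407	222747	C19		VvMYB5a	Metabolism	306	2
yruo	Bv4g073190_yruo	4	1667414	1671378	C27		EgMYB2, PtMYB4	Metabolism	397	2
ygxg	Bv4g074860_ygxg	4	3396314	3392041	C28	S18	HvGAMYB, AtDUO1	Development	556	3
skuh	Bv4g078900_skuh	4	7533943	7547807	C42	MYB4R	AtMYB4R1		919	12
zfig	Bv4g079610_zfig	4	8546454	8544269	C25	S13	AtMYB61	Metabolism	449	2
oref	Bv4g079670_oref	4	8669284	8678138	C41	CDC5	AtCDC5	Cell cycle	991	4
josh	Bv4g083815_josh	4	16552338	16566035					209	3
rwwj	Bv4g084340_rwwj	4	18292096	18285979	C14	S4	AtMYB4, HvMYB5	Metabolism	322	3
xwne	Bv4g091510_xwne	4	32888798	32889966	C11		AtTDF1	Development	316	3
jofq	Bv5g098940_jofq	5	834523	837220	C10				294	2
sskd	Bv5g100530_sskd	5	2767018	2770045	C23		AtMYB103	Development	378	3
mhxh	Bv5g101320_mhxh	5	3800529	3804868	C37	MYB3R	AtMYB3R1	Cell cycle	525	7
zkef	Bv5g107260_zkef	5	14451259	14465332					272	2
ztyd	Bv5g110930_ztyd	5	25553310	25538334	C32	S19	AtMYB21	Development	231	3
udmh	Bv5g110960_udmh	5	25780619	25782807	C4	S1	AtMYB30	Defense	293	3
tcwd	Bv5g112510_tcwd	5	31754754	31740788	C37	MYB3R	AtMYB3R1	Cell cycle	549	7
nmrg	Bv5g115970_nmrg	5	42841475	42839260	C4	S1	AtMYB30	Defense	334	3
oaxt	Bv5g116880_oaxt	5	44348080	44350042	C11		AtTDF1	Development	356	3
tfkh	Bv5g118200_tfkh	5	46474363	46471416	C38	S25	AtPGA37	Development	501	3
ahtj	Bv5g118320_ahtj	5	46667594	46670167	C38	S25	AtPGA37	Development	456	3
cfqe	Bv5g118940_cfqe	5	47478672	47484506					354	3
roao	Bv5g122000_roao	5	50845046	50849238	C9	S2	NtMYB1, AtMYB13	Defense	304	3
iogq	Bv5g122370_iogq	5	51297529	51287534	C13	S7	ZmP, AtPFG1	Metabolism	387	3
ijmc	Bv5g123335_ijmc	5	52180596	52182338	C33	S20	TaPIMP1, AtBOS1	Def., devel.	313	3
ohkk	Bv5ug126300_ohkk	5un	58923676	58920132	C39		AmPHAN, AtAS1	Development	369	1
knac	Bv5ug126380_knac	5un	59366406	59371048	C36	S21	AtLOF1, AtMYB52	Devel., metab.	354	3
qcwx	Bv5ug126530_qcwx	5un	60109952	60111819	C7	S11	AtMYB102	Defense	334	3
such	Bv6g128620_such	6	508583	510104	C34	S22	AtMYB44	Def., devel.	313	1
hwmt	Bv6g129790_hwmt	6	2064496	2062852	C12	S14	SlBLIND, AtRAX1	Development	321	3
oypc	Bv6g136060_oypc	6	9418772	9413559	C6	S24			326	3
usyi	Bv6g142590_usyi	6	24870820	24874245	C33	S20	TaPIMP1, AtBOS1	Def., devel.	275	3
qttn	Bv6g154730_qttn	6	58819129	58822997	C36	S21	AtLOF1, AtMYB52	Devel., metab.	461	3
zeqy	Bv6g155340_zeqy	6	59766073	59770527	C40		AtFLP	Differentiation	445	12
yejr	Bv7g162730_yejr	7	7720067	7722320	C12	S14	SlBLIND, AtRAX1	Development	380	3
ahzs	Bv7g172570_ahzs	7	37491045	37494304	C26		AtMYB26	Development	405	3
eztu	Bv7g172590_eztu	7	37594009	37596132	C26		AtMYB26	Development	417	3
qzms	Bv7g174540_qzms	7	40066216	40070163	C38	S25	AtPGA37	Development	481	3
ksge	Bv7g176420_ksge	7	42070277	42071595	C30		AtMYB59	Development	249	2
qzfy	Bv7ug180860_qzfy	7un	49349681	49351461	C31				264	3
dxny	Bv8g183050_dxny	8	719286	716855	C7	S11	AtMYB102	Defense	409	3
zguf	Bv8g183060_zguf	8	734446	721513	C7	S11	AtMYB102	Defense	396	3
jona	Bv8g199535_jona	8	37703170	37704769	C12	S14	SlBLIND, AtRAX1	Development	271	3
khqq	Bv8g200250_khqq	8	38542747	38540562	C12	S14	SlBLIND, AtRAX1	Development	368	3
gjwr	Bv9g216350_gjwr	9	33882588	33884593	C14	S4	AtMYB4, HvMYB5	Metabolism	276	2
krez	Bv9g225930_krez	9	44634979	44633906	C34	S22	AtMYB44	Def., devel.	253	1
ezhe	Bvg229250_ezhe	rnd0020	411935	416451	C28	S18	HvGAMYB, AtDUO1	Development	410	3
crae	Bvg229400_crae	rnd0039	39535	40725	C17	S5	AtTT2	Metabolism	282	3
entg	Bvg229850_entg	rnd0043	141170	143052	C33	S20	TaPIMP1, AtBOS1	Def., devel.	310	3
swwi	Bvg235150_swwi	rnd0157	176581	179181					191	3
oyjz	Bvg238960_oyjz	rnd0254	47161	49928	C3		AtLMI2	Development	239	3
dani	Bvg239075_dani	rnd0254	156586	162101	C24	S16	AtLAF1	Development	285	3
sjwa	Bvg239080_sjwa	rnd0254	178734	182264	C24	S16	AtLAF1	Development	278	3
pgya	Bvg243050_pgya	rnd0446	12407	14214					326	3
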