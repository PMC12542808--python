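sample_id	n_reads	n_on_target	pct_on_target	n_loci_with_reads	n_loci_with_seq	n_loci_50	n_loci_75	n_paralog_len	n_paralog_depth	total_bases
Astragalus_brachypetalus	13096388	2197494	16.8	819	794	790	780	28	43	757905
Astragalus_christianus	10890516	2162531	19.9	819	790	784	775	21	30	761679
Astragalus_contortuplicatus	12954696	2476545	19.1	819	798	795	792	23	25	771726
Astragalus_depressus	3803474	1081395	28.4	819	759	754	738	16	18	722751
Astragalus_echinatus	21947158	4067973	18.5	819	804	801	796	287	373	772437
Astragalus_guttatus	14311544	2414407	16.9	819	798	796	794	16	18	771000
Astragalus_hissaricus	5194436	818111	15.7	819	613	594	556	11	12	578916
Astragalus_hoffmeisteri	6693262	2560090	38.2	819	796	794	792	17	20	781161
Astragalus_hymenostegis	8930610	1986014	22.2	819	797	793	784	36	42	761667
Astragalus_leucocephalus	13467798	2747841	20.4	819	805	805	802	19	20	777093
Astragalus_lonchocarpus	5926928	1440551	24.3	819	728	706	662	216	253	680127
Astragalus_mareoticus	9754798	2638608	27.0	819	805	804	788	239	293	763911
Astragalus_monspessulanus	12255330	4235194	34.6	819	786	782	777	24	30	758790
Astragalus_norvegicus	6846986	918944	13.4	819	593	580	554	9	12	569157
Astragalus_nuttallianus	5466098	1430111	26.2	819	763	758	726	300	354	719895
Astragalus_pelecinus	8200056	2252069	27.5	819	752	750	745	13	13	721428
Astragalus_psilacanthus	4518478	1592032	35.2	819	792	791	781	23	31	770313
Astragalus_stalinskyi	8108134	1800468	22.2	819	789	788	784	19	20	755565
Astragalus_sungpanensis	15393230	5932392	38.5	819	814	811	805	29	64	787215
Astragalus_uliginosus	4429540	789492	17.8	819	544	537	517	10	12	534834
Colutea_persica	7406784	1663545	22.5	819	791	787	778	26	31	759198
Oxytropis_purpurea	12328132	1824155	14.8	819	756	752	742	13	23	729177
Podlechiella_vogelii	6924508	1203549	17.4	819	746	746	737	16	16	730305
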