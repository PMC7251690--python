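tair_id	symbol	membrane_p	membrane_log2fc	soluble_p	soluble_log2fc	gene_log2fc	gene_fdr
AT5G04120	dPGM	0.000	1.080	NA	NA	3.663	0.000
AT1G17810	TIP3-2	0.050	0.500	NA	NA	-2.131	0.020
AT5G19370	-	0.000	0.370	NA	NA	1.011	0.003
AT4G18480	CHLI1	0.043	0.320	NA	NA	1.207	0.000
AT3G16290	FTSHI2	0.023	0.320	NA	NA	1.003	0.005
AT4G19710	AK-HSDH II	0.032	0.250	NA	NA	1.020	0.001
AT1G11580	PMEPCRA	0.026	-0.390	NA	NA	-1.223	0.005
AT3G48730	GSA2	0.001	-0.500	NA	NA	1.102	0.000
AT1G66280	BGLU22	0.001	-0.550	NA	NA	-1.024	0.003
AT1G19530	POLEA	0.001	-0.970	NA	NA	-1.746	0.000
AT5G08280	HEMC	NA	NA	0.014	-0.232	1.030	0.008
AT3G52960	PRXIIE	NA	NA	0.047	-0.257	1.139	0.001
AT5G09650	PPa6	NA	NA	0.045	-0.359	1.057	0.001
AT5G59090	SBT4.12	NA	NA	0.042	-0.377	-1.443	0.000
AT5G43780	APS4	NA	NA	0.048	-0.410	-1.351	0.000
AT5G56870	BGAL4	NA	NA	0.032	-0.539	-1.280	0.000
AT3G11930	-	NA	NA	0.002	-0.544	-1.467	0.000
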