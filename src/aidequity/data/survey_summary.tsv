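country	survey_dates	households	deaths	child_years_thousands
Albania	10/2008-4/2009	7987	105	24.1
Angola	1/2011-6/2011	8023	1275	57.5
Armenia	9/2005-11/2005	6619	100	16.1
Armenia	10/2010-12/2010	6665	59	13.5
Azerbaijan	7/2006-11/2006	7124	268	24.6
Bangladesh	3/2007-8/2007	10369	968	60.6
Bolivia	8/2003-1/2004	18946	1924	100.7
Bolivia	2/2008-6/2008	19408	1292	87.6
Burkina Faso	5/2010-12/2010	14326	4134	128.4
Burundi	8/2010-1/2011	8540	1546	58.1
Cambodia	9/2005-3/2006	14035	1945	84.8
Cambodia	7/2010-1/2011	15616	1121	76.6
Cameroon	2/2004-9/2004	10234	2134	64.6
Cameroon	1/2011-8/2011	14056	2629	95.2
Chad	7/2004-12/2004	5321	1996	46.9
Colombia	6/2004-7/2005	37102	864	147.4
Colombia	11/2009-12/2010	51184	848	185.0
Congo	7/2005-11/2005	5822	990	37.0
Dem. Rep. of the Congo	1/2007-9/2007	8723	2504	67.0
Dominican Republic	3/2007-8/2007	32228	839	117.9
Egypt	4/2005-7/2005	21755	1363	126.9
Egypt	3/2008-6/2008	18866	744	102.4
Ethiopia	4/2005-8/2005	13567	2529	91.1
Ethiopia	12/2010-5/2011	16509	2633	106.0
Gabon	1/2012-5/2012	9673	720	49.0
Ghana	9/2008-11/2008	11660	512	26.1
Guyana	3/2009-8/2009	5406	168	22.5
Haiti	10/2005-5/2006	7951	1139	54.5
Haiti	1/2012-6/2012	12769	1189	61.4
India	12/2005-8/2006	103625	8050	534.8
Kenya	4/2003-9/2003	8476	1169	48.1
Kenya	11/2008-3/2009	9016	969	51.2
Lesotho	10/2009-1/2010	9281	707	30.7
Liberia	12/2006-4/2007	6604	1456	47.7
Liberia	12/2008-3/2009	4149	1185	32.1
Madagascar	11/2008-7/2009	17686	1998	115.9
Malawi	1/2004-2/2005	13457	2979	80.4
Malawi	6/2010-10/2010	24689	4472	169.2
Maldives	1/2009-10/2009	6408	202	34.4
Mali	3/2006-12/2006	12905	5465	115.6
Moldova	6/2005-8/2005	10911	79	16.2
Morocco	10/2003-2/2004	10929	714	63.7
Mozambique	8/2003-1/2004	6876	3261	80.1
Mozambique	6/2011-11/2011	13268	2014	85.1
Namibia	11/2006-3/2007	9022	668	44.2
Nepal	2/2006-8/2006	8660	993	57.1
Niger	1/2006-6/2006	7624	3288	78.4
Nigeria	3/2003-8/2003	7055	2301	46.9
Nigeria	6/2008-11/2008	33900	9047	231.0
Nigeria	10/2010-12/2010	5871	1542	45.2
Pakistan	9/2006-3/2007	13463	1677	88.1
Peru	12/2003-11/2008	39090	1410	181.5
Philippines	8/2008-9/2008	12309	517	64.0
Rwanda	9/2010-4/2011	12476	1694	78.8
Senegal	11/2008-2/2009	9094	3207	124.8
Senegal	10/2010-5/2011	7889	2095	101.1
Sierra Leone	4/2008-8/2008	7214	1832	48.4
Swaziland	7/2006-3/2007	4771	554	23.6
Tanzania	10/2004-2/2005	9670	1930	67.5
Tanzania	10/2007-2/2008	8455	1374	60.9
Tanzania	12/2009-5/2010	9586	1271	67.0
Timor-Leste	8/2009-2/2010	11447	1559	88.4
Uganda	5/2006-10/2006	8784	2257	68.6
Uganda	11/2009-2/2010	4410	745	32.5
Uganda	6/2011-12/2011	8992	1521	66.1
Ukraine	7/2007-11/2007	13159	51	13.5
Zambia	4/2007-10/2007	7081	1478	49.0
Zimbabwe	8/2005-4/2006	9191	685	43.8
Zimbabwe	9/2010-3/2011	9697	702	43.4
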