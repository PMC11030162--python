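ko_id	group
K00018	pathway
K00024	pathway
K00360	pathway
K00362	pathway
K00363	pathway
K00366	pathway
K00367	pathway
K00368	pathway
K00370	pathway
K00371	pathway
K00372	pathway
K00374	pathway
K00376	pathway
K00380	pathway
K00381	pathway
K00390	pathway
K00392	pathway
K00531	pathway
K00600	pathway
K00830	pathway
K00860	pathway
K00955	pathway
K00957	pathway
K00958	pathway
K01595	pathway
K01689	pathway
K02305	pathway
K02567	pathway
K02568	pathway
K02586	pathway
K02588	pathway
K02591	pathway
K03385	pathway
K04561	pathway
K05907	pathway
K07072	pathway
K07144	pathway
K08691	pathway
K08928	pathway
K08929	pathway
K09733	pathway
K10534	pathway
K11529	pathway
K11779	pathway
K11780	pathway
K11781	pathway
K13811	pathway
K13991	pathway
K13992	pathway
K14941	pathway
K15864	pathway
K15876	pathway
K17877	pathway
K18933	pathway
K00135	housekeeping
K00396	housekeeping
K00740	housekeeping
K01229	housekeeping
K01285	housekeeping
K01527	housekeeping
K01583	housekeeping
K01625	housekeeping
K01770	housekeeping
K01901	housekeeping
K01932	housekeeping
K01937	housekeeping
K01954	housekeeping
K01989	housekeeping
K02028	housekeeping
K02058	housekeeping
K02130	housekeeping
K02254	housekeeping
K02290	housekeeping
K02374	housekeeping
K02399	housekeeping
K02544	housekeeping
K02641	housekeeping
K02683	housekeeping
K02720	housekeeping
K02817	housekeeping
K02973	housekeeping
K03067	housekeeping
K03085	housekeeping
K03193	housekeeping
K03377	housekeeping
K03837	housekeeping
K03860	housekeeping
K03869	housekeeping
K04057	housekeeping
K04113	housekeeping
K04239	housekeeping
K04364	housekeeping
K04487	housekeeping
K04727	housekeeping
K04774	housekeeping
K04944	housekeeping
K04946	housekeeping
K04958	housekeeping
K04981	housekeeping
K05406	housekeeping
K05452	housekeeping
K05507	housekeeping
K05775	housekeeping
K05891	housekeeping
K05923	housekeeping
K05976	housekeeping
K06157	housekeeping
K06749	housekeeping
K07036	housekeeping
K07151	housekeeping
K07245	housekeeping
K07316	housekeeping
K07562	housekeeping
K07601	housekeeping
K07646	housekeeping
K07887	housekeeping
K07999	housekeeping
K08114	housekeeping
K08141	housekeeping
K08610	housekeeping
K08846	housekeeping
K09105	housekeeping
K09124	housekeeping
K09239	housekeeping
K09326	housekeeping
K09419	housekeeping
K09436	housekeeping
K09490	housekeeping
K09823	housekeeping
K09839	housekeeping
K10109	housekeeping
K10146	housekeeping
K10281	housekeeping
K10294	housekeeping
K10441	housekeeping
K10612	housekeeping
K11146	housekeeping
K11209	housekeeping
K11256	housekeeping
K11371	housekeeping
K11475	housekeeping
K11648	housekeeping
K11757	housekeeping
K11849	housekeeping
K11983	housekeeping
K12100	housekeeping
K12203	housekeeping
K12467	housekeeping
K12642	housekeeping
K12811	housekeeping
K12938	housekeeping
K12999	housekeeping
K13039	housekeeping
K13162	housekeeping
K13609	housekeeping
K13702	housekeeping
K13703	housekeeping
K13729	housekeeping
K13735	housekeeping
K13819	housekeeping
K13911	housekeeping
K14012	housekeeping
K14108	housekeeping
K14210	housekeeping
K14603	housekeeping
K14708	housekeeping
K14719	housekeeping
K14850	housekeeping
K14949	housekeeping
K14964	housekeeping
K15129	housekeeping
K15257	housekeeping
K15536	housekeeping
K15892	housekeeping
K16023	housekeeping
K16178	housekeeping
K16224	housekeeping
K16267	housekeeping
K16270	housekeeping
K16276	housekeeping
K16628	housekeeping
K16776	housekeeping
K16892	housekeeping
K17210	housekeeping
K17424	housekeeping
K17518	housekeeping
K17560	housekeeping
K17718	housekeeping
K17949	housekeeping
K18005	housekeeping
K18030	housekeeping
K18057	housekeeping
K18241	housekeeping
K18288	housekeeping
K18327	housekeeping
K18359	housekeeping
K18494	housekeeping
K18529	housekeeping
K18558	housekeeping
K18708	housekeeping
K18718	housekeeping
K18777	housekeeping
K18823	housekeeping
K18911	housekeeping
K18939	housekeeping
K19003	housekeeping
K19058	housekeeping
K19097	housekeeping
K19104	housekeeping
K19188	housekeeping
K19305	housekeeping
K19477	housekeeping
K19955	housekeeping
K19983	housekeeping
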