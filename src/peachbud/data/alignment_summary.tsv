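library	total_reads	not_aligned_concordantly	aligned_concordantly_1_time	aligned_concordantly_multi	overall_alignment_rate
apical_T1_rep1	34,292,026	2,280,843	30,781,724	1,229,459	98.00
apical_T1_rep2	34,434,870	2,342,888	30,935,613	1,156,369	98.11
apical_T1_rep3	43,732,266	2,513,036	39,616,754	1,602,476	98.11
apical_T2_rep1	44,203,838	2,530,210	39,185,197	2,488,431	98.25
apical_T2_rep2	23,233,490	1,580,338	20,645,436	1,007,716	97.39
apical_T2_rep3	43,383,946	2,858,636	38,090,729	2,434,581	97.69
apical_T3_rep1	46,708,006	3,599,642	40,907,378	2,200,986	97.73
apical_T3_rep2	42,615,230	3,399,374	37,334,992	1,880,864	98.09
apical_T3_rep3	30,979,324	2,337,941	26,745,504	1,895,879	97.79
basal_T1_rep1	28,158,584	1,808,904	25,386,919	962,761	98.06
basal_T1_rep2	36,578,606	3,306,449	32,042,393	1,229,764	97.59
basal_T1_rep3	32,471,348	2,403,535	28,758,558	1,309,255	98.01
basal_T2_rep1	33,367,686	2,936,902	28,953,456	1,477,328	96.78
basal_T2_rep2	38,858,384	3,594,670	33,552,465	1,711,249	96.88
basal_T2_rep3	48,217,022	6,108,572	40,111,704	1,996,746	96.57
basal_T3_rep1	54,349,109	4,261,492	46,158,581	3,929,036	96.99
basal_T3_rep2	29,073,897	2,122,271	25,317,958	1,633,668	96.74
basal_T3_rep3	34,389,536	2,638,820	29,830,188	1,920,528	97.00
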