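week_no	sessions_min	sessions_max	pct_lo	pct_hi	endurance_min
1	3	3	40	50	20
2	3	4	40	50	25
3	3	4	45	55	25
4	3	4	45	55	30
5	3	4	50	60	30
6	3	4	50	60	35
7	3	4	55	65	35
8	3	4	55	65	40
9	3	4	60	70	40
10	3	4	60	70	45
11	3	4	65	75	45
12	3	4	65	75	50
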