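table_id	study	stratum	exposure	outcome	a	b	c	d	printed_or	printed_low	printed_high	printed_p	or_match	low_match	high_match
deposition	CSF	E318G+	APOE4_carrier	deposition	15	1	9	11	18.3	2.0	166.8	3.5e-3	1	1	0
deposition	CSF	E318G-	APOE4_carrier	deposition	299	105	201	322	4.5	3.4	6.0	1.7e-27	0	1	0
case_control	WU	E318G+	APOE4_carrier	case	24	3	21	26	9.9	2.6	37.5	1.7e-4	1	1	1
case_control	WU	E318G-	APOE4_carrier	case	605	187	381	608	5.1	4.1	6.3	3.2e-59	0	0	0
case_control	GERAD	E318G+	APOE4_carrier	case	60	8	24	33	10.3	4.1	25.5	4.1e-8	1	0	1
case_control	GERAD	E318G-	APOE4_carrier	case	1660	282	1169	818	4.1	3.5	4.8	1.1e-79	1	1	1
case_control	WU+GERAD	E318G+	APOE4_carrier	case	84	11	45	59	10.1	4.8	20.9	9.0e-12	0	1	0
case_control	WU+GERAD	E318G-	APOE4_carrier	case	2265	469	1550	1426	4.4	3.9	5.0	6.8e-139	1	1	1
apoe_dose	WU+GERAD	E318G+	APOE4_het	case	69	8	45	59	10.7	4.7	24.6	2.5e-10	0	0	0
apoe_dose	WU+GERAD	E318G+	APOE44	case	15	2	45	59	9.3	2.0	42.9	1.0e-3	0	0	0
apoe_dose	WU+GERAD	E318G-	APOE4_het	case	1800	426	1550	1426	3.9	3.4	4.4	2.8e-106	1	1	1
apoe_dose	WU+GERAD	E318G-	APOE44	case	465	43	1550	1426	9.9	7.2	13.7	3.4e-74	1	1	1
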