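sep_id	composition	support	avg_overlap
SEP_1	41_Leukopenia, 90_Feeling_abnormal, 99_Headache	123	69
SEP_2	90_Feeling_abnormal, 99_Headache, 110_Shock	123	73
SEP_3	58_Gout	120	60
SEP_4	70_Pneumonia, 99_Headache	117	71
SEP_5	110_Shock, 111_Infection	117	68
SEP_6	76_Asthma, 90_Feeling_abnormal, 99_Headache	117	68
SEP_7	65_Dermatitis	116	53
SEP_8	2_Haemorrhage, 76_Asthma	115	65
SEP_9	41_Leukopenia, 76_Asthma	115	62
SEP_10	48_Rhinitis, 99_Headache, 111_Infection	115	69
SEP_11	41_Leukopenia, 110_Shock	114	66
SEP_12	39_Stevens-Johnson_syndrome, 41_Leukopenia, 100_Erythema_multiforme	114	52
SEP_13	41_Leukopenia, 48_Rhinitis	113	67
SEP_14	99_Headache, 100_Erythema_multiforme	113	56
SEP_15	31_Lymphadenopathy	112	59
SEP_16	70_Pneumonia, 90_Feeling_abnormal	112	71
SEP_17	41_Leukopenia, 70_Pneumonia	112	64
SEP_18	76_Asthma, 111_Infection	112	64
SEP_19	80_Jaundice, 100_Erythema_multiforme	112	45
SEP_20	41_Leukopenia, 111_Infection	111	63
SEP_21	8_Haematuria, 90_Feeling_abnormal, 99_Headache	111	68
SEP_22	13_Pyrexia, 33_Musculoskeletal_discomfort, 48_Rhinitis, 99_Headache	111	69
SEP_23	13_Pyrexia, 70_Pneumonia	110	69
SEP_24	48_Rhinitis, 90_Feeling_abnormal, 110_Shock	110	70
SEP_25	13_Pyrexia, 90_Feeling_abnormal, 110_Shock	110	70
SEP_26	48_Rhinitis, 90_Feeling_abnormal, 111_Infection	110	69
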