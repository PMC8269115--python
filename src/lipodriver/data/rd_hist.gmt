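RD_HIST_H1	replication-dependent histone family	HIST_H1_01	HIST_H1_02	HIST_H1_03	HIST_H1_04	HIST_H1_05	HIST_H1_06
RD_HIST_H2A	replication-dependent histone family	HIST_H2A_01	HIST_H2A_02	HIST_H2A_03	HIST_H2A_04	HIST_H2A_05	HIST_H2A_06	HIST_H2A_07	HIST_H2A_08	HIST_H2A_09	HIST_H2A_10	HIST_H2A_11	HIST_H2A_12	HIST_H2A_13	HIST_H2A_14	HIST_H2A_15	HIST_H2A_16
RD_HIST_H2B	replication-dependent histone family	HIST_H2B_01	HIST_H2B_02	HIST_H2B_03	HIST_H2B_04	HIST_H2B_05	HIST_H2B_06	HIST_H2B_07	HIST_H2B_08	HIST_H2B_09	HIST_H2B_10	HIST_H2B_11	HIST_H2B_12	HIST_H2B_13	HIST_H2B_14	HIST_H2B_15	HIST_H2B_16	HIST_H2B_17	HIST_H2B_18
RD_HIST_H3	replication-dependent histone family	HIST_H3_01	HIST_H3_02	HIST_H3_03	HIST_H3_04	HIST_H3_05	HIST_H3_06	HIST_H3_07	HIST_H3_08	HIST_H3_09	HIST_H3_10	HIST_H3_11	HIST_H3_12	HIST_H3_13	HIST_H3_14	HIST_H3_15
RD_HIST_H4	replication-dependent histone family	HIST_H4_01	HIST_H4_02	HIST_H4_03	HIST_H4_04	HIST_H4_05	HIST_H4_06	HIST_H4_07	HIST_H4_08	HIST_H4_09	HIST_H4_10	HIST_H4_11
RD_HIST_ALL	replication-dependent histone family	HIST_H1_01	HIST_H1_02	HIST_H1_03	HIST_H1_04	HIST_H1_05	HIST_H1_06	HIST_H2A_01	HIST_H2A_02	HIST_H2A_03	HIST_H2A_04	HIST_H2A_05	HIST_H2A_06	HIST_H2A_07	HIST_H2A_08	HIST_H2A_09	HIST_H2A_10	HIST_H2A_11	HIST_H2A_12	HIST_H2A_13	HIST_H2A_14	HIST_H2A_15	HIST_H2A_16	HIST_H2B_01	HIST_H2B_02	HIST_H2B_03	HIST_H2B_04	HIST_H2B_05	HIST_H2B_06	HIST_H2B_07	HIST_H2B_08	HIST_H2B_09	HIST_H2B_10	HIST_H2B_11	HIST_H2B_12	HIST_H2B_13	HIST_H2B_14	HIST_H2B_15	HIST_H2B_16	HIST_H2B_17	HIST_H2B_18	HIST_H3_01	HIST_H3_02	HIST_H3_03	HIST_H3_04	HIST_H3_05	HIST_H3_06	HIST_H3_07	HIST_H3_08	HIST_H3_09	HIST_H3_10	HIST_H3_11	HIST_H3_12	HIST_H3_13	HIST_H3_14	HIST_H3_15	HIST_H4_01	HIST_H4_02	HIST_H4_03	HIST_H4_04	HIST_H4_05	HIST_H4_06	HIST_H4_07	HIST_H4_08	HIST_H4_09	HIST_H4_10	HIST_H4_11
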