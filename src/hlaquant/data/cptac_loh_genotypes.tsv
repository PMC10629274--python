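study	gene	patient_id	tumor_allele1	tumor_allele2	normal_allele1	normal_allele2
LUAD	A	C3L-00279	A*24:02P	A*24:02P	A*25:01P	A*24:02P
LUAD	A	C3N-00169	A*24:03P	A*24:03P	A*24:03P	A*11:01P
LUAD	A	C3N-00580	A*24:07P	A*24:07P	A*03:01P	A*24:07P
LUAD	C	C3N-00580	C*04:01P	C*04:01P	C*04:01P	C*03:04P
LUAD	A	C3N-02155	A*24:02P	A*24:02P	A*01:01P	A*24:02P
LUAD	C	C3N-02155	C*07:02P	C*07:02P	C*07:02P	C*06:02P
LUAD	A	C3N-02586	A*24:02P	A*24:02P	A*24:02P	A*02:06P
LSCC	A	C3L-01884	A*24:02P	A*24:02P	A*24:02P	A*03:01P
LSCC	A	C3L-02648	A*02:01P	A*02:01P	A*02:01P	A*11:01P
LSCC	A	C3L-03272	A*02:01P	A*02:01P	A*01:01P	A*02:01P
LSCC	A	C3N-01893	A*26:01P	A*69:01P	A*69:01P	A*69:01P
LSCC	A	C3N-02425	A*02:01P	A*02:01P	A*11:01P	A*02:01P
HNSCC	A	C3L-02651	A*23:01P	A*23:01P	A*23:01P	A*11:01P
HNSCC	B	C3N-02275	B*13:02P	B*13:02P	B*13:02P	B*15:01P
HNSCC	A	C3N-02279	A*68:01P	A*68:01P	A*68:01P	A*02:01P
HNSCC	A	C3N-03841	A*02:01P	A*02:01P	A*11:02P	A*02:01P
HNSCC	A	C3N-03928	A*33:01P	A*33:01P	A*33:01P	A*03:01P
CCRCC	A	C3N-00242	A*24:02P	A*24:02P	A*24:02P	A*03:01P
CCRCC	A	C3N-01175	A*23:01P	A*23:01P	A*23:01P	A*03:01P
CCRCC	B	C3N-01175	B*08:01P	B*08:01P	B*08:01P	B*35:01P
CCRCC	C	C3N-01175	C*07:01P	C*07:01P	C*04:01P	C*07:01P
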