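# spliceindex v0.1.0 pool_size=5 seed=42
pool_id	cell_type	cells	pool_size_param
T00.p0	T00	T00_c0007,T00_c0009,T00_c0012,T00_c0014,T00_c0015	5
T00.p1	T00	T00_c0000,T00_c0003,T00_c0006,T00_c0010,T00_c0019	5
T00.p2	T00	T00_c0002,T00_c0005,T00_c0011,T00_c0016,T00_c0018	5
T00.p3	T00	T00_c0001,T00_c0004,T00_c0008,T00_c0013,T00_c0017	5
T01.p0	T01	T01_c0004,T01_c0007,T01_c0008,T01_c0009,T01_c0018	5
T01.p1	T01	T01_c0001,T01_c0005,T01_c0006,T01_c0011,T01_c0015	5
T01.p2	T01	T01_c0000,T01_c0002,T01_c0012,T01_c0014,T01_c0019	5
T01.p3	T01	T01_c0003,T01_c0010,T01_c0013,T01_c0016,T01_c0017	5
T02.p0	T02	T02_c0006,T02_c0007,T02_c0008,T02_c0012,T02_c0013	5
T02.p1	T02	T02_c0001,T02_c0005,T02_c0009,T02_c0010,T02_c0017	5
T02.p2	T02	T02_c0003,T02_c0014,T02_c0015,T02_c0018,T02_c0019	5
T02.p3	T02	T02_c0000,T02_c0002,T02_c0004,T02_c0011,T02_c0016	5
T03.p0	T03	T03_c0002,T03_c0003,T03_c0008,T03_c0013,T03_c0018	5
T03.p1	T03	T03_c0000,T03_c0006,T03_c0011,T03_c0015,T03_c0019	5
T03.p2	T03	T03_c0004,T03_c0005,T03_c0014,T03_c0016,T03_c0017	5
T03.p3	T03	T03_c0001,T03_c0007,T03_c0009,T03_c0010,T03_c0012	5
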