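gene_name	gene_length	m6a_positions
aspA	1437	425
cspA	213	27,30,82,83,109,113,119,137,140,141,146,180,205,212
cspE	210	7
dnaK	1917	844
gatY	855	734
glpD	1506	962,1340
groL	1647	331,673,1433,1583,1596,1639
hflX	1281	148
ompC	1104	167
pal	522	425
proX	993	835,866
raiA	342	6,138,200,206,212,214,223
rpmF	174	9
rpoA	990	250,871
rpsA	1674	1088,1268,1272,1324,1363,1457,1516,1571,1613,1616
rpsG	540	534
rpsU	216	1
secY	1332	23
tig	1299	1289
tufA	1185	263,545,758,800
tufB	1185	181,268,479,545,676,709,732,733,751,755,803,924,940,941,942,947
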