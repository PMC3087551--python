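genome	fabZ	lpxA	lpxB	lpxC	lpxD	lpxH	lpxK	lpxL	lpxM	waaA
G12	1	1	.	1	.	1	1	1	1	1
G03	1	1	.	1	.	1	1	1	1	1
G04	1	1	.	1	.	1	1	1	2	.
G09	1	1	.	1	.	2	2	1	2	1
G10	1	1	.	1	.	2	2	1	3	1
G11	1	1	1	1	1	1	1	1	1	.
G07	1	.	1	1	1	1	1	1	1	.
G08	1	2	1	1	.	1	.	1	.	.
G01	1	1	1	1	1	2	.	.	1	.
G02	.	1	1	2	1	1	.	.	1	1
G05	.	1	1	2	1	1	.	.	2	.
G06	.	1	1	2	1	1	.	.	2	1
# fabZ: gain@N0 losses@N9 dups@N1
# lpxA: gain@N0 losses@G07 dups@G08
# lpxB: gain@N2 dups@N2
# lpxC: gain@N0
# lpxD: gain@N2 losses@G08
# lpxH: gain@N0 dups@N13,N4
# lpxK: gain@N0 losses@G08,N4
# lpxL: gain@N0 losses@N4
# lpxM: gain@N0 losses@G08
# waaA: gain@N0 losses@G01,G04,G05,N3
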