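mz_MH	sequence	MCC-0	MCC-D	MBP-0	MBP-D	SPC-0	SPC-D	sources
163.0714	SG			1.28		1.25		P02662;P02668;P00711
175.1078	VG		1.27		1.27		1.27	P00711;P24627;P02769
187.1078	PA		1.45		1.45		1.45	P02668;P02754
189.1234	IG		2.19		2.19		2.19	P02662;P02663
189.1234	VA	4.52	4.52	4.52	4.52		4.52	P02662;P02663;P02666;P02668;P02754;P24627;P02769
205.1183	VS	4.58	4.53	4.63	4.62		4.62	P02769
207.0976	ST		2.83		2.87		2.87	P02662;P02663;P02668;P00711;P24627;P02769
215.1391	VP			2.05	1.9			P02663;P24627
217.1183	PT						1.52	P02663;P02666;P02668;P02754;P24627;P02769
219.1340	SL		2.04		2.03		2.01	P02666;P02754;P24627;P02769
219.1340	VT		1.17		1.12			P02668;P02754;P24627;P02769
229.1547	PL		3.89		3.82		3.77	P02662;P02666;P02754;P24627;P02769
229.1547	IP		3.89		3.82		3.77	P02668
230.1136	PN		1.31		1.31		1.31	P24627;P02769
231.1704	VL		2.68		2.61			P02662;P02663;P02666;P02668;P02754;P24627;P02769
234.1449	SK		1.89		1.90			P02662;P02663;P02666;P24627
244.1656	PK		1.32		1.32		1.27	P02662;P02663;P02666;P24627;P02769
246.1449	IN						2.49	P02666;P02668;P00711
247.1111	PM		2.83		2.83		2.86	P02662;P02754
249.1268	VM		1.55		1.58		1.57	P02666;P02769
253.1296	PH		1.20		1.20		1.21	P02666;P02668;P00711;P02769
261.1445	IE		2.37		2.36		2.36	P02666;P02668;P02769
263.1391	PF		6.96		6.94		6.94	P02662;P02666;P02668
269.1609	IH		2.22		2.22		2.28	P02662;P02666;P02668
272.1718	PR						1.20	P24627
274.1874	VR		3.59					P02663;P02666;P02668;P02754;P24627;P02769
279.1340	PY		3.07		3.15		3.17	P02668;P24627;P02769
281.1496	VY		4.52		4.50		4.53	P02663;P02666;P02754
288.2031	IR		5.94		5.96			P02668;P02754;P24627
292.1292	SW		1.28		1.31		1.28	P02666;P24627
300.1918	IPA		3.45		3.45			P02754
302.1500	PW		5.82		5.82		5.82	P02663
318.1813	IW						2.32	P02663;P00711;P24627
326.2075	PPL		15.01		14.95			P02666;P02769
328.2231	VPL		7.71		7.76		7.59	P02662
360.1952	IPM		11.39		10.45		10.48	P24627
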