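source	name	casrn	animal	study_type	method	effect_level
EPA ToxVal	4-Cumylphenol	599-64-4	Rat	Repeat Dose	NOAEL	50
EPA ToxVal	AFB1	1162-65-8	Human	Repeat Dose	BMDL01	0.000078
EPA ToxVal	Atrazine	1912-24-9	Mouse	Reproductive	NOEL	0.001
EPA ToxVal	Bifenthrin	82657-04-3	Rat	Developmental	NOAEL	1
EPA ToxVal	Bis4CPS	620-92-8	Rat	Repeat Dose	LOEL	20
EPA ToxVal	BPA	80-05-07	Rat	Developmental	NOAEL	0.015
EPA ToxVal	Cyanazine	21725-46-2	Rat	Repeat Dose	NOAEL	0.005
EPA ToxVal	Cyclophosphamide	6055-19-2		Repeat Dose	Cancer	0.57
EPA ToxVal	Cyproterone ace	427-51-0	Mouse	Repeat Dose	NOAEL	125
EPA ToxVal	Eugenol	97-53-0	Rat	Repeat Dose	NOAEL	57
EPA ToxVal	Fenofibrate	49562-28-9	Mouse	Developmental	LEL	11.7
EPA ToxVal	Flutamide	13311-84-7	Rat	Repeat Dose	NOAEL	10
EPA ToxVal	Genistein	446-72-0	Rat	Developmental	NEL	20
EPA ToxVal	Lovastatin	75330-75-5	Mouse	Repeat Dose	NOAEL	30
EPA ToxVal	PFHxA	307-24-4	Rat	Repeat Dose	NOAEL	200
EPA ToxVal	PFOA	335-67-1	Mouse	Reproductive	LOEL	0.02
EPA ToxVal	Prochloraz	67747-09-5	Dog	Repeat Dose	NOAEL	2.5
EPA ToxVal	Propiconazole	60207-90-1	Mouse	Repeat Dose	NOAEL	2.7
EPA ToxVal	Pyraclostrobin	175013-18-0	Rat	Repeat Dose	NOAEL	3.4
EPA ToxVal	Reserpine	50-55-5	Mouse	Repeat Dose	NOAEL	0.12
EPA ToxVal	Rotenone	83-79-4	Rat	Developmental	LOAEL	0.75
EPA ToxVal	Simazine	122-34-9	Mouse	Reproductive	NOEL	0.005
EPA ToxVal	Trifloxystrobin	141517-21-7	Rabbit	Developmental	NOAEL	10
EPA ToxVal	Troglitazone	97322-87-7	Mouse	Repeat Dose	NOAEL	1200
EPA ToxVal	Vinclozolin	50471-44-8	mouse	Reproductive	LOEL	1
EPA ToxVal	Zidovudine	30516-87-1	Mouse	Repeat Dose	LEL	100
REACH	2DD-Glucose	66-13-6	rat	Reproductive	NOAEL	20
REACH	BPAF	1478-61-1	Rat	Repeat Dose	NOAEL	3.5
REACH	BPS	80-09-01	Rat	Reproductive / Developmental	NOAEL	10
REACH	Cyproconazole	94361-06-5	Rat	Reproductive	NOAEL	1
REACH	Estradiol	50-28-2	Rabbit	Developmental	NOEL	0.0003
REACH	Lactofen	77501-63-4	Rat	Reproductive	NOEL	2.5
REACH	TGSA	41481-66-7	Rat	Repeat Dose	NOEL	15
REACH	Thiram	137-26-8	Dog	Repeat Dose	NOEL	0.84
REACH	Urea	57-13-6		Developmental	NOAEL	500
OECD	B[a]P	50-32-8		Repeat Dose	LOEL	0.05
OECD	Fenpyroximate	111812-58-9		Reproductive	LOEL	8.45
OECD	Imazalil	35554-44-0		Reproductive	NOAEL	5
OECD	PFOS	1763-23-1		Reproductive	NOAEL	0.03
HC	Propyl gallate	121-79-9		Repeat Dose	NOAEL	135
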