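function	protein	site	wt_shift
Aconitate hydratase 2	AcnB	S244	1.20
Isocitrate lyase	AceA	S398	0.94
DNA protection during starvation protein	Dps	S106	0.71
Superoxide dismutase [Fe]	SodB	T34	0.69
Sensor histidine kinase DpiB	DpiB	S66	0.41
UPF0234 protein YajQ	YajQ	S104	0.29
Isocitrate lyase	AceA	T3	0.22
Sensor histidine kinase DpiB	DpiB	S69	0.22
Sensor histidine kinase DpiB	DpiB	S72	0.22
DNA-directed RNA polymerase subunit alpha	RpoA	S21	0.04
Phosphoenolpyruvate carboxykinase [ATP]	PckA	S250	-0.17
Phosphoribosylformylglycinamidine cyclo-ligase	PurM	S195	-0.42
UPF0339 protein YegP	YegP	T37	-0.53
D-3-phosphoglycerate dehydrogenase	SerA	T63	-1.07
Protein ElaB	ElaB	S60	-1.36
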