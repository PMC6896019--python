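dataset_name	dataset_code	n_normal	n_tumor	total
Bladder urothelial carcinoma	BLCA	21	418	439
Breast carcinoma	BRCA	96	791	887
Esophageal carcinoma	ESCA	16	185	201
Head and Neck squamous cell carcinoma	HNSC	50	528	578
Kidney renal clear cell carcinoma	KIRC	160	324	484
Kidney renal papillary cell carcinoma	KIRP	45	275	320
Liver hepatocellular carcinoma	LIHC	50	377	427
Lung adenocarcinoma	LUAD	32	473	505
Lung squamous cell carcinoma	LUSC	42	370	412
Pancreatic adenocarcinoma	PAAD	10	184	194
Prostate adenocarcinoma	PRAD	50	502	552
Thyroid carcinoma	THCA	56	507	563
Uterine Corpus Endometrial Carcinoma	UCEC	46	438	484
Colorectal carcinoma	CRC	45	411	456
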