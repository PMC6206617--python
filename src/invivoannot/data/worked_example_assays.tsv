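assay_id	description	assay_type	bao_format	assay_organism_l2	target_organism_l2	src_id
CHEMBL772714	Adjuvant arthritic rat activity determined with respect to spirogermanium at a dose of 30 mg/kg	F	BAO_0000218	Mammalia		1
CHEMBL777832	Blood pressure lowering activity in renal hypertensive rats after intravenous administration; no drop in blood pressure or a statistically insignificant drop in blood pressure was observed (in vivo)	F	BAO_0000218	Mammalia		1
CHEMBL683996	Compound was evaluated in vivo for cysLT1 receptor induced airway obstruction in guinea pig (OA) at 2.0 hour after oral administration.	F	BAO_0000218	Mammalia		1
CHEMBL716118	In vivo antimalarial activity in mice (Mus musculus) against chloroquine-resistant Plasmodium yoelii species. NS after subcutaneous administration	F	BAO_0000218	Mammalia		1
CHEMBL732290	Analgesic activity in tail flick test, oral administration	F	BAO_0000218	Mammalia		1
CHEMBL723844	Compound was administered subcutaneously and was evaluated for opioid agonist activity by antinociceptive tail-flick (TF) assay in mice; I denotes Inactive at 30 mg/kg	F	BAO_0000218	Mammalia		1
CHEMBL2328414	Antioxidant activity against CCl4-induced oxidative hepatic injury Wistar albino rat model assessed as effect on liver cytosolic catalase activity per mg protein at 100 mg/kg, ip for 7 consecutive days prior to CCL4 challenge measured 24 h post CCl4 challenge (Rvb = 218.25 +/- 11.43 U/mg protein)	F	BAO_0000218	Mammalia		1
CHEMBL703119	In vivo antitumor activity against L1210 leukemia in 18 mice measured as T/C value; T/C = 18/9	F	BAO_0000218	Mammalia		1
CHEMBL785102	In vivo binding specificity the compound in rat striatum at 60 min of intravenous injection.	F	BAO_0000218	Mammalia		1
CHEMBL732935	Compound was evaluated for the time from injection to peak inhibition of the twitch response at 0.4 mg/kg dose	F	BAO_0000218	Mammalia		1
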