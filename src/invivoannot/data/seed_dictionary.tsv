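assay_class_id	level1	level2	level3	source	patterns	pattern_flags	mesh_terms	inducer_compounds	control_compounds	provenance
AC_RADIANT_HEAT	Nervous System	Central Analgesic Activity	Radiant Heat Method	Hock_2016	[Tt]ail\W?[Ff]lick		PAIN		morphine;codeine;meperidine	external
AC_ANALGESIC_PHEN	Nervous System	General Analgesic Activity	General Analgesic Nociceptic and Allodynic Activity	phenotype	[Aa]nalges|[Aa]ntinocicept|[Aa]llodyni		PAIN			repo
AC_ADJUVANT_ARTHRITIS	Musculo-skeletal System	Anti-Inflammatory Activity	Adjuvant Arthritis in Rats	Hock_2016	[Aa]djuvant[ -]?arthrit		ARTHRITIS, EXPERIMENTAL	Freund's complete adjuvant		repo
AC_RENAL_HTN	Cardiovascular System	Cardiovascular analysis	Renal Hypertension	Hock_2016	[Rr]enal[ -]?hypertens		HYPERTENSION, RENAL;HYPERTENSION			repo
AC_AIRWAY	Respiratory System	Airway Function	General Airway Models	phenotype	[Aa]irway		RESPIRATORY TRACT DISEASES			repo
AC_ANTIMALARIAL	Antiparasitic Products, Insecticides and Repellents	Antiprotozoal Activity	General Antimalarial Activity	phenotype	[Aa]ntimalarial|[Pp]lasmodium		MALARIA		chloroquine	repo
AC_CCL4_LIVER	Alimentary Tract and Metabolism	Liver Function	Carbon tetrachloride CCl4 Induced Liver Fibrosis in Rats	Vogel_2008	CC[lL]4|[Cc]arbon[ -]?tetrachloride		LIVER CIRRHOSIS	carbon tetrachloride		repo
AC_DILI_PHEN	Alimentary Tract and Metabolism	Liver Function	General Models of Drug Induced Liver Injury	phenotype	[Hh]epatic injury|[Hh]epatic damage|[Ll]iver injury|[Ll]iver damage|[Ll]iver fibrosis|[Hh]epatotox|[Hh]epatoprotect		LIVER DISEASES			repo
AC_L1210	Antineoplastic and Immunomodulating Agents	Leukemia Oncology Models	L1210 Experimental Leukemia	Hock_2016	L1210		LEUKEMIA L1210			repo
AC_LEUKEMIA_PHEN	Antineoplastic and Immunomodulating Agents	Leukemia Oncology Models	General Leukemia	phenotype	[Ll]euk[ae]mi		LEUKEMIA			repo
AC_NEOPLASM_PHEN	Antineoplastic and Immunomodulating Agents	General Oncology Models	Neoplasms	phenotype	[Aa]ntitumou?r|[Aa]ntineoplastic|[Tt]umou?r xenograft		NEOPLASMS			repo
AC_ANGIOTENSIN	Cardiovascular System	Cardiovascular analysis	Angiotensin II Antagonism in Vivo	Hock_2016	[Aa]ngiotensin[ -]?II		HYPERTENSION;CARDIOVASCULAR DISEASES;VASCULAR DISEASES	angiotensin II		repo
AC_ANTIEPILEPTIC	Nervous System	Anti-Epileptic Activity	General Anti-Epileptic Activity	phenotype	[Aa]nti-?epileptic|[Aa]nticonvuls		EPILEPSY;SEIZURES	pentylenetetrazole		repo
AC_STARTLE	Nervous System	Tests for Anxiolytic Activity	Acoustic Startle Response in Rats	Hock_2016	[Aa]coustic[ -]?startle		ANXIETY;REFLEX, STARTLE		diazepam	repo
AC_RADIAL_MAZE	Nervous System	Learning and Memory	Spatial Discrimination Learning in the Radial Arm Maze	Vogel_2008	[Rr]adial[ -]?arm[ -]?maze		MEMORY DISORDERS	scopolamine		repo
AC_WRITHING	Nervous System	Peripheral Analgesic Activity	Writhing Test for Analgesic Activity	Hock_2016	[Ww]rithing		PAIN	acetic acid;phenylquinone	aspirin	repo
AC_PAW_EDEMA	Musculo-skeletal System	Anti-Inflammatory Activity	Paw Edema Test	Hock_2016	[Cc]arrageenan|[Pp]aw o?edema		INFLAMMATION	carrageenan;formaldehyde	indomethacin	repo
AC_AUTOIMMUNE	Antineoplastic and Immunomodulating Agents	Methods for Testing Immunological Factors	Spontaneous Autoimmune Diseases In Animals	Vogel_2008	[Aa]utoimmune		AUTOIMMUNE DISEASES;IMMUNE SYSTEM DISEASES			repo
AC_COLITIS	Alimentary Tract and Metabolism	Intestinal Function	Experimental Colitis Inflammatory Gut Disease	Vogel_2008	[Cc]olitis|DSS[ -]induced		COLITIS, ULCERATIVE;INFLAMMATORY BOWEL DISEASES;CROHN DISEASE;DIGESTIVE SYSTEM DISEASES	dextran sulfate sodium;trinitrobenzene sulfonic acid		repo
AC_LXR	Alimentary Tract and Metabolism	Measurement of Blood Glucose-Lowering and Antidiabetic Activity	Anti-Diabetic Effects of Liver X Receptor Agonists	Vogel_2008	[Ll]iver[ -]X[ -][Rr]eceptor|\bLXR\b		DIABETES MELLITUS;DIABETES MELLITUS, TYPE 2;DIABETES MELLITUS, TYPE 1			repo
AC_ESTROGEN	Genito Urinary System and Sex Hormones	Ovarian Hormones	General Estrogen or Progestogen Activity	phenotype	[Oo]?[Ee]strogen|[Pp]rogest[oe]gen|[Uu]terotrophic		GONADAL HORMONES		estradiol	repo
AC_MEAN_BP	Cardiovascular System	Cardiovascular Safety Pharmacology	Cardiovascular Safety Pharmacology: Mean Blood Pressure or Mean Arteral Blood Pressure	Vogel_2013	[Mm]ean arteria?l blood pressure|[Mm]ean blood pressure|\bMAP\b		BLOOD PRESSURE			repo
AC_LEWIS_LUNG	Antineoplastic and Immunomodulating Agents	Carcinoma Oncology Models	Lewis Lung Carcinoma	phenotype	[Ll]ewis[ -][Ll]ung		CARCINOMA, LEWIS LUNG;CARCINOMA;NEOPLASMS, EXPERIMENTAL			repo
AC_DESPAIR_SWIM	Nervous System	Tests for Anti-Depressant Activity	Despair Swim Test	Hock_2016	[Ff]orced[ -]swim|[Dd]espair[ -]swim|[Bb]ehaviou?ral despair		DEPRESSIVE DISORDER		imipramine	repo
AC_ANTIDEPRESSANT	Nervous System	Tests for Anti-Depressant Activity	General Anti-Depressant Activity	phenotype	[Aa]nti-?depress		DEPRESSIVE DISORDER;MENTAL DISORDERS			repo
AC_HEART_RATE	Cardiovascular System	Cardiovascular Safety Pharmacology	Heart Rate Measurement	Vogel_2013	[Hh]eart[ -]rate|\bHR\b		HEART RATE			repo
AC_ANTIINFLAM	Musculo-skeletal System	Anti-Inflammatory Activity	General Anti-Inflammatory Models	phenotype	[Aa]nti-?inflammatory		INFLAMMATION			repo
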