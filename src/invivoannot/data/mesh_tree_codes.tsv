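mesh_term	tree_codes
ANXIETY	F01
ARTHRITIS, EXPERIMENTAL	C05
AUTOIMMUNE DISEASES	C20
BLOOD PRESSURE	G09
CARCINOMA	C04
CARCINOMA, LEWIS LUNG	C04
CARDIOVASCULAR DISEASES	C14
COLITIS, ULCERATIVE	C06
CROHN DISEASE	C06
DEPRESSIVE DISORDER	F03
DIABETES MELLITUS	C18;C19
DIABETES MELLITUS, TYPE 1	C18;C19;C20
DIABETES MELLITUS, TYPE 2	C18;C19
DIGESTIVE SYSTEM DISEASES	C06
EPILEPSY	C10
GONADAL HORMONES	D06
HEART RATE	G09
HYPERTENSION	C14
HYPERTENSION, RENAL	C12;C14
IMMUNE SYSTEM DISEASES	C20
INFLAMMATION	C23
INFLAMMATORY BOWEL DISEASES	C06
LEUKEMIA	C04;C20
LEUKEMIA L1210	C04
LIVER CIRRHOSIS	C06
LIVER DISEASES	C06
MALARIA	C03
MEMORY DISORDERS	C10;C23
MENTAL DISORDERS	F03
NEOPLASMS	C04
NEOPLASMS, EXPERIMENTAL	C04
PAIN	C23
REFLEX, STARTLE	G11
RESPIRATORY TRACT DISEASES	C08
SEIZURES	C10;C23
VASCULAR DISEASES	C14
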