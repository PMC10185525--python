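concept_id	name	entity_class	relation	doc_id	sentence
chem:cocaine	(-)-Cocaine	CHEMICAL	CAUSE	d01	Additionally, cocaine use has been associated with left ventricular hypertrophy, myocarditis, and dilated cardiomyopathy, which can lead to heart failure if drug use is continued
chem:vitamin-e	Vitamin E	CHEMICAL	CAUSE	d02	Yet, high doses of supplemental vitamin E have been associated with an elevated risk of heart failure and all-cause mortality
chem:vitamin-e	Vitamin E	CHEMICAL	CAUSE	d03	Vitamin E supplementation might be associated with an increase in total mortality, heart failure, and hemorrhagic stroke
food:salt	Salt	FOOD	CAUSE	d04	In patients who already have heart failure, a high salt intake aggravates the retention of salt and water, thereby exacerbating heart failure symptoms and progression of the disease
food:meat-products	Meat products	FOOD	CAUSE	d05	Thermal processing of meat products generates cardiotoxic compounds capable of inducing heart failure in both humans and laboratory animals
chem:n3-fatty-acid	Acid, n-3 fatty	CHEMICAL	TREAT	d06	Evidence from epidemiological, clinical and experimental studies indicates a beneficial role of the omega-3 polyunsaturated fatty acids (omega-3 PUFA) found in fish oils in the prevention and management of heart failure
chem:n3-fatty-acid	Acid, n-3 fatty	CHEMICAL	TREAT	d07	This review summarise the data related to use of omega-3 PUFA supplementation as a potential treatment for heart failure and discussed possible mechanism of action
chem:n3-fatty-acid	Acid, n-3 fatty	CHEMICAL	TREAT	d08	The 2017 American Heart Association science advisory on omega-3 fatty acid supplements suggested that it is reasonable to use omega-3 fatty acids for secondary prevention in people with coronary heart disease and heart failure
chem:canagliflozin	Antidiabetics canagliflozin	CHEMICAL	TREAT	d09	It has been concluded that canagliflozin, dapagliflozin, empagliflozin, or ertugliflozin can be recommended for preventing hospitalization associated with heart failure in patients with type 2 diabetes and established cardiovascular disease or those at high cardiovascular risk
chem:dha	DHA	CHEMICAL	TREAT	d10	Intake of fish oil containing docosahexaenoic acid (DHA) and eicosapentaenoic acid (EPA) prevents heart failure; however, the mechanisms are unclear
chem:ester	Ester	CHEMICAL	TREAT	d11	Because L-carnitine and its esters help reduce oxidative stress, they have been proposed as a treatment for many conditions, i.e. heart failure, angina and weight loss
chem:omega3-fatty-acid	Omega-3 fatty acid	CHEMICAL	TREAT	d08	The 2017 American Heart Association science advisory on omega-3 fatty acid supplements suggested that it is reasonable to use omega-3 fatty acids for secondary prevention in people with coronary heart disease and heart failure
chem:calcium	Calcium	CHEMICAL	TREAT	d12	Here we review the key observations, controversies, and discoveries that have led to the development of novel compounds targeting the RyR2/calcium release channel for treating heart failure and for preventing lethal arrhythmias
food:dietary-fish-oil	Dietary fish oil	FOOD	TREAT	d10	Intake of fish oil containing docosahexaenoic acid (DHA) and eicosapentaenoic acid (EPA) prevents heart failure; however, the mechanisms are unclear
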