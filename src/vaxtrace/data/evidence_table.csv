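vaccine,country_category,technology_category,outcome_kind,outcome_label,severity,probability_raw,probability_format
AstraZeneca,other,vector,side_effect,Blood clots,extreme,20,per_million
AstraZeneca,other,vector,side_effect,Immune system attacks nerves,extreme,10,per_million
AstraZeneca,other,vector,side_effect,Immune system attacks blood,extreme,5,per_million
AstraZeneca,other,vector,benefit,COVID-19 infection,not_applicable,78,percent
AstraZeneca,other,vector,benefit,Severe COVID-19,not_applicable,91,percent
AstraZeneca,other,vector,benefit,Death from COVID-19,not_applicable,92,percent
BioNTech/Pfizer,other,mRNA,side_effect,Heart muscle inflammation,extreme,16,per_million
BioNTech/Pfizer,other,mRNA,side_effect,Heart membrane inflammation,extreme,28,per_million
BioNTech/Pfizer,other,mRNA,side_effect,Severe tiredness,severe,46000,per_million
BioNTech/Pfizer,other,mRNA,benefit,COVID-19 infection,not_applicable,95,percent
BioNTech/Pfizer,other,mRNA,benefit,Severe COVID-19,not_applicable,96,percent
BioNTech/Pfizer,other,mRNA,benefit,Death from COVID-19,not_applicable,98,percent
Moderna,US,mRNA,side_effect,Heart muscle inflammation,extreme,25,per_million
Moderna,US,mRNA,side_effect,Heart membrane inflammation,extreme,32,per_million
Moderna,US,mRNA,side_effect,Severe muscle pain,severe,100000,per_million
Moderna,US,mRNA,benefit,COVID-19 infection,not_applicable,96,percent
Moderna,US,mRNA,benefit,Severe COVID-19,not_applicable,97,percent
Moderna,US,mRNA,benefit,Death from COVID-19,not_applicable,98,percent
Johnson & Johnson,US,vector,side_effect,Blood clots,extreme,38,per_million
Johnson & Johnson,US,vector,side_effect,Immune system attacks nerves,extreme,98,per_million
Johnson & Johnson,US,vector,side_effect,Severe muscle pain,severe,14000,per_million
Johnson & Johnson,US,vector,benefit,COVID-19 infection,not_applicable,71,percent
Johnson & Johnson,US,vector,benefit,Severe COVID-19,not_applicable,86,percent
Johnson & Johnson,US,vector,benefit,Death from COVID-19,not_applicable,82,percent
Novavax,US,other,side_effect,Severe general discomfort,severe,63000,per_million
Novavax,US,other,side_effect,Severe tiredness,severe,83000,per_million
Novavax,US,other,side_effect,Severe muscle pain,severe,49000,per_million
Novavax,US,other,benefit,COVID-19 infection,not_applicable,90,percent
Novavax,US,other,benefit,Severe COVID-19,not_applicable,87,percent
Novavax,US,other,benefit,Death from COVID-19,not_applicable,,percent
Sinovac,China,other,side_effect,Facial paralysis,extreme,50,per_million
Sinovac,China,other,side_effect,Tiredness,mild,82000,per_million
Sinovac,China,other,side_effect,Muscle pain,mild,40000,per_million
Sinovac,China,other,benefit,COVID-19 infection,not_applicable,53,percent
Sinovac,China,other,benefit,Severe COVID-19,not_applicable,71,percent
Sinovac,China,other,benefit,Death from COVID-19,not_applicable,73,percent
Bharat Biotech,other,other,side_effect,Fever,mild,6700,per_million
Bharat Biotech,other,other,side_effect,Headache,mild,6700,per_million
Bharat Biotech,other,other,side_effect,Tiredness,mild,3200,per_million
Bharat Biotech,other,other,benefit,COVID-19 infection,not_applicable,78,percent
Bharat Biotech,other,other,benefit,Severe COVID-19,not_applicable,93,percent
Bharat Biotech,other,other,benefit,Death from COVID-19,not_applicable,,percent
CanSino Biologics,China,vector,side_effect,Severe drowsiness,severe,42000,per_million
CanSino Biologics,China,vector,side_effect,Severe headache,severe,54000,per_million
CanSino Biologics,China,vector,side_effect,Severe muscle pain,severe,41000,per_million
CanSino Biologics,China,vector,benefit,COVID-19 infection,not_applicable,58,percent
CanSino Biologics,China,vector,benefit,Severe COVID-19,not_applicable,92,percent
CanSino Biologics,China,vector,benefit,Death from COVID-19,not_applicable,,percent
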