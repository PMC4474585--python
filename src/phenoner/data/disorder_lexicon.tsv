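chest pain	sosy
shortness of breath	sosy
dyspnea	sosy
orthopnea	sosy
fatigue	sosy
palpitations	sosy
edema	sosy
cough	sosy
nausea	sosy
left atrial dilation	sosy
coronary artery disease	dsyn
myocardial infarction	dsyn
cardiomyopathy	dsyn
ischemic heart disease	dsyn
atrial fibrillation	dsyn
hypertension	dsyn
hypercholesterolemia	dsyn
hyperlipidemia	dsyn
diabetes mellitus	dsyn
obesity	dsyn
anaemia	dsyn
anemia	dsyn
proteinuria	fndg
dysuria	fndg
hematuria	fndg
renal insufficiency	dsyn
renal function	fndg
chronic kidney disease	dsyn
elevated creatinine	fndg
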