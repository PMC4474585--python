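# Starter token-pattern rule pack.
# One rule per line: LABEL => [spec](quantifier), ...
# This pack covers the documented worked patterns plus a few variants for
# the bundled synthetic vocabulary; it is NOT a reconstruction of any
# full production rule set.

# Noun(s) + optional be-verb + past participle/adjective, excluding
# normal-condition words: matches "heart is enlarged", "abdomen was
# distended", "leg swollen"; rejects "chest is normal", "heart is regular".
SignSymptom => [syn=NN|NNP]{1,3}, [sem=beverb]?, [syn=VBN|JJ, token!="normal"|"regular"|"stable"]

# Kidney-related findings: optional participle/adjective + renal/kidney + noun.
NonTraditionalRiskFactor => [syn=VBN|JJ]?, [token=renal|kidney], [syn=NN]

# Common lexicalized risk factors.
RiskFactor => [token=hypertension|hypercholesterolemia|hyperlipidemia|obesity|smoking]

# Cardiac etiologies expressed as adjective + noun compounds.
Cause => [token=coronary|myocardial|ischemic|valvular|atrial], [syn=NN]{1,2}
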