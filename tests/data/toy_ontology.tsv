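# Toy smoking-cessation feature ontology (synthetic fixture for tests).
# child	relation	parent ; '!' marks a negated literal in disjointWith rows.
nurse	subClassOf	health_professional
doctor	subClassOf	health_professional
pharmacological_support	subClassOf	somatic_delivery
NRT	subClassOf	pharmacological_support
bupropion	subClassOf	pharmacological_support
varenicline	subClassOf	pharmacological_support
placebo	subClassOf	pharmacological_support
pill	subClassOf	somatic_delivery
patch	subClassOf	somatic_delivery
bupropion	disjointWith	!pill
varenicline	disjointWith	!pill
control
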