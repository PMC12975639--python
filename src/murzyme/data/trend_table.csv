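id,category,feature,classical,murburn,tier,weight
1,structural,heme,no,yes,salient,2.0
2,structural,flavin,usually-no,some-yes,soft,0.5
3,structural,fes,rare,some-yes,soft,0.5
4,structural,constrained_access,no,yes,definite,1.0
5,structural,substrate_larger_than_site,no,some-yes,soft,0.5
6,theoretical,redox_reaction,no,yes,definite,1.0
7,theoretical,exergonic,mixed,yes,soft,0.5
8,theoretical,oxygen_needed,usually-no,usually-yes,soft,0.5
9,theoretical,drs_involvement,usually-no,yes,salient,2.0
10,theoretical,reversible,yes,need-not-be,soft,0.5
11,experimental,substrate_selectivity,yes,no,salient,2.0
12,experimental,product_specificity,yes,no,definite,1.0
13,experimental,modulator_diversity,no,yes,definite,1.0
14,experimental,nonintegral_stoichiometry,no,yes,salient,2.0
15,experimental,variable_stoichiometry,no,yes,definite,1.0
16,experimental,unusual_kinetic_values,no,yes,definite,1.0
17,experimental,kcat_exceeds_diffusion,no,yes,definite,1.0
18,experimental,atypical_substrate_dependence,no,yes,definite,1.0
19,experimental,bulk_phase_dependency,no,yes,definite,1.0
20,experimental,atypical_temperature_dependence,no,yes,definite,1.0
21,postulate,shape_change_needed,sometimes,no,soft,0.5
22,postulate,multisubstrate_serial,yes,no,definite,1.0
23,postulate,complex_requirements,sometimes,no,soft,0.5
24,postulate,intermediate_molecularity,sometimes-high,low,soft,0.5
25,postulate,n_mechanistic_steps,sometimes-high,moderate,soft,0.5
26,postulate,probability_index,low,moderate,definite,1.0
27,postulate,long_distance_et,sometimes,no,soft,0.5
28,postulate,high_affinity_es_complex,yes,usually-no,soft,0.5
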